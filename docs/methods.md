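# Methods

This note documents the generative model, the estimation and detection
procedures, the synthetic-data generator, the evaluation metrics and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Generative model of a fluorescence trace

Frame `k` of a trace starts at `start_time + k / rate` (frame-onset
convention, 0-based). A single spike at onset `T` contributes

    g(t, T, τ) = (1 − e^{(T−t)/τ₁}) e^{(T−t)/τ₂},  t ≥ T  (0 before T)

which peaks `τ₁·ln((τ₁+τ₂)/τ₁)` after onset with peak value
`(1−r)·r^{τ₁/τ₂}`, `r = τ₁/(τ₁+τ₂)`. The noiseless trace is
`b₀ + a·Σᵢ g(t, Tᵢ, τ)`; transients superpose linearly. Amplitude `a` is
the kernel multiplier, so the observable single-spike peak is
`a · peak(g)`. Transients are truncated at `8·τ₂` past onset
(< 3.4·10⁻⁴ of the peak), keeping superposition linear-time.

Nonlinearity enters as `f(x) = x^α` for `x > 1`, identity otherwise, with
`x` in units of the single-spike peak. Saturation (α < 1) and
superlinearity (α > 1) therefore bend only superpositions — bursts —
never isolated transients. Gaussian noise with SD `σ` completes the model.

**SNR convention.** SNR = single-spike peak amplitude / noise SD. The
simulator's `snr` parameter sets `σ = peak / snr`.

## Model estimation (`ca_model.CalciumModel`)

Given traces and known spike times, the fit maximizes the Gaussian
likelihood over (a, b₀, σ, τ₁, τ₂) and per-spike latent sub-frame jitters:

- (a, b₀) have the closed-form least-squares solution given τ and the
  jitters; σ is the residual SD. These are exact conditional updates, so
  the log-likelihood never decreases (asserted in tests).
- τ₁ and τ₂ alternate one-dimensional grid searches (τ₁: 20 log-spaced
  points in [0.005, 0.2] s; τ₂: 25 in [0.1, 2.0] s — brackets reported
  indicator kinetics from fast GCaMP variants to OGB-1), up to 20 outer
  iterations, followed by local refinement whose span shrinks five-fold
  per round (three rounds). Sub-percent τ precision matters because a
  decay-constant error of ~1% biases the downstream vernier timing by
  several milliseconds.
- Latent jitters are optimized greedily on the vernier grid (step =
  interval/10, range ±half an interval). With ≤ 25 usable spikes the fit
  searches τ₁ and the jitters *jointly* over the τ₁ grid: alternating
  updates provably trap in a distorted-τ₁ optimum when the supplied spike
  times carry sub-frame errors, because a single rise sample cannot
  separate "earlier onset" from "slower rise".

**Data selection.** Fitting uses 2 s post-spike segments. Spikes whose
neighbour is closer than 2 s are excluded when at least 10 isolated spikes
remain — superpositions are exactly where real indicators go nonlinear —
otherwise all spikes are used with a warning (the design matrix always
contains the *full* superposition, so overlaps are modelled either way).

**Degeneracy.** A fit is rejected (`DegenerateFitError`) when the trace
has no dynamic range or the fitted amplitude is ≤ 10⁻⁹ of it.

**Identifiability limit.** For a single spike sampled below ~30 Hz
(interval ≳ 3·τ₁ for fast indicators), the onset and τ₁ are confounded:
distorted-τ₁ fits attain equal or higher likelihood than the truth, so no
estimator resolves such an onset to a tenth of an interval. With several
spikes sharing one kernel, or at ≥ 40 Hz, the confound disappears.

## Nonlinearity analysis and compensation

Observed ΔF/F is regressed on the linear prediction at every frame
(pooled across cells). Three response curves are fitted by least squares:
`y = s·x`, and `y = c₁·e^{c₂x} + c₃` with either sign pattern
(c₁, c₂ < 0: saturating; c₁, c₂ > 0: growing; both strictly increasing,
hence invertible). Small-sample-corrected AIC selects the family.
Compensation maps observed values through the numeric inverse (monotone
bisection, 64 halvings) within the fitted range; values above clamp to
the upper edge, values below pass through unchanged. The pass-through can
introduce a step where the fitted curve's lower end differs from the
identity; monotonicity of the map is guaranteed within the fitted curve's
output range. If the prediction spans less than one single-spike
amplitude, the data cannot constrain a curve and the linear family is
returned with a warning. Compensation is applied before detection only
when a non-linear family wins.

## Detection

**Coincidence score.** First differences of the trace cross-correlated
with first differences of the kernel sampled at the trace rate (support
5·τ₂) — a matched filter for transient onsets, invariant to constant
offsets. The derivative tail is zero-padded so onsets near the end of the
trace still score (partial support). Scores are standardized by
median/MAD (robust SD units): transient-laden traces would inflate a
mean/SD standardization.

**Candidates.** One candidate per upward threshold crossing; the
pseudo-spike time PT is the crossing frame's onset. Segments of
`pre + 1 + post` frames of trace values and scores, edge-replicated at
trace boundaries, form the feature vector.

**Labelling.** Candidates are labelled against ground truth by optimal
one-to-one matching of PTs within `max(evaluation window, one frame
interval)`. The floor at one interval is deliberate: PTs are frame-onset
quantized, so at 10 Hz a half-interval window would systematically label
true spikes occurring late in their frame as non-spikes and poison the
classifier. Final evaluation keeps the strict window rule.

**Hyperparameters.** Threshold (0.5–5 robust SDs, step 0.5) × segment_pre
(1–3) × segment_post (2, 4, 6, 8) are grid-searched to maximize the mean
*post-classification* F1 on the training cells (a classifier is trained
and applied per configuration; configurations whose candidate sensitivity
cannot reach the current best are skipped). Scoring raw candidate
extraction instead is available (`objective="candidates"`) but caps
sensitivity: the classifier exists precisely so that permissive
thresholds are affordable. Ties break toward the lower threshold, then
the shorter segment.

**Classifier.** An RBF-kernel SVM (C = 1, γ = 'scale', class-balanced)
on standardized `[segment values ∥ segment scores]`. Class weighting
matters because false crossings outnumber spikes at permissive
thresholds; negatives are subsampled to ≤ 2000 (fixed seed) to keep
training near-linear. A single-label training set degrades to a constant
classifier with a warning.

## Vernier timing refinement

For each accepted candidate, in time order: subtract the modelled
transients of already-placed spikes, then slide a single modelled
transient over SJ ∈ (−Δ, +Δ) in steps of Δ/10 (Δ = frame interval) and
minimize the squared residual over a window from `segment_pre` frames
before PT to `max(segment_post, ⌈(peak delay + τ₂/2)·rate⌉)` frames after
— enough to cover the rise, the peak and the early decay, where the
prediction actually moves with SJ. The window is truncated before the
next candidate's onset so a following spike's rise cannot bias the
estimate (this measurably improves timing in bursts). Exact ties go to
the smaller |SJ|. The refined time is TT = PT + SJ. The ±1-frame span
(rather than [0, Δ)) covers crossings that lead or lag the true onset
under noise.

## Unsupervised operation

`bayes_detect` estimates everything from the bare trace by penalized
greedy maximum likelihood:

- **Initialization.** Noise floor σ from MAD of first differences /√2
  (transients barely move consecutive frames); baseline from a low
  quantile with Gaussian bias correction; single-spike peak from the 40th
  percentile of local-maximum heights of a ~50 ms-smoothed trace, peaks
  separated by ≥ 300 ms, each height measured against its local pre-onset
  level and filtered at 2.5σ — this discounts noise maxima, decay
  shoulders and burst superpositions; τ at the fitting grid midpoints.
- **Forward step.** Matched filtering of the residual proposes frame-grid
  onsets; every frame whose gain clears the penalty (≤ 25 per round) is
  refined on the vernier grid; the best proposal is accepted while its
  log-likelihood gain exceeds a BIC-style penalty of ½·ln N per spike
  time. After each acceptance, neighbours within 4·τ₂ are re-placed on
  the vernier grid (strictly SSE-decreasing), untangling close pairs.
- **Rounds.** When no proposal clears the penalty, spikes whose retention
  gain is ≤ penalty are pruned (backward step), the model is re-fitted on
  the survivors (CalciumModel with latent jitters, plus a robust
  amplitude: the median of per-spike least-squares amplitudes, immune to
  segments contaminated by still-missing spikes), the acceptance noise
  scale is widened to the current residual floor (at high SNR the
  residual is model mismatch, not noise — this stops mop-up spikes), and
  another round starts; at most 4 re-fits. Finally the model is
  re-calibrated and all times re-placed, twice.
- The recorded ascent accumulates each accepted proposal's realized
  likelihood gain under the model current at proposal time; it is
  strictly increasing by construction (asserted in tests).

`unsupervised_pipeline` then builds a simulation configuration from the
estimates (10 cells × 30 expected spikes, α = 1 unless a nonlinearity
model is supplied), trains the detector on the synthetic cells, and runs
candidate extraction + classification + vernier refinement on the real
trace. Ground truth is never an argument on this path.

Known limitation: at low sampling rate *and* low SNR (10 Hz, SNR 3) the
initial amplitude is overestimated by peak-selection bias and the greedy
search under-detects relative to the supervised pipeline; at SNR ≥ 5, or
at ≥ 30 Hz, the two modes perform comparably (tested).

## Evaluation metrics

- **Matching**: optimal one-to-one pairing (max hits, then min total
  |Δt|, earlier-truth tie-break) of estimates to truths within the
  window; implemented as a non-crossing DP and validated against
  exhaustive enumeration. A nearest-first greedy is *not* equivalent
  (counterexample: truth {0, 0.5}, estimate {0.4, 0.9}, window 0.45).
- **Window rule**: half the sampling interval; 50 ms at ≥ 30 Hz.
- **Sensitivity/precision/F1** with zero-denominator conventions
  (precision = 0 when nothing is detected; F1 = 0 when both are 0).
- **Spike distance**: minimum edit cost, insertion/deletion 1, shift
  |Δt|/window, by the standard dynamic program, normalized by the truth
  count; the inverse is capped at 100. Validated against brute-force
  enumeration on small trains.
- **CosMIC**: triangle kernel of half-width = window; L1 norms on a grid
  of 200 points per kernel width; `2‖min(y, ŷ)‖ / (‖y‖ + ‖ŷ‖)`. Two empty
  trains score 1 by convention.
- **Hyperacuity index**: sampling interval / mean |timing error| over
  matched spikes, with a 10⁻⁶ s floor. Timing errors for the index are
  paired within a *full* sampling interval (never below 50 ms), unlike
  the ROC window: a frame-grid estimator's errors are uniform over the
  whole interval, and conditioning them on a half-interval window would
  discard exactly the quantization error the index measures — under the
  full-interval pairing a frame-onset estimator sits at the Nyquist
  baseline of 2, the documented behaviour of grid-resolution methods.
- **Cross-validation**: `loocv` trains on n−1 cells and tests the
  held-out cell; summaries report mean ± 2·SEM.

## The synthetic-data generator

The generator emulates the benchmark regime the package is validated in:
homogeneous Poisson spiking (continuous-time onsets, so sampling jitter
arises naturally — no explicit jitter parameter), τ₁ = 0.01 s, τ₂ ∈
0.2–1 s, α ∈ 0.2–3, SNR ∈ {3, 5, 10}, sampling 10–60 Hz, 10 cells × 50
expected spikes at 1 Hz by default (≈ 500 spikes per condition, split
5/5 into train and test). Per-cell duration is `spikes_per_cell /
firing_rate`, so counts vary Poisson-fashion around the nominal value —
conditioning on exact counts would distort interval statistics. Per-cell
seeds derive from the master seed by a counter-based scheme, making
cells independent of generation order.

It does **not** emulate: Hill-type dye saturation, photobleaching,
baseline drift, movement artefacts, per-spike amplitude variability, or
correlated noise. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not performance on any particular
recording; the nonlinearity compensation and robust standardizations are
the pieces that address the gap, and real-data validation is the user's
responsibility.

## Benchmark problem sizes

The timing benchmark (`hyperspike.benchmarks`) uses a stratified 12-point
subset of the 3 × 3 × 3 × 3 condition grid — each factor level appears at
least three times, balanced across sampling rates — with 10 cells × 50
expected spikes per condition. These sizes keep a full run near one
minute on a single core while leaving ~2500 matched spikes in the
averages; per-condition indices at larger cell counts agree within the
reported 2·SEM.

## Reproducibility

All randomness flows from explicit seeds through
`numpy.random.SeedSequence`; the SVM (libsvm) and every numerical routine
are deterministic given their inputs, so identical seeds reproduce
identical datasets, fits and spike trains bit-for-bit.
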