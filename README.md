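# hyperspike

Spike detection and **sub-frame spike-time inference** from two-photon
calcium-imaging fluorescence traces.

Two-photon imaging trades temporal resolution for spatial coverage: traces
are sampled at 5–100 Hz while the underlying action potentials are
millisecond events, and the calcium indicator adds slow dynamics,
nonlinearity and noise. `hyperspike` recovers spike trains from ΔF/F traces
and places each detected spike on a *vernier* time grid ten times finer
than the sampling interval, reaching a timing precision well beyond the
frame rate ("hyperacuity").

## Who it is for

Systems-neuroscience labs that record population activity by calcium
imaging — with or without simultaneous electrical ground truth — and need
spike *times*, not just spike counts, e.g. for temporal-coding or
synchrony analyses.

## The model and the algorithm

A single action potential produces a stereotyped fluorescence transient
modelled by a double-exponential kernel

    g(t, T, τ) = (1 − exp[(T − t)/τ₁]) · exp[(T − t)/τ₂]   for t ≥ T,
    g(t, T, τ) = 0                                          for t < T,

with rise constant τ₁ and decay constant τ₂. A trace is the linear
superposition of one kernel per spike with common amplitude *a* on a
constant baseline *b₀*, optionally distorted by a power-law nonlinearity
f(x) = x^α above the single-spike level, plus i.i.d. Gaussian noise σ.

The supervised pipeline runs in three steps:

1. **Model estimation.** (a, b₀, σ) by closed-form EM-style conditional
   updates and (τ₁, τ₂) by an alternating one-dimensional grid search with
   progressive local refinement, using isolated spikes (inter-spike
   interval ≥ 2 s) when enough exist; sub-frame spike onsets are latent
   and optimized on the vernier grid. A nonlinearity analysis then
   regresses observed ΔF/F on the linear prediction, fits
   linear/saturating/growing response curves, and compensates the trace
   through the inverse curve when a non-linear family wins.
2. **Detection.** A coincidence score — the first difference of the trace
   cross-correlated with the first difference of the kernel — is
   thresholded (robust-SD units) to yield candidate events; an SVM trained
   on labelled candidate segments (trace values ∥ scores) separates spikes
   from false crossings. Threshold and segment length are grid-searched to
   maximize training-cell F1.
3. **Timing.** Each accepted candidate's pseudo-spike time PT (a frame
   onset) is refined by sliding the modelled transient over ±1 frame in
   steps of a tenth of the frame interval, minimizing the squared residual
   after subtracting previously placed spikes: TT = PT + SJ.

An unsupervised mode (`bayes_detect` / `unsupervised_pipeline`) estimates
the model and candidate spikes from the bare trace by penalized greedy
maximum likelihood, simulates labelled training data at the estimated
parameters, and self-trains the classifier — no electrical ground truth
anywhere.

Evaluation follows the field's conventions: windowed one-to-one matching
(half a sampling interval, 50 ms at ≥ 30 Hz), sensitivity / precision /
F1, a Victor–Purpura-style spike distance (insertion/deletion cost 1,
shift cost |Δt|/window, normalized by the truth count), the CosMIC
triangle-kernel overlap, and the **hyperacuity index** — sampling interval
divided by the mean absolute timing error of matched spikes (2 is the
frame-grid quantization limit).

## Worked example

```python
import hyperspike as hs

# 10 cells, 1 Hz Poisson firing, tau2 = 0.5 s, SNR 5, 60 Hz sampling
cfg = hs.SimulationConfig(firing_rate=1.0, tau2=0.5, alpha=1.0, snr=5.0,
                          sampling_rate=60.0, seed=1)
train, test = hs.generate_dataset(cfg, split=True)

result = hs.SupervisedPipeline(train, seed=0).fit()
reports = result.evaluate(test)
print(result.summary(reports))
```

prints

```
Supervised hyperacuity spike-inference pipeline
===============================================
train cells               5
transient tau1 / tau2     0.0093 s / 0.5001 s
amplitude / baseline      1.1069 / -0.0000 dF/F
noise sigma               0.1982 dF/F
nonlinearity family       linear
score threshold           1.50 robust SD
segment (pre+1+post)      2+1+4 frames
vernier factor            10
match window              50.0 ms
test-cell metrics (mean +/- 2SEM)
  sensitivity            0.927 +/- 0.038
  precision              0.949 +/- 0.026
  f1                     0.938 +/- 0.027
  inv_spike_distance     4.892 +/- 1.123
  cosmic                 0.860 +/- 0.026
  hyperacuity_index      3.389 +/- 0.578
```

The fitted decay constant (0.50 s) and noise SD (0.198) recover the
generating values (0.5 s, 0.2); on held-out cells the pipeline detects
~94% of spikes with ~95% precision, and the mean timing error is ~3.4×
smaller than the 16.7 ms sampling interval. `result.detect(trace)` returns
a `SpikeTrain` for any new trace; pass `refine=False` to keep frame-grid
times. Single spike trains are scored with
`hs.evaluate(truth, estimate, sampling_rate)`.

A `hyperspike` command-line tool wraps the same library:
`hyperspike simulate | fit | detect [--unsupervised] | evaluate | benchmark`.

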