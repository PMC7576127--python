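"""Sub-frame spike-time refinement on a vernier grid.

For each detected candidate the sampling jitter SJ — the offset between the
pseudo-spike time PT (a frame onset) and the true spike onset — is found by
sliding the modelled transient on a grid ``vernier_factor`` times finer than
the frame interval across a full +/- 1 frame, and minimizing the squared
residual between the local trace and the model prediction.  Transients of
previously accepted spikes are subtracted first, so overlapping responses do
not bias the search.  The refined (true) spike time is TT = PT + SJ.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .kernel import superpose
from .types import CalciumTrace, CaSpikeModel, DetectionConfig, SpikeTrain

__all__ = ["estimate_jitter", "refine_spike_times", "residual_post_frames"]


def residual_post_frames(model: CaSpikeModel, config: DetectionConfig,
                         sampling_rate: float) -> int:
    """Frames after PT entering the residual: cover the rise, peak and the
    early decay (where the prediction still moves with SJ), never less than
    the classifier segment."""
    span = model.peak_delay + 0.5 * model.tau2
    return max(config.segment_post, int(np.ceil(span * sampling_rate)))


def _vernier_offsets(interval: float, vernier_factor: int) -> np.ndarray:
    step = interval / vernier_factor
    return np.arange(-(vernier_factor - 1), vernier_factor) * step


def estimate_jitter(trace: CalciumTrace, model: CaSpikeModel, pt: float,
                    prior_spikes: SpikeTrain, config: DetectionConfig,
                    post_frames: Optional[int] = None) -> float:
    """Sampling jitter of the spike at PT, in seconds.

    Searches SJ in (-interval, +interval) at interval/vernier_factor steps;
    exact ties in the residual go to the smaller |SJ|.
    """
    dt = trace.frame_interval
    ft = trace.frame_times()
    k = int(round((pt - trace.start_time) * trace.sampling_rate))
    if post_frames is None:
        post_frames = residual_post_frames(model, config, trace.sampling_rate)
    lo = max(k - config.segment_pre, 0)
    hi = min(k + post_frames + 1, trace.n_frames)
    if lo >= hi:
        raise ValueError("residual window falls outside the trace")
    tl = ft[lo:hi]
    local = trace.values[lo:hi].astype(float)
    if len(prior_spikes):
        local = local - model.amplitude_a * superpose(
            prior_spikes.times, tl, model.tau1, model.tau2)
    offsets = _vernier_offsets(dt, config.vernier_factor)
    sse = np.empty(offsets.size)
    for i, off in enumerate(offsets):
        pred = model.baseline_b0 + model.amplitude_a * superpose(
            [pt + off], tl, model.tau1, model.tau2)
        r = local - pred
        sse[i] = float(r @ r)
    best = sse.min()
    close = np.flatnonzero(sse <= best + 1e-12 * max(best, 1.0))
    sj = offsets[close[np.argmin(np.abs(offsets[close]))]]
    return float(sj)


def refine_spike_times(trace: CalciumTrace, model: CaSpikeModel,
                       pts: Sequence[float], config: DetectionConfig) -> SpikeTrain:
    """Refine accepted candidates (sorted PTs) to vernier-resolution times.

    Candidates are processed in time order; each accepted spike joins the
    set subtracted from the trace for the jitter estimates that follow.
    """
    pts = sorted(float(p) for p in pts)
    rate = trace.sampling_rate
    post_res = residual_post_frames(model, config, rate)
    tts: list = []
    for i, pt in enumerate(pts):
        # truncate the residual before the next candidate's onset frame, so
        # a closely following spike's rise cannot bias this spike's jitter
        pf = post_res
        if i + 1 < len(pts):
            gap = int(round((pts[i + 1] - pt) * rate))
            pf = max(min(post_res, gap), 1)
        priors = SpikeTrain(np.sort(tts)) if tts else SpikeTrain(np.empty(0))
        sj = estimate_jitter(trace, model, pt, priors, config, post_frames=pf)
        tts.append(max(pt + sj, 0.0))
    return SpikeTrain(np.sort(tts))
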