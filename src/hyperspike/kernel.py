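"""The double-exponential single-spike transient kernel and superposition.

The unit kernel is

    g(t, T, tau) = (1 - exp[(T - t)/tau1]) * exp[(T - t)/tau2]   for t >= T
    g(t, T, tau) = 0                                             for t <  T

with rise constant tau1 and decay constant tau2 (0 < tau1 < tau2).  Its peak
sits at T + tau1*log((tau1 + tau2)/tau1).  A trace is modelled as the linear
superposition of one kernel per spike, scaled by a common amplitude, on top
of a constant baseline.
"""

from __future__ import annotations

import numpy as np

from .types import CaSpikeModel, SpikeTrain

__all__ = ["kernel_value", "kernel_peak_time", "kernel_peak_value",
           "superpose", "linear_prediction"]


def _check_taus(tau1: float, tau2: float) -> None:
    if not (0.0 < tau1 < tau2):
        raise ValueError("need 0 < tau1 < tau2")


def kernel_value(t, T, tau1: float, tau2: float):
    """Evaluate the unit kernel g(t, T, tau); vectorized over ``t``."""
    _check_taus(tau1, tau2)
    t = np.asarray(t, dtype=float)
    s = t - T
    with np.errstate(over="ignore"):
        out = (1.0 - np.exp(-s / tau1)) * np.exp(-s / tau2)
    out = np.where(s >= 0.0, out, 0.0)
    return out if out.ndim else float(out)


def kernel_peak_time(tau1: float, tau2: float) -> float:
    """Delay from onset to peak, tau1*log((tau1+tau2)/tau1) (closed form)."""
    _check_taus(tau1, tau2)
    return tau1 * np.log((tau1 + tau2) / tau1)


def kernel_peak_value(tau1: float, tau2: float) -> float:
    """Peak value of the unit kernel."""
    _check_taus(tau1, tau2)
    r = tau1 / (tau1 + tau2)
    return float((1.0 - r) * r ** (tau1 / tau2))


def superpose(spike_times, frame_times, tau1: float, tau2: float,
              support: float | None = None) -> np.ndarray:
    """Sum of unit kernels, one per spike, at the requested times.

    ``support`` truncates each transient (default 8*tau2, < 3.4e-4 of the
    peak) so long traces stay linear-time in spikes x local frames.
    """
    _check_taus(tau1, tau2)
    frame_times = np.asarray(frame_times, dtype=float)
    spike_times = np.asarray(spike_times, dtype=float)
    out = np.zeros_like(frame_times)
    if spike_times.size == 0 or frame_times.size == 0:
        return out
    if support is None:
        support = 8.0 * tau2
    # frames are uniform in every caller, but only monotonicity is assumed
    lo = np.searchsorted(frame_times, spike_times, side="left")
    hi = np.searchsorted(frame_times, spike_times + support, side="right")
    for T, a, b in zip(spike_times, lo, hi):
        if a >= b:
            continue
        s = frame_times[a:b] - T
        out[a:b] += (1.0 - np.exp(-s / tau1)) * np.exp(-s / tau2)
    return out


def linear_prediction(spikes: SpikeTrain, model: CaSpikeModel,
                      frame_times) -> np.ndarray:
    """b0 + a * sum_i g(t, T_i, tau): the linear response to a spike train."""
    g = superpose(spikes.times, frame_times, model.tau1, model.tau2)
    return model.baseline_b0 + model.amplitude_a * g
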