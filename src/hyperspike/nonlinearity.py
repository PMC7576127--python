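"""Sub/superlinearity of observed traces against the linear model prediction.

The observed dF/F is plotted against the linear prediction of the transient
model at every frame, and three candidate response curves are fitted by
least squares:

    linear       y = s * x
    saturating   y = c1 * exp(c2 * x) + c3   with c1 < 0, c2 < 0
    growing      y = c1 * exp(c2 * x) + c3   with c1 > 0, c2 > 0

Either exponential branch is strictly increasing (c1*c2 > 0), hence
invertible.  The winner by small-sample-corrected AIC becomes the
nonlinearity model; compensation maps observed values back through its
inverse so that the compensated trace is (approximately) linear in the
underlying spike superposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy.optimize import curve_fit

from .kernel import linear_prediction
from .types import CalciumTrace, CaSpikeModel

__all__ = ["NonlinearityModel", "analyze_nonlinearity", "compensate"]

FAMILIES = ("linear", "saturating-exponential", "growing-exponential")


@dataclass(frozen=True)
class NonlinearityModel:
    """A fitted monotone response curve y(x) on ``fit_range``."""

    family: str
    params: tuple
    fit_range: tuple

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family != "linear":
            c1, c2, _ = self.params
            if c1 * c2 <= 0:
                raise ValueError("exponential curve is not strictly increasing")

    @property
    def is_linear(self) -> bool:
        return self.family == "linear"

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.is_linear:
            return self.params[0] * x
        c1, c2, c3 = self.params
        return c1 * np.exp(c2 * x) + c3


def _exp_curve(x, c1, c2, c3):
    return c1 * np.exp(c2 * x) + c3


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2.0 * k * (k + 1) / (n - k - 1)
    return aic


def _fit_exponential(x, y, sign: int):
    """LS fit of c1*exp(c2*x)+c3 with sign(c2) = sign(c1) = ``sign``."""
    xr = float(x.max() - x.min())
    yr = float(y.max() - y.min())
    if sign > 0:
        p0 = [max(yr, 1e-6) * np.exp(-x.max() / xr), 1.0 / xr, float(y.min())]
        bounds = ([1e-12, 1e-9, -np.inf], [np.inf, 50.0 / xr, np.inf])
    else:
        p0 = [-max(yr, 1e-6), -1.0 / xr, float(y.max()) + 0.1 * yr]
        bounds = ([-np.inf, -50.0 / xr, -np.inf], [-1e-12, -1e-9, np.inf])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_exp_curve, x, y, p0=p0, bounds=bounds,
                                maxfev=20000)
    except (RuntimeError, ValueError):
        return None
    resid = y - _exp_curve(x, *popt)
    return tuple(float(p) for p in popt), float(resid @ resid)


def analyze_nonlinearity(traces, spikes, model: CaSpikeModel) -> NonlinearityModel:
    """Fit the response curve of observed dF/F vs. the linear prediction.

    Accepts one trace/spike-train pair or aligned lists (frames pooled).
    If the prediction spans less than one single-spike amplitude the data
    cannot constrain a curve and the linear family is returned with a
    warning.
    """
    if isinstance(traces, CalciumTrace):
        traces, spikes = [traces], [spikes]
    xs, ys = [], []
    for trace, st in zip(traces, spikes):
        xs.append(linear_prediction(st, model, trace.frame_times()))
        ys.append(trace.values)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    fit_range = (float(x.min()), float(x.max()))

    slope = float((x @ y) / (x @ x)) if float(x @ x) > 0 else 1.0
    rss_lin = float(((y - slope * x) ** 2).sum())

    if x.max() - x.min() < model.peak_amplitude:
        warnings.warn("insufficient dynamic range for nonlinearity analysis; "
                      "assuming a linear response", stacklevel=2)
        return NonlinearityModel("linear", (slope,), fit_range)

    n = x.size
    candidates = [("linear", (slope,), _aicc(rss_lin, n, 1))]
    for family, sign in (("saturating-exponential", -1),
                         ("growing-exponential", +1)):
        fit = _fit_exponential(x, y, sign)
        if fit is None:
            continue
        params, rss = fit
        candidates.append((family, params, _aicc(rss, n, 3)))
    family, params, _ = min(candidates, key=lambda c: c[2])
    return NonlinearityModel(family, params, fit_range)


def compensate(trace: CalciumTrace, nl: NonlinearityModel) -> CalciumTrace:
    """Map the trace through the inverse fitted curve.

    Linear family: values / slope.  Exponential families: monotone bisection
    of y = c1*exp(c2*x)+c3 to 1e-9 within the fit range; observed values
    below the curve at the lower fit edge pass through unchanged, values
    above the upper edge clamp to it.
    """
    if nl.is_linear:
        return CalciumTrace(trace.values / nl.params[0], trace.sampling_rate,
                            trace.start_time)
    x_lo, x_hi = nl.fit_range
    y_lo = float(nl.predict(x_lo))
    y_hi = float(nl.predict(x_hi))
    y = trace.values
    out = y.copy().astype(float)
    inside = (y >= y_lo) & (y <= y_hi)
    lo = np.full(int(inside.sum()), x_lo)
    hi = np.full(int(inside.sum()), x_hi)
    target = y[inside]
    for _ in range(64):  # (x_hi-x_lo)/2^64 << 1e-9
        mid = 0.5 * (lo + hi)
        higher = nl.predict(mid) < target
        lo = np.where(higher, mid, lo)
        hi = np.where(higher, hi, mid)
    out[inside] = 0.5 * (lo + hi)
    out[y > y_hi] = x_hi
    return CalciumTrace(out, trace.sampling_rate, trace.start_time)
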