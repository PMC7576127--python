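"""Synthetic spike trains and calcium traces.

The generator emulates the benchmark conditions used throughout the
package's validation: homogeneous Poisson spiking (1-10 Hz), a
double-exponential transient with tau1 = 0.01 s and tau2 in 0.2-1 s, a
power-law nonlinearity f(x) = x^alpha applied above the single-spike peak
level, and i.i.d. Gaussian noise fixed by the SNR (single-spike peak
amplitude / noise SD; typical values 3, 5, 10).

Spike onsets are continuous-time, never frame-aligned, so sub-frame
sampling jitter between spike onset and frame onset arises naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .kernel import kernel_peak_value, superpose
from .types import CalciumTrace, CaSpikeModel, SpikeTrain

__all__ = [
    "SimulationConfig",
    "generate_spike_train",
    "apply_alpha_nonlinearity",
    "synthesize_trace",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated recording condition.

    Defaults: 10 cells x 50 expected spikes at 1 Hz (500 spikes total),
    tau1 = 0.01 s, tau2 = 0.5 s, linear responses (alpha = 1), SNR 5,
    unit single-spike peak amplitude, zero baseline.
    """

    firing_rate: float = 1.0
    n_cells: int = 10
    spikes_per_cell: int = 50
    tau1: float = 0.01
    tau2: float = 0.5
    alpha: float = 1.0
    snr: float = 5.0
    sampling_rate: float = 60.0
    peak_amplitude: float = 1.0
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.firing_rate > 0 and self.snr > 0 and self.alpha > 0):
            raise ValueError("firing_rate, snr and alpha must be > 0")
        if not (0 < self.tau1 < self.tau2):
            raise ValueError("need 0 < tau1 < tau2")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        """Per-cell duration giving the nominal expected spike count."""
        return self.spikes_per_cell / self.firing_rate

    def model(self) -> CaSpikeModel:
        """The generative transient model implied by this configuration."""
        gpk = kernel_peak_value(self.tau1, self.tau2)
        return CaSpikeModel(
            tau1=self.tau1,
            tau2=self.tau2,
            amplitude_a=self.peak_amplitude / gpk,
            baseline_b0=self.baseline,
            noise_sigma=self.peak_amplitude / self.snr,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def generate_spike_train(firing_rate: float, duration: float, seed) -> SpikeTrain:
    """Homogeneous Poisson process on [0, duration)."""
    if not (firing_rate > 0):
        raise ValueError("firing_rate must be > 0")
    if not (duration > 0):
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(firing_rate * duration)
    return SpikeTrain(np.sort(rng.uniform(0.0, duration, size=n)))


def apply_alpha_nonlinearity(x, alpha: float):
    """Pointwise v -> v**alpha for v > 1, identity otherwise.

    ``x`` is in units of the single-spike peak amplitude, so the power law
    bends only superpositions (bursts), not isolated transients.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    out = np.where(x > 1.0, np.power(np.maximum(x, 1.0), alpha), x)
    return out if out.ndim else float(out)


def synthesize_trace(spikes: SpikeTrain, model: CaSpikeModel, alpha: float,
                     snr: float, sampling_rate: float, duration: float,
                     seed=None) -> CalciumTrace:
    """Render a spike train into a noisy fluorescence trace.

    The linear superposition is expressed in single-spike-peak units, passed
    through the power-law nonlinearity, rescaled, and finished with Gaussian
    noise of SD (peak amplitude)/snr plus the baseline.
    """
    if not (snr > 0):
        raise ValueError("snr must be > 0")
    if len(spikes) and (spikes.times[0] < 0 or spikes.times[-1] >= duration):
        raise ValueError("spikes must lie within [0, duration)")
    n_frames = max(2, int(round(duration * sampling_rate)))
    t = np.arange(n_frames) / sampling_rate
    xn = model.amplitude_a * superpose(spikes.times, t, model.tau1, model.tau2)
    xn /= model.peak_amplitude  # single-spike peak == 1
    f = apply_alpha_nonlinearity(xn, alpha)
    values = model.peak_amplitude * f
    if seed is not None:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, model.peak_amplitude / snr, size=n_frames)
    values = values + model.baseline_b0
    return CalciumTrace(values, sampling_rate)


def cell_seeds(master_seed: int, n_cells: int) -> list:
    """Counter-based per-cell seeds, independent of generation order."""
    return np.random.SeedSequence(master_seed).spawn(n_cells)


def generate_dataset(config: SimulationConfig, split: bool = False):
    """Generate one (trace, spikes) pair per cell; deterministic given seed.

    With ``split=True`` returns ``(train_cells, test_cells)`` as the first /
    last half of the cells (5/5 at defaults).
    """
    if split and config.n_cells < 2:
        raise ValueError("need n_cells >= 2 for a train/test split")
    model = config.model()
    cells = []
    for ss in cell_seeds(config.seed, config.n_cells):
        spike_ss, noise_ss = ss.spawn(2)
        spikes = generate_spike_train(config.firing_rate, config.duration, spike_ss)
        trace = synthesize_trace(spikes, model, config.alpha, config.snr,
                                 config.sampling_rate, config.duration,
                                 seed=noise_ss)
        cells.append((trace, spikes))
    if not split:
        return cells
    half = config.n_cells // 2
    return cells[:half], cells[half:]
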