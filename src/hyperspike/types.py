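"""Domain types shared across the package.

All times are absolute seconds on the trace's clock; frame ``k`` of a trace
starts at ``start_time + k / sampling_rate`` (frame-onset convention,
0-based indices).  A single convention everywhere avoids half-frame offsets
that would silently corrupt sub-frame timing scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np

__all__ = [
    "CalciumTrace",
    "SpikeTrain",
    "CaSpikeModel",
    "DetectionConfig",
    "EvalReport",
]


@dataclass(frozen=True)
class CalciumTrace:
    """A uniformly sampled dF/F fluorescence series.

    Parameters
    ----------
    values : array-like of float
        dF/F amplitude per frame (dimensionless).  Any affine dF/F scale is
        accepted; the transient model absorbs amplitude and baseline.
    sampling_rate : float
        Frame rate in Hz (> 0).
    start_time : float, default 0
        Onset time of frame 0, in seconds.
    """

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if vals.size < 2:
            raise ValueError("a trace needs at least 2 frames")
        if not np.all(np.isfinite(vals)):
            raise ValueError("trace values must be finite")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")
        object.__setattr__(self, "values", vals)

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Span covered by the frames, onset of frame 0 to end of last frame."""
        return self.n_frames / self.sampling_rate

    def frame_times(self) -> np.ndarray:
        """Onset timestamp of every frame."""
        return self.start_time + np.arange(self.n_frames) / self.sampling_rate


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times in seconds (ground truth or estimate)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        if t.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError("spike times must be finite")
        if t.size and np.any(t < 0):
            raise ValueError("spike times must be >= 0")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("spike times must be non-decreasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self):
        return iter(self.times)


@dataclass(frozen=True)
class CaSpikeModel:
    """The stereotyped single-spike fluorescence transient.

    ``tau1``/``tau2`` are the rise and decay time constants (s) of the
    double-exponential kernel, ``amplitude_a`` the kernel multiplier in dF/F
    units, ``baseline_b0`` the trace baseline and ``noise_sigma`` the
    Gaussian noise SD, both in dF/F units.
    """

    tau1: float
    tau2: float
    amplitude_a: float
    baseline_b0: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.tau1 < self.tau2):
            raise ValueError("need 0 < tau1 < tau2")
        if not (self.amplitude_a > 0):
            raise ValueError("amplitude_a must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def peak_delay(self) -> float:
        """Delay from spike onset to transient peak: tau1*log((tau1+tau2)/tau1)."""
        return self.tau1 * np.log((self.tau1 + self.tau2) / self.tau1)

    @property
    def kernel_peak(self) -> float:
        """Peak value of the unit kernel g."""
        r = self.tau1 / (self.tau1 + self.tau2)
        return float((1.0 - r) * r ** (self.tau1 / self.tau2))

    @property
    def peak_amplitude(self) -> float:
        """Peak dF/F of a single spike above baseline (a * peak of g)."""
        return self.amplitude_a * self.kernel_peak

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CaSpikeModel":
        return cls(**{k: float(d[k]) for k in
                      ("tau1", "tau2", "amplitude_a", "baseline_b0", "noise_sigma")})


@dataclass(frozen=True)
class DetectionConfig:
    """Hyperparameters of candidate extraction and timing refinement.

    ``score_threshold`` is in robust-SD units of the standardized coincidence
    score; ``segment_pre``/``segment_post`` are frame counts around the
    threshold-crossing frame; ``vernier_factor`` is the sub-frame grid
    refinement (10 -> time bins 10x finer than the sampling interval);
    ``match_window`` is the evaluation pairing window in seconds.
    """

    score_threshold: float = 2.0
    segment_pre: int = 1
    segment_post: int = 2
    vernier_factor: int = 10
    match_window: float = 0.05

    def __post_init__(self) -> None:
        if self.vernier_factor < 2:
            raise ValueError("vernier_factor must be >= 2")
        if self.segment_pre < 0 or self.segment_post < 0:
            raise ValueError("segment_pre/segment_post must be >= 0")
        if not (self.match_window > 0):
            raise ValueError("match_window must be > 0")

    @property
    def segment_length(self) -> int:
        return int(self.segment_pre + 1 + self.segment_post)


@dataclass
class EvalReport:
    """Evaluation of one (truth, estimate) spike-train pair."""

    hits: int
    misses: int
    false_positives: int
    sensitivity: float
    precision: float
    f1: float
    spike_distance: float
    inv_spike_distance: float
    cosmic: float
    hyperacuity_index: float
    paired_errors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["paired_errors"] = [float(e) for e in self.paired_errors]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            hits=int(d["hits"]),
            misses=int(d["misses"]),
            false_positives=int(d["false_positives"]),
            sensitivity=float(d["sensitivity"]),
            precision=float(d["precision"]),
            f1=float(d["f1"]),
            spike_distance=float(d["spike_distance"]),
            inv_spike_distance=float(d["inv_spike_distance"]),
            cosmic=float(d["cosmic"]),
            hyperacuity_index=float(d["hyperacuity_index"]),
            paired_errors=[float(e) for e in d.get("paired_errors", [])],
        )
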