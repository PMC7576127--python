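"""Spike-candidate detection: matched-filter score, extraction, SVM.

The coincidence score is the cross-correlation of the first difference of
the trace with the first difference of the sampled transient kernel — a
matched filter for transient onsets that is invariant to constant offsets.
Scores are standardized to zero median and unit robust SD (median/MAD), so
thresholds are in robust-SD units.  Each upward threshold crossing yields a
candidate with a pseudo-spike time (PT, the crossing frame's onset) and a
fixed-length trace/score segment; a radial-basis SVM trained on labelled
candidates separates spikes from non-spikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import median_abs_deviation
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .kernel import kernel_value
from .metrics import match_pairs, matching_window, roc_scores
from .types import CalciumTrace, CaSpikeModel, DetectionConfig, SpikeTrain

__all__ = [
    "CandidateSegment",
    "coincidence_score",
    "extract_candidates",
    "label_window",
    "optimize_detection",
    "SpikeClassifier",
    "train_classifier",
    "classify",
]

THRESHOLD_GRID = tuple(np.arange(0.5, 5.01, 0.5))
PRE_GRID = (1, 2, 3)
POST_GRID = (2, 4, 6, 8)


@dataclass
class CandidateSegment:
    """A windowed excerpt around one coincidence-threshold crossing."""

    frames: np.ndarray       # trace values, length segment_pre+1+segment_post
    scores: np.ndarray       # standardized scores on the same support
    pt: float                # pseudo-spike time (s), on the frame grid
    frame_index: int
    label: str = "unknown"   # {"spike", "non-spike", "unknown"}

    def feature_vector(self) -> np.ndarray:
        return np.concatenate([self.frames, self.scores])


def _kernel_diff_template(model: CaSpikeModel, sampling_rate: float) -> np.ndarray:
    """First differences of the kernel sampled at the trace rate (>= 5*tau2)."""
    dt = 1.0 / sampling_rate
    n = max(int(np.ceil(5.0 * model.tau2 * sampling_rate)), 2)
    g = kernel_value(np.arange(n + 1) * dt, 0.0, model.tau1, model.tau2)
    return np.diff(g)


def coincidence_score(trace: CalciumTrace, model: CaSpikeModel) -> np.ndarray:
    """Standardized matched-filter score; score[k] peaks for an onset in frame k."""
    d = _kernel_diff_template(model, trace.sampling_rate)
    dy = np.diff(trace.values)
    if d.size > dy.size:
        raise ValueError("kernel support exceeds trace length")
    # zero-pad the tail so onsets near the end of the trace still score
    # (partial-support matched filter)
    padded = np.concatenate([dy, np.zeros(d.size - 1)])
    raw = np.correlate(padded, d, mode="valid")  # length n - 1
    scores = np.zeros(trace.n_frames)
    med = float(np.median(raw))
    scale = float(median_abs_deviation(raw, scale="normal"))
    if scale <= 0:
        scale = float(np.std(raw)) or 1.0
    scores[:raw.size] = (raw - med) / scale
    return scores


def label_window(sampling_rate: float) -> float:
    """Window for labelling candidates against ground truth.

    PTs are frame-onset quantized, so the window is never narrower than one
    frame interval; otherwise true spikes late in their frame could not be
    labelled as spikes at low sampling rates.
    """
    return max(matching_window(sampling_rate), 1.0 / sampling_rate)


def extract_candidates(trace: CalciumTrace, scores: np.ndarray,
                       config: DetectionConfig,
                       truth: Optional[SpikeTrain] = None) -> list:
    """One candidate per upward threshold crossing, edge-padded to length.

    With ``truth`` given, candidates are labelled spike/non-spike by
    one-to-one matching of PTs to true spike times within
    :func:`label_window`.
    """
    thr = config.score_threshold
    above = scores >= thr
    crossing = above & ~np.concatenate([[False], above[:-1]])
    idx = np.flatnonzero(crossing)
    n = trace.n_frames
    out = []
    for k in idx:
        span = np.clip(np.arange(k - config.segment_pre, k + config.segment_post + 1),
                       0, n - 1)
        out.append(CandidateSegment(
            frames=trace.values[span].copy(),
            scores=scores[span].copy(),
            pt=trace.start_time + k / trace.sampling_rate,
            frame_index=int(k)))
    if truth is not None and out:
        pts = np.array([c.pt for c in out])
        pairs = match_pairs(truth.times, pts, label_window(trace.sampling_rate))
        matched = {j for _, j in pairs}
        for j, c in enumerate(out):
            c.label = "spike" if j in matched else "non-spike"
    return out


def _crossings(scores: np.ndarray, threshold: float) -> np.ndarray:
    above = scores >= threshold
    return np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))


def _segment_matrix(values: np.ndarray, idx: np.ndarray, pre: int,
                    post: int) -> np.ndarray:
    span = np.clip(idx[:, None] + np.arange(-pre, post + 1)[None, :],
                   0, values.size - 1)
    return values[span]


def _candidate_f1(trace: CalciumTrace, scores: np.ndarray, threshold: float,
                  truth: SpikeTrain) -> float:
    idx = _crossings(scores, threshold)
    pts = trace.start_time + idx / trace.sampling_rate
    pairs = match_pairs(truth.times, pts, label_window(trace.sampling_rate))
    hits = len(pairs)
    _, _, f1 = roc_scores(hits, len(truth) - hits, pts.size - hits)
    return f1


def optimize_detection(train_cells: Sequence[tuple], model: CaSpikeModel,
                       thresholds=THRESHOLD_GRID, pre_grid=PRE_GRID,
                       post_grid=POST_GRID, vernier_factor: int = 10,
                       objective: str = "pipeline") -> DetectionConfig:
    """Grid-search detection hyperparameters by mean training-cell F1.

    ``objective="pipeline"`` (default) scores each configuration by the F1
    of classified detections — a classifier is trained per configuration
    and applied to the training cells, so permissive thresholds whose false
    crossings the classifier can prune are preferred.  ``"candidates"``
    scores raw candidate extraction instead.  Ties break toward the lower
    threshold, then the shorter segment.
    """
    if not train_cells:
        raise ValueError("need at least one training cell with ground truth")
    rate = train_cells[0][0].sampling_rate
    cell_scores = [(trace, coincidence_score(trace, model), truth)
                   for trace, truth in train_cells]
    best = None  # (sort key, thr, pre, post)

    if objective == "candidates":
        for thr in thresholds:
            f1 = float(np.mean([_candidate_f1(trace, sc, thr, truth)
                                for trace, sc, truth in cell_scores]))
            for pre in pre_grid:
                for post in post_grid:
                    key = (-f1, thr, pre + post, pre)
                    if best is None or key < best[0]:
                        best = (key, thr, pre, post)
    elif objective == "pipeline":
        for thr in thresholds:
            per_cell = []
            cand_sens = []
            for trace, sc, truth in cell_scores:
                idx = _crossings(sc, thr)
                pts = trace.start_time + idx / trace.sampling_rate
                pairs = match_pairs(truth.times, pts,
                                    label_window(trace.sampling_rate))
                matched = np.zeros(idx.size, dtype=bool)
                matched[[j for _, j in pairs]] = True
                per_cell.append((trace, sc, truth, idx, pts, matched))
                cand_sens.append(len(pairs) / max(len(truth), 1))
            # even a perfect classifier cannot beat candidate sensitivity
            bound = 2.0 * np.mean(cand_sens) / (1.0 + np.mean(cand_sens))
            if best is not None and -bound > best[0][0]:
                continue
            for pre in pre_grid:
                for post in post_grid:
                    X_parts, y_parts = [], []
                    for trace, sc, truth, idx, pts, matched in per_cell:
                        X_parts.append(np.hstack([
                            _segment_matrix(trace.values, idx, pre, post),
                            _segment_matrix(sc, idx, pre, post)]))
                        y_parts.append(matched)
                    X = np.vstack(X_parts)
                    y = np.concatenate(y_parts).astype(int)
                    if np.unique(y).size < 2:
                        keep = y  # constant classifier: accept everything
                        pred = np.ones_like(y, dtype=bool)
                    else:
                        clf = _fit_svc(X, y)
                        pred = clf.predict(X).astype(bool)
                    f1s = []
                    off = 0
                    for trace, sc, truth, idx, pts, matched in per_cell:
                        kp = pred[off:off + idx.size]
                        off += idx.size
                        kept_pts = pts[kp]
                        pr = match_pairs(truth.times, kept_pts,
                                         label_window(trace.sampling_rate))
                        hits = len(pr)
                        _, _, f1 = roc_scores(hits, len(truth) - hits,
                                              kept_pts.size - hits)
                        f1s.append(f1)
                    key = (-float(np.mean(f1s)), thr, pre + post, pre)
                    if best is None or key < best[0]:
                        best = (key, thr, pre, post)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    _, thr, pre, post = best
    return DetectionConfig(score_threshold=float(thr), segment_pre=int(pre),
                           segment_post=int(post),
                           vernier_factor=vernier_factor,
                           match_window=matching_window(rate))


_MAX_NEGATIVES = 2000  # keeps SVM training near-linear on permissive thresholds


def _fit_svc(X: np.ndarray, y: np.ndarray, max_negatives: int = _MAX_NEGATIVES):
    neg = np.flatnonzero(y == 0)
    if neg.size > max_negatives:
        rng = np.random.default_rng(1234)  # fixed: subsampling must be reproducible
        sel = np.sort(np.concatenate(
            [np.flatnonzero(y == 1),
             rng.choice(neg, max_negatives, replace=False)]))
        X, y = X[sel], y[sel]
    pipe = make_pipeline(
        StandardScaler(),
        SVC(kernel="rbf", C=1.0, gamma="scale", class_weight="balanced"))
    pipe.fit(X, y)
    return pipe


class SpikeClassifier:
    """Max-margin spike/non-spike classifier on [frames || scores] features."""

    def __init__(self):
        self._pipe = None
        self.n_features_: Optional[int] = None

    def fit(self, candidates: Sequence[CandidateSegment]) -> "SpikeClassifier":
        X = np.array([c.feature_vector() for c in candidates])
        y = np.array([1 if c.label == "spike" else 0 for c in candidates])
        if np.unique(y).size < 2:
            raise ValueError("training candidates must contain both classes")
        self.n_features_ = X.shape[1]
        self._pipe = _fit_svc(X, y)
        return self

    def predict(self, candidates: Sequence[CandidateSegment]) -> list:
        if not candidates:
            return []
        X = np.array([c.feature_vector() for c in candidates])
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"feature length {X.shape[1]} != training length {self.n_features_}")
        y = self._pipe.predict(X)
        return ["spike" if v == 1 else "non-spike" for v in y]


class ConstantClassifier:
    """Degenerate fallback when training candidates carry a single label."""

    def __init__(self, label: str):
        self.label = label
        self.n_features_ = None

    def predict(self, candidates: Sequence[CandidateSegment]) -> list:
        return [self.label] * len(candidates)


def train_classifier(candidates: Sequence[CandidateSegment],
                     allow_constant: bool = False):
    """Train the SVM; with ``allow_constant`` a single-label training set
    yields a classifier that always emits that label instead of an error."""
    if allow_constant:
        labels = {c.label for c in candidates}
        if len(labels) == 1:
            warnings.warn("single-class candidate set; using a constant "
                          "classifier", stacklevel=2)
            return ConstantClassifier(labels.pop())
    return SpikeClassifier().fit(candidates)


def classify(clf: SpikeClassifier, candidates: Sequence[CandidateSegment]) -> list:
    return clf.predict(candidates)
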