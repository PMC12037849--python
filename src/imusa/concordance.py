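"""Breath-by-breath concordance and summary statistics.

The time axis is segmented into breaths at respiratory nadirs; each breath
is labelled detected-positive (overlaps any detected event) and
reference-positive (overlaps any reference apnea/hypopnea). Matching allows
a configurable breath gap in both directions and is non-consuming. Also
provides 2x2 metrics, macro-F1 over severity confusion matrices,
Bland-Altman agreement, and ROC/AUC with a Youden-optimal cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .events import RespiratoryEvent
from .io_formats import AnnotationSet

from .ahi import SEVERITY_ORDER

#: Minimum nadir separation — one minimal respiratory cycle (1 / 0.7 Hz).
MIN_BREATH_S = 1.0 / 0.7


@dataclass
class BreathTrack:
    """Nadir-delimited breath intervals with detection/reference labels."""

    nadir_times_s: np.ndarray
    re_positive: np.ndarray | None = None
    ref_positive: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nadir_times_s = np.asarray(self.nadir_times_s, dtype=float)
        if len(self.nadir_times_s) < 2:
            raise ValueError("need at least 2 nadirs to form a breath")
        if not np.all(np.diff(self.nadir_times_s) > 0):
            raise ValueError("nadir times must be strictly increasing")
        for name in ("re_positive", "ref_positive"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=bool)
                if v.shape != (self.n_breaths,):
                    raise ValueError(f"{name} must have one label per breath")
                setattr(self, name, v)

    @property
    def n_breaths(self) -> int:
        return len(self.nadir_times_s) - 1

    def intervals(self) -> np.ndarray:
        """Half-open breath intervals as an (n_breaths, 2) array."""
        return np.column_stack([self.nadir_times_s[:-1], self.nadir_times_s[1:]])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AgreementSummary:
    mean_difference: float
    loa_low: float
    loa_high: float
    r: float
    rmse: float


def segment_breaths(
    reference_resp: np.ndarray | None = None,
    sampling_rate_hz: float | None = None,
    nadir_times_s: Sequence[float] | None = None,
    min_separation_s: float = MIN_BREATH_S,
) -> BreathTrack:
    """Build a BreathTrack from a respiratory series or an explicit nadir list."""
    if nadir_times_s is not None:
        return BreathTrack(np.asarray(nadir_times_s, dtype=float))
    if reference_resp is None or sampling_rate_hz is None:
        raise ValueError("provide either nadir_times_s or (reference_resp, sampling_rate_hz)")
    x = np.asarray(reference_resp, dtype=float)
    distance = max(1, int(np.ceil(min_separation_s * sampling_rate_hz)))
    peaks, _ = find_peaks(-x, distance=distance)
    if len(peaks) < 2:
        raise ValueError("fewer than 2 respiratory nadirs found")
    return BreathTrack(peaks / sampling_rate_hz)


def _overlap_labels(intervals: np.ndarray, spans: Iterable[tuple[float, float]]) -> np.ndarray:
    labels = np.zeros(len(intervals), dtype=bool)
    starts, ends = intervals[:, 0], intervals[:, 1]
    for lo, hi in spans:
        labels |= (starts < hi) & (ends > lo)  # half-open overlap
    return labels


def label_breaths(
    track: BreathTrack,
    detected: Iterable[RespiratoryEvent] | None,
    reference: AnnotationSet | None,
) -> BreathTrack:
    """Label each breath by overlap with detected events / reference events."""
    intervals = track.intervals()
    re_pos = track.re_positive
    ref_pos = track.ref_positive
    if detected is not None:
        re_pos = _overlap_labels(intervals, [(e.onset_s, e.end_s) for e in detected])
    if reference is not None:
        ref_pos = _overlap_labels(intervals, [(a.onset_s, a.end_s) for a in reference])
    return BreathTrack(track.nadir_times_s, re_positive=re_pos, ref_positive=ref_pos)


def gap_tolerant_confusion(track: BreathTrack, gap_breaths: int = 1) -> ConfusionCounts:
    """Breath-level confusion counts allowing a +/- gap_breaths match window.

    Matching is non-consuming: one reference-positive breath may legitimize
    several nearby detected positives. TN absorbs everything unmatched.
    """
    if track.re_positive is None or track.ref_positive is None:
        raise ValueError("breath labels are not populated")
    det = track.re_positive
    ref = track.ref_positive
    n = len(det)
    g = int(gap_breaths)
    if g < 0:
        raise ValueError("gap must be non-negative")

    def near(labels: np.ndarray, i: int) -> bool:
        return bool(labels[max(0, i - g) : min(n, i + g + 1)].any())

    tp = sum(1 for i in range(n) if det[i] and near(ref, i))
    fp = int(det.sum()) - tp
    fn = sum(1 for j in range(n) if ref[j] and not near(det, j))
    tn = n - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def binary_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity/specificity/accuracy/PPV/NPV/F1; NaN marks undefined ones."""

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    sens = ratio(c.tp, c.tp + c.fn)
    spec = ratio(c.tn, c.tn + c.fp)
    ppv = ratio(c.tp, c.tp + c.fp)
    npv = ratio(c.tn, c.tn + c.fn)
    acc = ratio(c.tp + c.tn, c.total)
    f1 = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "ppv": ppv,
        "npv": npv,
        "f1": f1,
    }


def severity_confusion(
    predicted: Sequence[str], reference: Sequence[str]
) -> np.ndarray:
    """4x4 matrix, rows = predicted class, columns = reference class."""
    if len(predicted) != len(reference):
        raise ValueError("label lists differ in length")
    idx = {c: i for i, c in enumerate(SEVERITY_ORDER)}
    m = np.zeros((4, 4), dtype=int)
    for p, r in zip(predicted, reference):
        m[idx[p], idx[r]] += 1
    return m


def macro_f1(matrix: np.ndarray) -> float:
    """Unweighted mean of one-vs-rest class F1 scores.

    A class with no predictions or no actual members (undefined precision or
    recall) contributes F1 = 0; with tp = 0 the identity
    F1 = 2*tp / (row_sum + col_sum) already yields 0.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4) or (m < 0).any():
        raise ValueError("expected a non-negative 4x4 matrix")
    scores = []
    for k in range(4):
        denom = m[k, :].sum() + m[:, k].sum()
        scores.append(2.0 * m[k, k] / denom if denom > 0 else 0.0)
    return float(np.mean(scores))


def bland_altman(pairs: Sequence[tuple[float, float]]) -> AgreementSummary:
    """Agreement between reference and estimate: mean diff and +/-1.96 SD limits."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (reference, estimate) pairs")
    ref, est = arr[:, 0], arr[:, 1]
    d = est - ref
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.std(ref) == 0 or np.std(est) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(ref, est)[0, 1])
    return AgreementSummary(
        mean_difference=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        r=r,
        rmse=float(np.sqrt(np.mean(d**2))),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> tuple[float, float]:
    """AUC (trapezoidal over the empirical ROC) and the Youden-optimal cutoff.

    The cutoff semantics are "positive when score >= cutoff"; ties on
    Youden's J resolve to the lowest cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    # rank-based AUC (ties averaged) == trapezoidal area over the ROC
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    best_j, best_cut = -np.inf, float("nan")
    for cut in np.sort(np.unique(s)):
        pred = s >= cut
        sens = (pred & y).sum() / n_pos
        spec = (~pred & ~y).sum() / n_neg
        j_stat = sens + spec - 1.0
        if j_stat > best_j:  # strict '>' keeps the lowest cutoff on ties
            best_j, best_cut = j_stat, float(cut)
    return float(auc), best_cut


def positive_breath_rate(track: BreathTrack, monitoring_hours: float) -> float:
    """Hourly rate of detected-positive breaths."""
    if track.re_positive is None:
        raise ValueError("breath labels are not populated")
    if monitoring_hours <= 0:
        raise ValueError("monitoring_hours must be positive")
    return float(track.re_positive.sum()) / monitoring_hours
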