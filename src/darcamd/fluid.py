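"""Subretinal-fluid (SRF) quantification and conversion detection.

Per-visit SRF is the pixel sum of the binary per-slice segmentation masks of
the OCT volume.  Because eyes are scanned an uneven number of times, fluid is
summarized per 6-month interval as the *accumulated SRF*: total SRF pixels
across all scans in the window divided by the number of scans.  An eye
"converts" at the first interval that is SRF-positive while the preceding
period (baseline for the first interval) was SRF-negative; eyes already
SRF-positive at baseline cannot newly convert.  The module also provides
pixel-level precision/recall evaluation for segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VisitRecord:
    """One OCT acquisition: a stack of per-slice binary SRF masks."""

    eye_id: int
    month: float  # months since the baseline (DARC) date
    masks: list  # list of 2-D bool arrays, one per B-scan

    def __post_init__(self):
        if self.masks:
            shape = np.asarray(self.masks[0]).shape
            for m in self.masks:
                if np.asarray(m).shape != shape:
                    raise ValueError(
                        f"eye {self.eye_id}: visit masks differ in shape")

    @property
    def n_slices(self) -> int:
        return len(self.masks)


def visit_srf_amount(visit: VisitRecord) -> int:
    """Total SRF pixels summed over all slices of one visit."""
    if visit.n_slices == 0:
        raise ValueError(f"eye {visit.eye_id}: visit has no masks")
    return int(sum(np.count_nonzero(m) for m in visit.masks))


def interval_accumulated_srf(visits: list[VisitRecord]) -> tuple[float, int]:
    """Scan-averaged SRF over a 6-month window.

    Returns ``(accumulated_srf, n_scans)``; an empty window yields
    ``(nan, 0)`` and must be flagged by the caller.  Averaging by scan count
    makes the summary invariant to how often an eye happened to be imaged.
    """
    if not visits:
        return float("nan"), 0
    total = sum(visit_srf_amount(v) for v in visits)
    return total / len(visits), len(visits)


def srf_positive(accumulated_srf: float, min_pixels: float = 0.0) -> bool:
    """Positivity rule: accumulated SRF strictly above ``min_pixels``.

    The default of 0 treats any detected fluid as positive; a higher
    threshold rejects speckle-sized segmentations.
    """
    if np.isnan(accumulated_srf):
        raise ValueError("cannot classify an interval with no scans")
    return bool(accumulated_srf > min_pixels)


@dataclass
class IntervalSummary:
    index: int  # 0-based 6-month window
    n_scans: int
    accumulated_srf: float  # px per scan; nan when no scans
    srf_pos: bool
    new_srf: bool = False
    carried_forward: bool = False  # status copied from the previous interval
    unique_spot_count: int = 0  # filled by the prediction stage

    def __post_init__(self):
        if self.n_scans > 0 and not self.accumulated_srf >= 0:
            raise ValueError("accumulated SRF must be non-negative")
        if self.new_srf and not self.srf_pos:
            raise ValueError("new-SRF implies SRF-positive")


@dataclass
class EyeTimeline:
    eye_id: int
    baseline_srf: bool
    intervals: list[IntervalSummary]
    darc_count: int = 0
    baseline_label: str = ""  # clinical diagnosis group, if known
    conversion_interval: int | None = None

    def statuses(self) -> list[bool]:
        return [iv.srf_pos for iv in self.intervals]


def build_timeline(eye_id: int, baseline_srf: bool,
                   visits_by_interval: dict[int, list[VisitRecord]],
                   n_intervals: int, min_pixels: float = 0.0,
                   allow_recurrence: bool = False) -> EyeTimeline:
    """Assemble per-interval summaries and mark the conversion interval.

    Intervals with no scans carry the previous interval's status forward
    (baseline status for interval 0) and are flagged ``carried_forward``.
    """
    intervals: list[IntervalSummary] = []
    prev_status = baseline_srf
    for k in range(n_intervals):
        accum, n_scans = interval_accumulated_srf(visits_by_interval.get(k, []))
        if n_scans == 0:
            intervals.append(IntervalSummary(k, 0, float("nan"),
                                             prev_status, carried_forward=True))
        else:
            pos = srf_positive(accum, min_pixels)
            intervals.append(IntervalSummary(k, n_scans, accum, pos))
            prev_status = pos
    tl = EyeTimeline(eye_id, baseline_srf, intervals)
    tl.conversion_interval = detect_conversion(tl, allow_recurrence)
    return tl


def detect_conversion(timeline: EyeTimeline,
                      allow_recurrence: bool = False) -> int | None:
    """First interval with new SRF, or None.

    New SRF: SRF-positive with an SRF-negative preceding period (baseline for
    the first interval).  Eyes SRF-positive at baseline return None.  Only
    the first such interval counts; with ``allow_recurrence`` every
    negative-to-positive transition is additionally flagged ``new_srf``
    (the returned conversion interval is still the first).
    """
    for iv in timeline.intervals:
        iv.new_srf = False
    if timeline.baseline_srf:
        return None
    prev = False
    conversion = None
    for iv in timeline.intervals:
        if iv.srf_pos and not prev:
            if conversion is None:
                conversion = iv.index
                iv.new_srf = True
            elif allow_recurrence:
                iv.new_srf = True
        prev = iv.srf_pos
    return conversion


def conversion_rate(timelines: list[EyeTimeline], k: int) -> float:
    """Cumulative conversion percent among at-risk eyes through interval ``k``.

    At risk: SRF-negative at baseline with at least one scanned interval at
    or before ``k``.  Cumulative by construction, hence non-decreasing in
    ``k``.  Returns NaN (flagged undefined) when no eye is at risk.
    """
    at_risk = 0
    converted = 0
    for tl in timelines:
        if tl.baseline_srf:
            continue
        if not any(iv.n_scans > 0 for iv in tl.intervals[:k + 1]):
            continue
        at_risk += 1
        if tl.conversion_interval is not None and tl.conversion_interval <= k:
            converted += 1
    if at_risk == 0:
        return float("nan")
    return 100.0 * converted / at_risk


# ---------------------------------------------------------------------------
# segmentation evaluation


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; NaN if both are zero."""
    if precision + recall == 0:
        return float("nan")
    return 2 * precision * recall / (precision + recall)


@dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    precision_at: float = float("nan")
    recall_at: float = float("nan")
    f1: float = float("nan")
    auc: float = float("nan")
    no_positive_truth: bool = False


def precision_recall(predictions, truths, thresholds=None,
                     operating_threshold: float = 0.5) -> PRCurve:
    """Pixel-level precision-recall evaluation pooled over images.

    ``predictions`` may be probability maps or binary masks; ``truths`` are
    binary.  For each threshold t, a pixel is predicted positive when its
    score is >= t; TP/FP/FN are pooled over all images.  The AUC is the
    trapezoid integral of precision over the recall axis.  If the truth has
    no positive pixels, recall is undefined and the curve is flagged.
    """
    def _as_list(obj, caster):
        if isinstance(obj, np.ndarray) and obj.ndim == 2:
            return [caster(obj)]
        return [caster(a) for a in obj]

    preds = _as_list(predictions, lambda a: np.asarray(a, float))
    trus = _as_list(truths, lambda a: np.asarray(a).astype(bool))
    if len(preds) != len(trus):
        raise ValueError("predictions and truths must pair up")
    for p, t in zip(preds, trus):
        if p.shape != t.shape:
            raise ValueError("prediction/truth shape mismatch")
    score = np.concatenate([p.ravel() for p in preds])
    truth = np.concatenate([t.ravel() for t in trus])
    n_pos = int(truth.sum())

    if thresholds is None:
        thresholds = np.unique(np.concatenate([[operating_threshold],
                                               np.unique(score)]))
    thresholds = np.sort(np.asarray(thresholds, float))

    prec = np.empty(thresholds.size)
    rec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = score >= t
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        fn = n_pos - tp
        prec[i] = tp / (tp + fp) if tp + fp > 0 else float("nan")
        rec[i] = tp / (tp + fn) if n_pos > 0 else float("nan")
    curve = PRCurve(thresholds, prec, rec, no_positive_truth=(n_pos == 0))

    if n_pos > 0:
        pred = score >= operating_threshold
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        curve.precision_at = tp / (tp + fp) if tp + fp > 0 else float("nan")
        curve.recall_at = tp / n_pos
        curve.f1 = f1_score(curve.precision_at, curve.recall_at)
        ok = ~(np.isnan(prec) | np.isnan(rec))
        if ok.sum() >= 2:
            order = np.argsort(rec[ok])
            curve.auc = float(np.trapezoid(prec[ok][order], rec[ok][order]))
    return curve
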