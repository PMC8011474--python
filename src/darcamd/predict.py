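"""Eye-level prediction of new subretinal fluid from baseline spots.

The analysis asks whether marker-positive spots seen once at baseline
anticipate where and when subretinal fluid appears.  Spots overlying fluid
already present at baseline are excluded; each remaining spot is tracked
against the follow-up OCT volumes and counted once, at the first interval
where it overlies fluid (a "unique spot").  Per interval, an eye is then

* TP - new SRF and >=1 unique spot first overlapping it this interval,
* FN - new SRF but no unique spot,
* FP - no new SRF but unique spots (a first overlap with persisting or
  chance fluid outside the conversion interval),
* TN - neither.

From the per-interval confusion matrices come PPV, NPV, sensitivity and
specificity; the module also builds SRF-free "survival" curves split by the
baseline DARC count (> 5 vs <= 5) and tests the association between spot
counts and fluid magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import stats as dstats
from .fluid import EyeTimeline, VisitRecord
from .registration import OCTGeometry, OutOfVolumeError, fundus_to_oct

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpotSRFIntersection:
    eye_id: int
    spot_id: int
    interval: int  # first interval where the spot overlies SRF
    slice_index: int
    column: int
    baseline_overlap: bool = False


@dataclass
class ConfusionMatrix:
    interval: int
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def add(self, label: str) -> None:
        setattr(self, label.lower(), getattr(self, label.lower()) + 1)


@dataclass(frozen=True)
class PredictiveMetrics:
    """PPV/NPV/sensitivity/specificity; NaN marks an undefined ratio."""

    ppv: float
    npv: float
    sensitivity: float
    specificity: float


def spot_overlies_srf(point, masks: list, geometry: OCTGeometry,
                      tol_slices: int = 1, tol_cols: int = 10
                      ) -> tuple[bool, int, int]:
    """Does any SRF pixel fall in the tolerance window around the spot?

    The spot's fundus position maps to a (slice, column); the window spans
    +-``tol_slices`` B-scans and +-``tol_cols`` columns (all depth rows).
    Returns ``(hit, slice, column)``.  Raises OutOfVolumeError for points
    outside the volume footprint.
    """
    s, c = fundus_to_oct(point, geometry)
    lo_s, hi_s = max(0, s - tol_slices), min(len(masks) - 1, s + tol_slices)
    for si in range(lo_s, hi_s + 1):
        m = np.asarray(masks[si])
        lo_c = max(0, c - tol_cols)
        if m[:, lo_c:c + tol_cols + 1].any():
            return True, s, c
    return False, s, c


@dataclass
class UniqueSpotResult:
    eye_id: int
    records: list  # SpotSRFIntersection, first occurrence per spot
    counts: np.ndarray  # unique spots first overlapping per interval
    active_at_start: np.ndarray  # candidate spots alive entering interval
    n_baseline_excluded: int = 0
    n_out_of_volume: int = 0


def unique_spots(eye_id: int, points: np.ndarray,
                 visits: list, visit_intervals: list,
                 baseline_masks: list, geometry: OCTGeometry,
                 n_intervals: int, tol_slices: int = 1, tol_cols: int = 10
                 ) -> UniqueSpotResult:
    """Track baseline spots to their first overlap with follow-up SRF.

    ``points`` are baseline-subtracted spot coordinates in the registered
    reference frame.  Spots overlying baseline SRF are excluded up front;
    each surviving spot is counted at most once, at the earliest interval
    where it overlies fluid in any of that interval's visits.
    """
    points = np.atleast_2d(np.asarray(points, float)) if np.size(points) \
        else np.empty((0, 2))
    records: list[SpotSRFIntersection] = []
    active: list[tuple[int, np.ndarray]] = []
    n_base = n_oov = 0
    for sid, p in enumerate(points):
        try:
            hit, s, c = spot_overlies_srf(p, baseline_masks, geometry,
                                          tol_slices, tol_cols)
        except OutOfVolumeError:
            n_oov += 1
            log.info("eye %s: spot %d outside volume footprint, excluded",
                     eye_id, sid)
            continue
        if hit:
            n_base += 1
            records.append(SpotSRFIntersection(eye_id, sid, -1, s, c, True))
        else:
            active.append((sid, p))

    by_interval: dict[int, list] = {}
    for v, iv in zip(visits, visit_intervals):
        by_interval.setdefault(iv, []).append(v)

    counts = np.zeros(n_intervals, int)
    active_start = np.zeros(n_intervals, int)
    for k in range(n_intervals):
        active_start[k] = len(active)
        still = []
        for sid, p in active:
            first = None
            for v in by_interval.get(k, []):
                hit, s, c = spot_overlies_srf(p, v.masks, geometry,
                                              tol_slices, tol_cols)
                if hit:
                    first = (s, c)
                    break
            if first is None:
                still.append((sid, p))
            else:
                records.append(SpotSRFIntersection(eye_id, sid, k,
                                                   first[0], first[1]))
                counts[k] += 1
        active = still
    return UniqueSpotResult(eye_id, records, counts, active_start,
                            n_base, n_oov)


def classify_eye_interval(unique_count: int, new_srf: bool) -> str:
    """Per-interval eye label from unique-spot count and new-SRF outcome."""
    if new_srf:
        return "TP" if unique_count > 0 else "FN"
    return "FP" if unique_count > 0 else "TN"


def build_confusion_matrices(timelines: list, spot_results: list,
                             n_intervals: int,
                             include_baseline_positive: bool = False
                             ) -> list:
    """One ConfusionMatrix per interval over evaluable eyes.

    Eyes SRF-positive at baseline are excluded by default (they cannot show
    "new" SRF under the first-occurrence rule).  Already-converted eyes stay
    in later matrices, classified by that interval's new-SRF flag.
    """
    matrices = [ConfusionMatrix(k) for k in range(n_intervals)]
    for tl, sr in zip(timelines, spot_results):
        if tl.baseline_srf and not include_baseline_positive:
            continue
        for k in range(n_intervals):
            label = classify_eye_interval(int(sr.counts[k]),
                                          tl.intervals[k].new_srf)
            matrices[k].add(label)
            tl.intervals[k].unique_spot_count = int(sr.counts[k])
    return matrices


def confusion_metrics(m: ConfusionMatrix) -> PredictiveMetrics:
    """PPV, NPV, sensitivity, specificity; zero denominators give NaN."""
    def ratio(num, den):
        return num / den if den > 0 else float("nan")
    return PredictiveMetrics(
        ppv=ratio(m.tp, m.tp + m.fp),
        npv=ratio(m.tn, m.tn + m.fn),
        sensitivity=ratio(m.tp, m.tp + m.fn),
        specificity=ratio(m.tn, m.tn + m.fp),
    )


@dataclass
class SurvivalCurve:
    """Per-interval proportion of eyes still SRF-free, split by DARC count."""

    intervals: np.ndarray
    high: np.ndarray  # DARC count > threshold
    low: np.ndarray  # DARC count <= threshold
    n_high: int
    n_low: int
    threshold: float


def srf_free_survival(timelines: list, darc_threshold: float = 5
                      ) -> SurvivalCurve:
    """Proportion of at-risk eyes not yet converted, per interval and group.

    At risk: SRF-negative at baseline.  An eye leaves the SRF-free state at
    its conversion interval and stays out (cumulative events), so both
    curves are non-increasing.  An empty group yields a NaN curve.
    """
    at_risk = [tl for tl in timelines if not tl.baseline_srf]
    n_int = max((len(tl.intervals) for tl in at_risk), default=0)
    groups = {"high": [tl for tl in at_risk if tl.darc_count > darc_threshold],
              "low": [tl for tl in at_risk if tl.darc_count <= darc_threshold]}
    props = {}
    for name, tls in groups.items():
        if not tls:
            log.warning("empty DARC group %r: survival curve undefined", name)
            props[name] = np.full(n_int, np.nan)
            continue
        curve = np.empty(n_int)
        for k in range(n_int):
            events = sum(1 for tl in tls
                         if tl.conversion_interval is not None
                         and tl.conversion_interval <= k)
            curve[k] = 1.0 - events / len(tls)
        props[name] = curve
    return SurvivalCurve(np.arange(n_int), props["high"], props["low"],
                         len(groups["high"]), len(groups["low"]),
                         darc_threshold)


@dataclass(frozen=True)
class GroupComparison:
    wilcoxon_w: float
    wilcoxon_p: float
    wilcoxon_defined: bool
    regression: dstats.RegressionComparison


def compare_groups(curve: SurvivalCurve) -> GroupComparison:
    """Paired per-interval comparison of the two SRF-free curves.

    Wilcoxon signed-rank on the paired proportions (p = 1 when the curves
    are identical: no nonzero differences) plus per-group linear regressions
    of proportion on interval with a pooled slope-difference test.
    """
    if curve.intervals.size < 2:
        raise ValueError("need >= 2 intervals to compare groups")
    diffs = curve.high - curve.low
    try:
        w, p = dstats.wilcoxon_signed_rank(diffs)
        defined = True
    except ValueError:
        w, p, defined = 0.0, 1.0, False
    reg = dstats.linreg_compare(curve.intervals, curve.high,
                                curve.intervals, curve.low)
    return GroupComparison(w, p, defined, reg)


@dataclass
class AssociationResult:
    interval: int
    n: int
    spearman_r: float
    mannwhitney_u: float
    mannwhitney_p: float
    n_high: int
    n_low: int


def spot_srf_association(timelines: list, split_threshold: float = 2000.0
                         ) -> list:
    """Per-interval spot-count vs fluid-magnitude association.

    For each interval: Spearman correlation between the cumulative
    unique-spot count up to that interval and the interval's accumulated
    SRF, over eyes with a scanned (non-carried) interval; plus a
    Mann-Whitney comparison of counts between high- and low-SRF eyes split
    at ``split_threshold`` pixels.  Intervals with fewer than 3 evaluable
    eyes, or all-tied input, are reported with NaN statistics.
    """
    n_int = max((len(tl.intervals) for tl in timelines), default=0)
    out: list[AssociationResult] = []
    for k in range(n_int):
        counts, srf = [], []
        for tl in timelines:
            iv = tl.intervals[k]
            if iv.carried_forward or np.isnan(iv.accumulated_srf):
                continue
            cum = sum(tl.intervals[j].unique_spot_count for j in range(k + 1))
            counts.append(cum)
            srf.append(iv.accumulated_srf)
        counts = np.asarray(counts, float)
        srf = np.asarray(srf, float)
        if counts.size < 3:
            out.append(AssociationResult(k, counts.size, float("nan"),
                                         float("nan"), float("nan"), 0, 0))
            continue
        r = dstats.spearman(counts, srf)
        hi = counts[srf > split_threshold]
        lo = counts[srf <= split_threshold]
        if hi.size and lo.size:
            u, p = dstats.mann_whitney(hi, lo)
        else:
            u, p = float("nan"), float("nan")
        out.append(AssociationResult(k, counts.size, r, u, p,
                                     hi.size, lo.size))
    return out
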