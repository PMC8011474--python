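"""Spot detection on en-face fundus images.

A classical matched-filter detector: candidate spots are local maxima of the
normalized cross-correlation between the image and a Gaussian template,
thresholded and de-duplicated by greedy non-maximum suppression (NMS).
Baseline-autofluorescent spots (present before the fluorescent marker is
injected) are removed by proximity matching so that the reported DARC count
reflects marker-positive cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage.feature import match_template, peak_local_max


@dataclass(frozen=True)
class DetectorConfig:
    template_sigma: float = 2.0  # px; Gaussian template scale
    threshold: float = 0.5  # normalized correlation in (-1, 1)
    nms_radius: float = 5.0  # px; min distance between accepted spots
    min_area: int = 1  # px; connected correlation area around a peak
    max_area: int = 10_000
    baseline_match_radius: float = 3.0  # px; baseline-subtraction proximity

    def __post_init__(self):
        if not (-1.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (-1, 1), got {self.threshold}")
        if self.nms_radius <= 0:
            raise ValueError("nms_radius must be positive")
        if self.template_sigma <= 0:
            raise ValueError("template_sigma must be positive")


@dataclass
class SpotSet:
    """Detected spots in fundus pixel coordinates (0-based, x=col, y=row)."""

    x: np.ndarray
    y: np.ndarray
    score: np.ndarray
    accepted: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, float).ravel()
        self.y = np.asarray(self.y, float).ravel()
        self.score = np.asarray(self.score, float).ravel()
        self.accepted = np.asarray(self.accepted, bool).ravel()
        n = self.x.size
        if not (self.y.size == self.score.size == self.accepted.size == n):
            raise ValueError("spot fields must have equal length")

    def __len__(self) -> int:
        return int(self.x.size)

    @classmethod
    def empty(cls) -> "SpotSet":
        z = np.empty(0)
        return cls(z, z.copy(), z.copy(), np.empty(0, bool))

    @classmethod
    def from_points(cls, points, score=1.0) -> "SpotSet":
        pts = np.atleast_2d(np.asarray(points, float))
        if pts.size == 0:
            return cls.empty()
        scores = np.broadcast_to(np.asarray(score, float), (pts.shape[0],))
        return cls(pts[:, 0], pts[:, 1], scores.copy(),
                   np.ones(pts.shape[0], bool))

    def points(self, accepted_only: bool = True) -> np.ndarray:
        keep = self.accepted if accepted_only else np.ones(len(self), bool)
        return np.column_stack([self.x[keep], self.y[keep]])

    def select(self, mask: np.ndarray) -> "SpotSet":
        return SpotSet(self.x[mask], self.y[mask],
                       self.score[mask], self.accepted[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y,
                             "score": self.score, "accepted": self.accepted})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpotSet":
        if len(df) == 0:
            return cls.empty()
        score = df["score"] if "score" in df else np.ones(len(df))
        acc = df["accepted"] if "accepted" in df else np.ones(len(df), bool)
        return cls(df["x"].to_numpy(), df["y"].to_numpy(),
                   np.asarray(score, float), np.asarray(acc, bool))


def gaussian_template(sigma: float) -> np.ndarray:
    """Unit-peak Gaussian blob template of half-width 3 sigma."""
    r = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    return np.exp(-(xx**2 + yy**2) / (2 * sigma**2))


def nms(candidates: SpotSet, radius: float) -> SpotSet:
    """Greedy non-maximum suppression by descending score.

    Ties in score are broken by (y, x) lexicographic order, making the
    accepted subset deterministic.  Idempotent: running NMS on its own
    output changes nothing.
    """
    n = len(candidates)
    if n == 0:
        return candidates
    order = np.lexsort((candidates.x, candidates.y, -candidates.score))
    pts = np.column_stack([candidates.x, candidates.y])
    keep = np.zeros(n, bool)
    kept_pts: list[np.ndarray] = []
    for i in order:
        if not candidates.accepted[i]:
            continue
        p = pts[i]
        if kept_pts and np.min(np.linalg.norm(np.array(kept_pts) - p, axis=1)) < radius:
            continue
        keep[i] = True
        kept_pts.append(p)
    out = SpotSet(candidates.x.copy(), candidates.y.copy(),
                  candidates.score.copy(), keep)
    return out


def detect_spots(image: np.ndarray, cfg: DetectorConfig | None = None) -> SpotSet:
    """Matched-filter spot detection.

    Normalized cross-correlation against a Gaussian template, local maxima
    above ``cfg.threshold``, optional area gating on the connected
    above-threshold correlation region, then greedy NMS.
    """
    cfg = cfg or DetectorConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    template = gaussian_template(cfg.template_sigma)
    if min(image.shape) < max(template.shape):
        raise ValueError("image smaller than the detection template")
    corr = match_template(image, template, pad_input=True)
    peaks = peak_local_max(corr, threshold_abs=cfg.threshold,
                           exclude_border=False)
    if peaks.size == 0:
        return SpotSet.empty()
    scores = corr[peaks[:, 0], peaks[:, 1]]
    cand = SpotSet(peaks[:, 1].astype(float), peaks[:, 0].astype(float),
                   scores, np.ones(len(peaks), bool))

    if cfg.min_area > 1 or cfg.max_area < corr.size:
        from scipy import ndimage
        labels, _ = ndimage.label(corr >= cfg.threshold)
        areas = np.bincount(labels.ravel())
        lab = labels[peaks[:, 0], peaks[:, 1]]
        ok = (areas[lab] >= cfg.min_area) & (areas[lab] <= cfg.max_area)
        cand = replace(cand, accepted=cand.accepted & ok)
    return nms(cand, cfg.nms_radius)


def match_spots(a: SpotSet, b: SpotSet, radius: float
                ) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Greedy one-to-one nearest-neighbor matching within ``radius``.

    Candidate pairs are taken in order of increasing distance; each spot
    participates in at most one pair.  Returns ``(pairs, unmatched_a,
    unmatched_b)`` with pairs as (index in a, index in b) over accepted spots.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pa, pb = a.points(), b.points()
    if pa.shape[0] == 0 or pb.shape[0] == 0:
        return [], np.arange(pa.shape[0]), np.arange(pb.shape[0])
    d = cdist(pa, pb)
    ia, ib = np.nonzero(d <= radius)
    order = np.lexsort((ib, ia, d[ia, ib]))
    used_a = np.zeros(pa.shape[0], bool)
    used_b = np.zeros(pb.shape[0], bool)
    pairs: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ia[k]), int(ib[k])
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((i, j))
    return pairs, np.nonzero(~used_a)[0], np.nonzero(~used_b)[0]


def subtract_baseline(darc: SpotSet, autofluorescent: SpotSet,
                      radius: float) -> SpotSet:
    """Remove DARC spots within ``radius`` of any baseline-autofluorescent spot.

    Both sets must be in the same registered frame.  Spots present before
    marker injection are not marker signal and are excluded from the count.
    """
    pa = darc.points()
    pb = autofluorescent.points()
    acc_idx = np.nonzero(darc.accepted)[0]
    if pa.shape[0] == 0 or pb.shape[0] == 0:
        return darc.select(darc.accepted)
    near = (cdist(pa, pb) <= radius).any(axis=1)
    keep_global = np.zeros(len(darc), bool)
    keep_global[acc_idx[~near]] = True
    return darc.select(keep_global)


def darc_count(spots: SpotSet) -> int:
    """Number of accepted spots (after baseline subtraction)."""
    return int(spots.accepted.sum())
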