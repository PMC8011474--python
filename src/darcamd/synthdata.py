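"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates the structure of a small wet-AMD imaging cohort:
per eye, a baseline en-face fluorescence acquisition carrying three kinds of
spots (angiogenic marker-positive, nuisance, and baseline-autofluorescent),
followed by an irregular schedule of OCT volume scans over 36 months grouped
into 6-month intervals.  Subretinal-fluid lesions are planted as axis-aligned
ellipses on the fundus plane: with probability ``association_strength`` an
angiogenic spot seeds a lesion centered on itself whose onset is at least one
interval after baseline; lesions can also arise spontaneously at random
locations, and a fraction of eyes carry fluid already at baseline.  Lesions
persist and grow once present.  Everything is reproducible from the seed, and
the planted truth (spot labels, lesion footprints, onset and conversion
intervals) is returned alongside the dataset so that every downstream stage
can be scored against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fluid import VisitRecord
from .registration import AffineTransform2D, OCTGeometry
from .spotdetect import SpotSet

SPOT_LABELS = ("angiogenic", "nuisance", "autofluorescent")


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the structure of the emulated trial: 36 months of
    follow-up in 6-month intervals, roughly two OCT scans per eye per
    interval, 50-slice volumes, and about a third of eyes fluid-positive
    already at baseline.
    """

    n_eyes: int = 29
    months_followup: int = 36
    interval_length: int = 6
    visits_per_interval_mean: float = 2.1  # scans/eye/interval (Poisson, min 1)
    slices_per_volume: int = 50
    spot_count_mean: float = 6.0  # angiogenic spots per eye (Poisson)
    nuisance_spot_mean: float = 2.0
    autofluorescent_spot_mean: float = 3.0
    association_strength: float = 0.06  # P(angiogenic spot seeds a lesion)
    spontaneous_lesion_mean: float = 0.1  # spot-independent lesions (Poisson)
    baseline_srf_fraction: float = 0.3
    image_size: tuple = (256, 256)  # (height, width) px
    spot_amplitude: float = 100.0
    spot_sigma: float = 2.0
    background_level: float = 20.0
    background_noise_sd: float = 10.0
    lesion_semiaxis_min: float = 8.0  # fundus px
    lesion_semiaxis_max: float = 25.0
    lesion_growth_per_interval: float = 0.15
    lesion_thickness_px: int = 4  # depth rows per slice in the B-scan mask
    mask_depth: int = 64
    clinical_flip_prob: float = 0.15  # clinical-vs-automated disagreement
    misalign: bool = True  # small random affine between DARC and ref frames
    render_images: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("visits_per_interval_mean", "spot_count_mean",
                     "nuisance_spot_mean", "autofluorescent_spot_mean",
                     "spontaneous_lesion_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("association_strength", "baseline_srf_fraction",
                     "clinical_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_eyes < 0:
            raise ValueError("n_eyes must be >= 0")
        if self.months_followup % self.interval_length != 0:
            raise ValueError(
                "interval_length must divide months_followup "
                f"({self.interval_length} vs {self.months_followup})")

    @property
    def n_intervals(self) -> int:
        return self.months_followup // self.interval_length


@dataclass
class Lesion:
    """Axis-aligned elliptical SRF footprint on the fundus plane.

    ``onset`` is the 0-based interval at which fluid first appears; -1 marks
    a lesion already present at baseline.  The footprint scales by
    ``1 + growth * (interval - onset)`` as it ages.
    """

    cx: float
    cy: float
    a: float  # semi-axis along x, fundus px
    b: float  # semi-axis along y
    onset: int
    kind: str  # "seeded" | "spontaneous" | "baseline"
    seed_spot: int | None = None

    def scale_at(self, interval: int, growth: float) -> float:
        return 1.0 + growth * (interval - self.onset)

    def contains(self, x: float, y: float, scale: float = 1.0) -> bool:
        return ((x - self.cx) / (self.a * scale))**2 \
            + ((y - self.cy) / (self.b * scale))**2 <= 1.0


@dataclass
class EyeTruth:
    eye_id: int
    spots: pd.DataFrame  # spot_id, x, y, label (reference frame)
    lesions: list
    baseline_srf: bool
    clinical_srf: bool
    conversion_interval: int | None
    darc_spot_count: int  # angiogenic + nuisance (autofluorescent excluded)


@dataclass
class GroundTruth:
    eyes: list

    def to_dict(self) -> dict:
        out = []
        for e in self.eyes:
            out.append({
                "eye_id": e.eye_id,
                "spots": e.spots.to_dict(orient="list"),
                "lesions": [asdict(l) for l in e.lesions],
                "baseline_srf": e.baseline_srf,
                "clinical_srf": e.clinical_srf,
                "conversion_interval": e.conversion_interval,
                "darc_spot_count": e.darc_spot_count,
            })
        return {"eyes": out}


@dataclass
class EyeData:
    """Everything the pipeline sees for one eye (no truth labels)."""

    eye_id: int
    geometry: OCTGeometry
    affine_darc_to_ref: AffineTransform2D
    fiducials_src: np.ndarray  # DARC-frame points
    fiducials_dst: np.ndarray  # reference-frame points
    darc_spots: pd.DataFrame  # x, y in the DARC (240-min) frame
    baseline_spots: pd.DataFrame  # x, y autofluorescent, reference frame
    baseline_visit: VisitRecord
    visits: list  # follow-up VisitRecords with .month set
    visit_intervals: list  # interval index per follow-up visit
    clinical_srf: bool
    darc_image: np.ndarray | None = None
    baseline_image: np.ndarray | None = None


@dataclass
class Cohort:
    config: CohortConfig
    eyes: list


def render_fundus_image(spots: SpotSet, config: CohortConfig,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Render Gaussian blobs on a noisy constant background (additive)."""
    h, w = config.image_size
    rng = rng or np.random.default_rng(config.seed)
    img = np.full((h, w), config.background_level, float)
    if config.background_noise_sd > 0:
        img += rng.normal(0.0, config.background_noise_sd, size=(h, w))
    pts = spots.points(accepted_only=False)
    for i, (x, y) in enumerate(pts):
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"spot {i} at ({x}, {y}) is outside the image")
        r = int(math.ceil(3 * config.spot_sigma))
        y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
        x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        img[y0:y1, x0:x1] += config.spot_amplitude * np.exp(
            -((xx - x)**2 + (yy - y)**2) / (2 * config.spot_sigma**2))
    return img


def default_geometry(config: CohortConfig) -> OCTGeometry:
    h, w = config.image_size
    spacing = h / config.slices_per_volume
    return OCTGeometry(n_slices=config.slices_per_volume,
                       row0=spacing / 2.0, spacing=spacing, n_cols=w)


def rasterize_lesions(lesions: list, interval: int, config: CohortConfig,
                      geometry: OCTGeometry) -> list:
    """Binary per-slice masks for all lesions active at ``interval``.

    A lesion contributes, on every slice whose fundus row intersects its
    (grown) ellipse, a block of ``lesion_thickness_px`` depth rows spanning
    the chord columns.  Deterministic; areas are exactly reproducible from
    the lesion parameters.
    """
    depth, width = config.mask_depth, geometry.n_cols
    masks = [np.zeros((depth, width), bool) for _ in range(geometry.n_slices)]
    d0 = depth // 2 - config.lesion_thickness_px // 2
    rows = geometry.slice_rows()
    for les in lesions:
        if les.onset > interval:
            continue
        s = les.scale_at(interval, config.lesion_growth_per_interval)
        a, b = les.a * s, les.b * s
        for si in range(geometry.n_slices):
            dy = (rows[si] - les.cy) / b
            if abs(dy) > 1.0:
                continue
            half = a * math.sqrt(1.0 - dy * dy)
            c0 = int(math.ceil(les.cx - half))
            c1 = int(math.floor(les.cx + half))
            c0, c1 = max(0, c0), min(width - 1, c1)
            if c1 >= c0:
                masks[si][d0:d0 + config.lesion_thickness_px, c0:c1 + 1] = True
    return masks


def generate_srf_series(lesions: list, visit_intervals: list,
                        config: CohortConfig,
                        geometry: OCTGeometry | None = None) -> list:
    """Per-visit mask stacks for a schedule of visit intervals.

    ``visit_intervals`` uses -1 for the baseline acquisition.  Masks are
    empty before every lesion's onset; footprints only grow with age, so the
    planted pixel set is non-decreasing over intervals.
    """
    geometry = geometry or default_geometry(config)
    return [rasterize_lesions(lesions, iv, config, geometry)
            for iv in visit_intervals]


def _uniform_margin(rng, n, lo_x, hi_x, lo_y, hi_y):
    if n == 0:
        return np.empty((0, 2))
    return np.column_stack([rng.uniform(lo_x, hi_x, n),
                            rng.uniform(lo_y, hi_y, n)])


def _misalignment(rng, config) -> AffineTransform2D:
    """Small random rotation+translation mapping the DARC frame to reference."""
    if not config.misalign:
        return AffineTransform2D.identity()
    h, w = config.image_size
    theta = math.radians(rng.uniform(-2.0, 2.0))
    tx, ty = rng.uniform(-5.0, 5.0, 2)
    c, s = math.cos(theta), math.sin(theta)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    # rotate about the image center, then translate
    lin = np.array([[c, -s], [s, c]])
    trans = np.array([cx, cy]) - lin @ np.array([cx, cy]) + np.array([tx, ty])
    return AffineTransform2D(np.hstack([lin, trans[:, None]]))


def _generate_eye(eye_id: int, config: CohortConfig,
                  rng: np.random.Generator) -> tuple[EyeData, EyeTruth]:
    h, w = config.image_size
    n_int = config.n_intervals
    geometry = default_geometry(config)

    # keep lesion footprints inside the image at their largest extent
    max_scale = 1.0 + config.lesion_growth_per_interval * n_int
    margin = config.lesion_semiaxis_max * max_scale
    margin = min(margin, (min(h, w) - 1) / 2.0 - 1)
    spot_margin = 3 * config.spot_sigma + 1

    n_ang = rng.poisson(config.spot_count_mean)
    n_nui = rng.poisson(config.nuisance_spot_mean)
    n_auto = rng.poisson(config.autofluorescent_spot_mean)
    ang = _uniform_margin(rng, n_ang, margin, w - 1 - margin,
                          margin, h - 1 - margin)
    nui = _uniform_margin(rng, n_nui, spot_margin, w - 1 - spot_margin,
                          spot_margin, h - 1 - spot_margin)
    auto = _uniform_margin(rng, n_auto, spot_margin, w - 1 - spot_margin,
                           spot_margin, h - 1 - spot_margin)
    spots = pd.DataFrame({
        "spot_id": np.arange(n_ang + n_nui + n_auto),
        "x": np.concatenate([ang[:, 0], nui[:, 0], auto[:, 0]]),
        "y": np.concatenate([ang[:, 1], nui[:, 1], auto[:, 1]]),
        "label": (["angiogenic"] * n_ang + ["nuisance"] * n_nui
                  + ["autofluorescent"] * n_auto),
    })

    lesions: list[Lesion] = []
    # angiogenic seeding: all of an eye's seeded lesions share one onset
    # interval (>= 1: the marker signal precedes leakage)
    seeded = rng.random(n_ang) < config.association_strength
    if seeded.any() and n_int >= 2:
        onset = int(rng.integers(1, n_int))
        for sid in np.nonzero(seeded)[0]:
            a = rng.uniform(config.lesion_semiaxis_min,
                            config.lesion_semiaxis_max)
            b = rng.uniform(config.lesion_semiaxis_min,
                            config.lesion_semiaxis_max)
            lesions.append(Lesion(float(ang[sid, 0]), float(ang[sid, 1]),
                                  a, b, onset, "seeded", int(sid)))
    # spontaneous lesions, independent of spot placement
    for _ in range(rng.poisson(config.spontaneous_lesion_mean)):
        cx = rng.uniform(margin, w - 1 - margin)
        cy = rng.uniform(margin, h - 1 - margin)
        a = rng.uniform(config.lesion_semiaxis_min, config.lesion_semiaxis_max)
        b = rng.uniform(config.lesion_semiaxis_min, config.lesion_semiaxis_max)
        lesions.append(Lesion(cx, cy, a, b, int(rng.integers(0, n_int)),
                              "spontaneous", None))
    baseline_srf = bool(rng.random() < config.baseline_srf_fraction)
    if baseline_srf:
        cx = rng.uniform(margin, w - 1 - margin)
        cy = rng.uniform(margin, h - 1 - margin)
        a = rng.uniform(config.lesion_semiaxis_min, config.lesion_semiaxis_max)
        b = rng.uniform(config.lesion_semiaxis_min, config.lesion_semiaxis_max)
        lesions.append(Lesion(cx, cy, a, b, -1, "baseline", None))

    if baseline_srf:
        conversion = None
    else:
        onsets = [l.onset for l in lesions]
        conversion = min(onsets) if onsets else None
    clinical = baseline_srf ^ bool(rng.random() < config.clinical_flip_prob)

    # visit schedule: baseline at month 0, then >=1 scan per interval
    visit_intervals: list[int] = []
    months: list[float] = []
    for k in range(n_int):
        n_vis = max(1, int(rng.poisson(config.visits_per_interval_mean)))
        mk = np.sort(rng.uniform(k * config.interval_length,
                                 (k + 1) * config.interval_length, n_vis))
        months.extend(float(m) for m in mk)
        visit_intervals.extend([k] * n_vis)

    baseline_masks = rasterize_lesions(lesions, -1, config, geometry)
    visits = [VisitRecord(eye_id, m,
                          rasterize_lesions(lesions, iv, config, geometry))
              for m, iv in zip(months, visit_intervals)]
    baseline_visit = VisitRecord(eye_id, 0.0, baseline_masks)

    affine = _misalignment(rng, config)
    inv = affine.inverse()
    darc_ref = spots[["x", "y"]].to_numpy()  # all three kinds fluoresce late
    darc_frame = inv.apply(darc_ref) if len(darc_ref) else darc_ref
    fid_dst = np.array([[20.0, 20.0], [w - 21.0, 25.0],
                        [25.0, h - 21.0], [w - 26.0, h - 26.0]])
    fid_src = inv.apply(fid_dst)

    eye = EyeData(
        eye_id=eye_id, geometry=geometry, affine_darc_to_ref=affine,
        fiducials_src=fid_src, fiducials_dst=fid_dst,
        darc_spots=pd.DataFrame({"x": darc_frame[:, 0] if len(darc_frame) else [],
                                 "y": darc_frame[:, 1] if len(darc_frame) else []}),
        baseline_spots=pd.DataFrame({"x": auto[:, 0], "y": auto[:, 1]}),
        baseline_visit=baseline_visit, visits=visits,
        visit_intervals=visit_intervals, clinical_srf=clinical)
    if config.render_images:
        eye.baseline_image = render_fundus_image(
            SpotSet.from_points(auto), config, rng)
        eye.darc_image = render_fundus_image(
            SpotSet.from_points(darc_frame), config, rng)

    truth = EyeTruth(eye_id, spots, lesions, baseline_srf, clinical,
                     conversion, n_ang + n_nui)
    return eye, truth


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a synthetic cohort and its planted ground truth.

    Fully determined by ``config.seed`` (per-eye independent substreams), so
    the same configuration always reproduces the same dataset byte for byte.
    """
    ss = np.random.SeedSequence(config.seed)
    eyes, truths = [], []
    for eye_id, child in enumerate(ss.spawn(config.n_eyes)):
        rng = np.random.default_rng(child)
        eye, truth = _generate_eye(eye_id, config, rng)
        eyes.append(eye)
        truths.append(truth)
    return Cohort(config, eyes), GroundTruth(truths)


# ---------------------------------------------------------------------------
# on-disk schemas (visits.csv, spots.csv, geometry.json, truth.json, masks)


def write_cohort(cohort: Cohort, truth: GroundTruth, outdir,
                 write_masks: bool = False) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    visit_rows, spot_rows = [], []
    for eye in cohort.eyes:
        visit_rows.append({"eye_id": eye.eye_id, "month": 0.0,
                           "interval": -1,
                           "n_slices": eye.baseline_visit.n_slices})
        for v, iv in zip(eye.visits, eye.visit_intervals):
            visit_rows.append({"eye_id": eye.eye_id, "month": v.month,
                               "interval": iv, "n_slices": v.n_slices})
        for _, r in eye.darc_spots.iterrows():
            spot_rows.append({"eye_id": eye.eye_id, "image": "darc",
                              "x": r.x, "y": r.y, "label": ""})
        for _, r in eye.baseline_spots.iterrows():
            spot_rows.append({"eye_id": eye.eye_id, "image": "baseline",
                              "x": r.x, "y": r.y, "label": "autofluorescent"})
        np.savetxt(out / f"fiducials_eye{eye.eye_id}.csv",
                   np.hstack([eye.fiducials_src, eye.fiducials_dst]),
                   delimiter=",", header="x_src,y_src,x_dst,y_dst", comments="")
        if write_masks:
            import tifffile
            tifffile.imwrite(
                out / f"masks_eye{eye.eye_id}_baseline.tif",
                np.stack(eye.baseline_visit.masks).astype(np.uint8))
            for i, v in enumerate(eye.visits):
                tifffile.imwrite(out / f"masks_eye{eye.eye_id}_visit{i}.tif",
                                 np.stack(v.masks).astype(np.uint8))
    pd.DataFrame(visit_rows).to_csv(out / "visits.csv", index=False)
    pd.DataFrame(spot_rows).to_csv(out / "spots.csv", index=False)
    geom = (cohort.eyes[0].geometry.to_dict() if cohort.eyes
            else default_geometry(cohort.config).to_dict())
    (out / "geometry.json").write_text(json.dumps(geom, indent=2))
    (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2,
                                               default=float))
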