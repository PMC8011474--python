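"""End-to-end orchestration: simulate/load -> register -> detect -> quantify
-> predict -> statistics, with reproducible configuration and CSV/JSON
outputs.

The pipeline consumes either a synthetic cohort (see
:mod:`darcamd.synthdata`) or on-disk tables/masks in the same schemas, and
writes per-eye timelines, per-interval confusion matrices and predictive
metrics, SRF-free survival curves with group tests, spot-fluid association
statistics, and a run manifest.  Identical configuration and seed produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import predict as dpredict
from . import stats as dstats
from .fluid import EyeTimeline, build_timeline, conversion_rate
from .registration import fit_affine
from .spotdetect import (DetectorConfig, SpotSet, darc_count, detect_spots,
                         subtract_baseline)
from .synthdata import Cohort, CohortConfig, GroundTruth, generate_cohort

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Single configuration object for a pipeline run.

    Either ``input_dir`` (on-disk cohort) or ``synth`` must be provided.
    All analysis thresholds are surfaced here: the DARC-count split (5), the
    high/low SRF split (2000 px), the 6-month interval length (inside the
    cohort config), the overlap tolerance and the detector settings.
    """

    synth: CohortConfig | None = None
    input_dir: str | None = None
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    use_detector: bool = False  # detect on rendered images vs spot tables
    srf_min_pixels: float = 0.0
    darc_count_threshold: float = 5.0
    srf_split_threshold: float = 2000.0
    overlap_tol_slices: int = 1
    overlap_tol_cols: int = 10
    include_baseline_positive: bool = False
    allow_recurrence: bool = False
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.synth is None and self.input_dir is None:
            raise ValueError("provide either synth config or input_dir")
        for name in ("darc_count_threshold", "srf_split_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "synth" in kwargs and kwargs["synth"] is not None:
            synth = dict(kwargs["synth"])
            if "image_size" in synth:
                synth["image_size"] = tuple(synth["image_size"])
            kwargs["synth"] = CohortConfig(**synth)
        if "detector" in kwargs and kwargs["detector"] is not None:
            kwargs["detector"] = DetectorConfig(**dict(kwargs["detector"]))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    config: RunConfig
    timelines: list
    spot_results: list
    matrices: list
    table1: pd.DataFrame
    survival: dpredict.SurvivalCurve
    comparison: dpredict.GroupComparison | None
    association: list
    kappa: float
    agreement: dstats.AgreementTable | None
    skipped_eyes: list
    manifest: dict

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "table1": self.table1.to_dict(orient="records"),
            "survival": {
                "intervals": self.survival.intervals.tolist(),
                "high": self.survival.high.tolist(),
                "low": self.survival.low.tolist(),
                "n_high": self.survival.n_high,
                "n_low": self.survival.n_low,
            },
            "comparison": None if self.comparison is None else {
                "wilcoxon_w": self.comparison.wilcoxon_w,
                "wilcoxon_p": self.comparison.wilcoxon_p,
                "wilcoxon_defined": self.comparison.wilcoxon_defined,
                "slope_high": self.comparison.regression.slope_a,
                "slope_low": self.comparison.regression.slope_b,
                "r2_high": self.comparison.regression.r2_a,
                "r2_low": self.comparison.regression.r2_b,
                "slope_diff_p": self.comparison.regression.slope_diff_p,
            },
            "association": [dataclasses.asdict(a) for a in self.association],
            "kappa_clinical_vs_automated": self.kappa,
            "skipped_eyes": self.skipped_eyes,
        }


def _eye_spot_points(eye, cfg: RunConfig) -> tuple[np.ndarray, int]:
    """Registered, baseline-subtracted spot coordinates + DARC count."""
    affine = fit_affine(eye.fiducials_src, eye.fiducials_dst)
    if cfg.use_detector and eye.darc_image is not None:
        darc = detect_spots(eye.darc_image, cfg.detector)
        base = detect_spots(eye.baseline_image, cfg.detector)
        base_pts = base.points()
    else:
        darc = SpotSet.from_points(eye.darc_spots[["x", "y"]].to_numpy())
        base_pts = eye.baseline_spots[["x", "y"]].to_numpy()
    darc_ref = SpotSet.from_points(
        affine.apply(darc.points()) if len(darc) else np.empty((0, 2)),
        score=1.0)
    base_set = SpotSet.from_points(base_pts) if len(base_pts) else SpotSet.empty()
    kept = subtract_baseline(darc_ref, base_set,
                             cfg.detector.baseline_match_radius)
    return kept.points(), darc_count(kept)


def run_pipeline(cfg: RunConfig, cohort: Cohort | None = None,
                 truth: GroundTruth | None = None) -> PipelineReport:
    """Execute the full analysis and (optionally) write the report bundle."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    if cohort is None:
        if cfg.synth is not None:
            synth = cfg.synth
            if cfg.seed != synth.seed:
                synth = dataclasses.replace(synth, seed=cfg.seed)
            cohort, truth = generate_cohort(synth)
        else:
            cohort, truth = load_cohort(cfg.input_dir)
    n_int = cohort.config.n_intervals
    if not cohort.eyes:
        raise ValueError("empty cohort: nothing to analyze")

    timelines: list[EyeTimeline] = []
    spot_results = []
    clinical, automated = [], []
    skipped = []
    for eye in cohort.eyes:
        try:
            pts, count = _eye_spot_points(eye, cfg)
            from .fluid import visit_srf_amount
            baseline_srf = visit_srf_amount(eye.baseline_visit) > cfg.srf_min_pixels
            by_interval: dict[int, list] = {}
            for v, iv in zip(eye.visits, eye.visit_intervals):
                by_interval.setdefault(iv, []).append(v)
            tl = build_timeline(eye.eye_id, baseline_srf, by_interval, n_int,
                                cfg.srf_min_pixels, cfg.allow_recurrence)
            tl.darc_count = count
            sr = dpredict.unique_spots(
                eye.eye_id, pts, eye.visits, eye.visit_intervals,
                eye.baseline_visit.masks, eye.geometry, n_int,
                cfg.overlap_tol_slices, cfg.overlap_tol_cols)
        except Exception as exc:  # per-eye skip, hard-fail only on empty cohort
            log.warning("eye %s skipped: %s", eye.eye_id, exc)
            skipped.append({"eye_id": eye.eye_id, "reason": str(exc)})
            continue
        timelines.append(tl)
        spot_results.append(sr)
        clinical.append(bool(eye.clinical_srf))
        automated.append(bool(baseline_srf))
    if not timelines:
        raise ValueError("no eye could be analyzed")

    matrices = dpredict.build_confusion_matrices(
        timelines, spot_results, n_int, cfg.include_baseline_positive)
    rows = []
    for m in matrices:
        pm = dpredict.confusion_metrics(m)
        rows.append({
            "interval": m.interval,
            "months": (m.interval + 1) * cohort.config.interval_length,
            "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
            "ppv": pm.ppv, "specificity": pm.specificity,
            "sensitivity": pm.sensitivity, "npv": pm.npv,
            "ppv_pct": round(100 * pm.ppv) if np.isfinite(pm.ppv) else np.nan,
            "specificity_pct": round(100 * pm.specificity)
                if np.isfinite(pm.specificity) else np.nan,
            "sensitivity_pct": round(100 * pm.sensitivity)
                if np.isfinite(pm.sensitivity) else np.nan,
            "npv_pct": round(100 * pm.npv) if np.isfinite(pm.npv) else np.nan,
            "conversion_rate": conversion_rate(timelines, m.interval),
        })
    table1 = pd.DataFrame(rows)

    survival = dpredict.srf_free_survival(timelines, cfg.darc_count_threshold)
    comparison = None
    if (np.isfinite(survival.high).all() and np.isfinite(survival.low).all()
            and survival.intervals.size >= 3):
        comparison = dpredict.compare_groups(survival)
    association = dpredict.spot_srf_association(timelines,
                                                cfg.srf_split_threshold)

    agreement = None
    kappa = float("nan")
    if clinical:
        agreement = dstats.AgreementTable.from_labels(clinical, automated)
        kappa = dstats.cohens_kappa(agreement)

    import darcamd
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": darcamd.__version__,
        "n_eyes": len(timelines),
        "n_intervals": n_int,
        "thresholds": {
            "darc_count": cfg.darc_count_threshold,
            "srf_split_px": cfg.srf_split_threshold,
            "srf_min_pixels": cfg.srf_min_pixels,
            "overlap_tol_slices": cfg.overlap_tol_slices,
            "overlap_tol_cols": cfg.overlap_tol_cols,
            "interval_months": cohort.config.interval_length,
        },
    }
    report = PipelineReport(cfg, timelines, spot_results, matrices, table1,
                            survival, comparison, association, kappa,
                            agreement, skipped, manifest)
    if cfg.outdir:
        write_report(report, cfg.outdir)
    return report


def write_report(report: PipelineReport, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tl_rows = []
    for tl in report.timelines:
        for iv in tl.intervals:
            tl_rows.append({
                "eye_id": tl.eye_id, "interval": iv.index,
                "n_scans": iv.n_scans, "accum_srf_px": iv.accumulated_srf,
                "srf_pos": iv.srf_pos, "new_srf": iv.new_srf,
                "carried_forward": iv.carried_forward,
                "unique_spots": iv.unique_spot_count,
                "darc_count": tl.darc_count,
                "baseline_srf": tl.baseline_srf,
            })
    pd.DataFrame(tl_rows).to_csv(out / "timelines.csv", index=False)
    report.table1.to_csv(out / "table1.csv", index=False)
    pd.DataFrame([{"interval": m.interval, "tp": m.tp, "fp": m.fp,
                   "fn": m.fn, "tn": m.tn} for m in report.matrices]
                 ).to_csv(out / "confusion.csv", index=False)
    pd.DataFrame({"interval": report.survival.intervals,
                  "srf_free_high": report.survival.high,
                  "srf_free_low": report.survival.low}
                 ).to_csv(out / "survival.csv", index=False)
    pd.DataFrame([dataclasses.asdict(a) for a in report.association]
                 ).to_csv(out / "association.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, default=_json_default))
    (out / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


# ---------------------------------------------------------------------------
# on-disk loading and validation


def load_cohort(indir) -> tuple[Cohort, GroundTruth | None]:
    """Load a cohort from the schemas written by :func:`synthdata.write_cohort`.

    Requires visits.csv, spots.csv, geometry.json, per-eye fiducial CSVs and
    per-eye multi-page TIFF mask stacks.
    """
    import tifffile

    from .fluid import VisitRecord
    from .registration import AffineTransform2D, OCTGeometry
    from .synthdata import EyeData

    indir = Path(indir)
    visits = pd.read_csv(indir / "visits.csv")
    spots = pd.read_csv(indir / "spots.csv")
    geom = OCTGeometry.from_dict(json.loads((indir / "geometry.json").read_text()))
    eyes = []
    months = 0
    for eye_id, vdf in visits.groupby("eye_id"):
        fid = np.loadtxt(indir / f"fiducials_eye{eye_id}.csv",
                         delimiter=",", skiprows=1, ndmin=2)
        base_stack = tifffile.imread(indir / f"masks_eye{eye_id}_baseline.tif")
        base = VisitRecord(int(eye_id), 0.0, [m > 0 for m in base_stack])
        follow = vdf[vdf["interval"] >= 0].reset_index(drop=True)
        vrecs, ivs = [], []
        for i, row in follow.iterrows():
            stack = tifffile.imread(indir / f"masks_eye{eye_id}_visit{i}.tif")
            vrecs.append(VisitRecord(int(eye_id), float(row["month"]),
                                     [m > 0 for m in stack]))
            ivs.append(int(row["interval"]))
        months = max(months, (max(ivs) + 1) * 6 if ivs else 0)
        sdf = spots[spots["eye_id"] == eye_id]
        eyes.append(EyeData(
            eye_id=int(eye_id), geometry=geom,
            affine_darc_to_ref=AffineTransform2D.identity(),
            fiducials_src=fid[:, :2], fiducials_dst=fid[:, 2:],
            darc_spots=sdf[sdf["image"] == "darc"][["x", "y"]],
            baseline_spots=sdf[sdf["image"] == "baseline"][["x", "y"]],
            baseline_visit=base, visits=vrecs, visit_intervals=ivs,
            clinical_srf=False))
    n_int = max(1, months // 6)
    config = CohortConfig(n_eyes=len(eyes), months_followup=n_int * 6,
                          interval_length=6)
    return Cohort(config, eyes), None


def validate_inputs(indir) -> list[dict]:
    """Schema check of an on-disk cohort; returns findings, never raises."""
    findings: list[dict] = []
    indir = Path(indir)

    def finding(file, row, column, message):
        findings.append({"file": str(file), "row": row,
                         "column": column, "message": message})

    vpath = indir / "visits.csv"
    if not vpath.exists():
        finding("visits.csv", None, None, "missing file")
    else:
        try:
            visits = pd.read_csv(vpath)
            if len(visits) == 0:
                finding("visits.csv", None, None, "no visits")
            for col in ("eye_id", "month", "interval", "n_slices"):
                if col not in visits.columns:
                    finding("visits.csv", None, col, "missing column")
            if "n_slices" in visits.columns:
                for i in visits.index[visits["n_slices"] <= 0]:
                    finding("visits.csv", int(i), "n_slices",
                            "non-positive slice count")
        except Exception as exc:
            finding("visits.csv", None, None, f"unreadable: {exc}")

    spath = indir / "spots.csv"
    if spath.exists():
        try:
            spots = pd.read_csv(spath)
            for col in ("eye_id", "image", "x", "y"):
                if col not in spots.columns:
                    finding("spots.csv", None, col, "missing column")
            for col in ("x", "y"):
                if col in spots.columns:
                    for i in spots.index[spots[col] < 0]:
                        finding("spots.csv", int(i), col,
                                "negative coordinate")
        except Exception as exc:
            finding("spots.csv", None, None, f"unreadable: {exc}")
    else:
        finding("spots.csv", None, None, "missing file")

    gpath = indir / "geometry.json"
    if gpath.exists():
        try:
            from .registration import OCTGeometry
            OCTGeometry.from_dict(json.loads(gpath.read_text()))
        except Exception as exc:
            finding("geometry.json", None, None, f"invalid geometry: {exc}")
    else:
        finding("geometry.json", None, None, "missing file")
    return findings
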