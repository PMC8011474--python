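import math

import numpy as np
import pytest

from conftest import tiny
from darcamd.fluid import EyeTimeline, IntervalSummary, VisitRecord
from darcamd.predict import (ConfusionMatrix, build_confusion_matrices,
                             classify_eye_interval, compare_groups,
                             confusion_metrics, spot_overlies_srf,
                             spot_srf_association, srf_free_survival,
                             unique_spots)
from darcamd.registration import OCTGeometry
from darcamd.synthdata import (Lesion, default_geometry, generate_cohort,
                               rasterize_lesions)

GEOM = OCTGeometry(n_slices=25, row0=2.56, spacing=5.12, n_cols=128)


def blank_masks(n=25, depth=32, width=128):
    return [np.zeros((depth, width), bool) for _ in range(n)]


def masks_with_block(slices, c0, c1, n=25, depth=32, width=128):
    masks = blank_masks(n, depth, width)
    for s in slices:
        masks[s][10:14, c0:c1 + 1] = True
    return masks


def timeline(statuses, baseline=False, eye_id=0, darc=0):
    ivs = [IntervalSummary(k, 1, 10.0 if s else 0.0, s)
           for k, s in enumerate(statuses)]
    tl = EyeTimeline(eye_id, baseline, ivs, darc_count=darc)
    from darcamd.fluid import detect_conversion
    tl.conversion_interval = detect_conversion(tl)
    return tl


class TestSpotOverliesSrf:
    def test_spot_inside_large_region_zero_tolerance(self):
        masks = masks_with_block(range(8, 14), 30, 90)
        hit, s, c = spot_overlies_srf((60.0, 55.0), masks, GEOM, 0, 0)
        assert hit

    def test_all_masks_empty(self):
        hit, *_ = spot_overlies_srf((60.0, 55.0), blank_masks(), GEOM)
        assert not hit

    def test_matches_brute_force_window_search(self, rng):
        masks = masks_with_block([5, 6, 12], 40, 55)
        rows = GEOM.slice_rows()
        tol_s, tol_c = 1, 10
        for _ in range(100):
            x = rng.uniform(0, 127)
            y = rng.uniform(rows[0], rows[-1])
            hit, s, c = spot_overlies_srf((x, y), masks, GEOM, tol_s, tol_c)
            # oracle: exhaustive scan of every mask pixel in the window
            d = np.abs(rows - y)
            s0 = int(np.flatnonzero(d == d.min())[0])
            c0 = int(np.floor(x + 0.5))
            expected = any(
                masks[si][dd, cc]
                for si in range(max(0, s0 - tol_s),
                                min(GEOM.n_slices, s0 + tol_s + 1))
                for dd in range(32)
                for cc in range(max(0, c0 - tol_c), min(128, c0 + tol_c + 1)))
            assert hit == expected


class TestUniqueSpots:
    def make_visits(self, mask_seq):
        visits = [VisitRecord(0, float(k), m) for k, m in enumerate(mask_seq)]
        return visits, list(range(len(mask_seq)))

    def test_baseline_overlap_excluded_entirely(self):
        base = masks_with_block([10, 11], 50, 70)
        follow = [masks_with_block([10, 11], 40, 80) for _ in range(3)]
        visits, ivs = self.make_visits(follow)
        res = unique_spots(0, [(60.0, 55.0)], visits, ivs, base, GEOM, 3)
        assert res.n_baseline_excluded == 1
        assert res.counts.sum() == 0

    def test_first_occurrence_only(self):
        follow = [blank_masks(), blank_masks(),
                  masks_with_block([10], 50, 70),
                  masks_with_block([10], 40, 80)]
        visits, ivs = self.make_visits(follow)
        res = unique_spots(0, [(60.0, 53.0)], visits, ivs, blank_masks(),
                           GEOM, 4)
        assert list(res.counts) == [0, 0, 1, 0]

    def test_three_seeding_spots_counted_once_at_onset(self):
        cfg = tiny()
        geom = default_geometry(cfg)
        les = Lesion(64.0, 64.0, 14.0, 14.0, onset=1, kind="seeded")
        spots = [(60.0, 60.0), (64.0, 64.0), (68.0, 68.0)]
        mask_seq = [rasterize_lesions([les], k, cfg, geom) for k in range(4)]
        visits, ivs = self.make_visits(mask_seq)
        base = rasterize_lesions([les], -1, cfg, geom)
        res = unique_spots(0, spots, visits, ivs, base, geom, 4)
        assert list(res.counts) == [0, 3, 0, 0]

    def test_out_of_volume_spot_excluded_and_counted(self):
        visits, ivs = self.make_visits([blank_masks()])
        res = unique_spots(0, [(60.0, -400.0)], visits, ivs, blank_masks(),
                           GEOM, 1)
        assert res.n_out_of_volume == 1
        assert res.counts.sum() == 0


class TestClassifyEyeInterval:
    @pytest.mark.parametrize("count,new_srf,expected", [
        (3, True, "TP"), (0, True, "FN"), (2, False, "FP"), (0, False, "TN")])
    def test_quoted_mapping(self, count, new_srf, expected):
        assert classify_eye_interval(count, new_srf) == expected


class TestConfusionMetrics:
    def test_hand_counted_matrix(self):
        m = ConfusionMatrix(0, tp=5, fp=2, fn=1, tn=19)
        pm = confusion_metrics(m)
        assert pm.ppv == pytest.approx(0.714, abs=5e-4)
        assert pm.sensitivity == pytest.approx(0.833, abs=5e-4)
        assert pm.specificity == pytest.approx(0.905, abs=5e-4)
        assert pm.npv == pytest.approx(0.950, abs=5e-4)

    def test_all_tn_degenerate(self):
        pm = confusion_metrics(ConfusionMatrix(0, tn=12))
        assert pm.specificity == 1.0
        assert math.isnan(pm.sensitivity)

    def test_single_tp_degenerate(self):
        pm = confusion_metrics(ConfusionMatrix(0, tp=1))
        assert pm.ppv == 1.0 and pm.sensitivity == 1.0
        assert math.isnan(pm.specificity) and math.isnan(pm.npv)


class TestSrfFreeSurvival:
    def test_no_conversions_constant_one(self):
        tls = [timeline([False] * 6, darc=d) for d in (2, 8, 3, 9)]
        sc = srf_free_survival(tls, 5)
        assert np.all(sc.high == 1.0) and np.all(sc.low == 1.0)

    def test_hand_counted_proportions(self):
        tls = [timeline([False, True, True, True], darc=8),
               timeline([False] * 4, darc=8),
               timeline([False, False, False, True], darc=8),
               timeline([False] * 4, darc=8)]
        sc = srf_free_survival(tls, 5)
        np.testing.assert_allclose(sc.high, [1.0, 0.75, 0.75, 0.5])

    def test_baseline_positive_eyes_excluded(self):
        tls = [timeline([True] * 4, baseline=True, darc=9),
               timeline([False] * 4, darc=9)]
        sc = srf_free_survival(tls, 5)
        assert sc.n_high == 1

    def test_curves_non_increasing_on_random_cohorts(self):
        from darcamd.pipeline import RunConfig, run_pipeline
        rep = run_pipeline(RunConfig(synth=tiny(n_eyes=12), seed=3))
        for curve in (rep.survival.high, rep.survival.low):
            finite = curve[np.isfinite(curve)]
            assert np.all(np.diff(finite) <= 1e-12)


class TestCompareGroups:
    def test_identical_curves_p_one(self):
        sc = srf_free_survival([timeline([False] * 5, darc=8),
                                timeline([False] * 5, darc=2)], 5)
        res = compare_groups(sc)
        assert res.wilcoxon_p == 1.0 and not res.wilcoxon_defined

    def test_slope_signs(self):
        from darcamd.predict import SurvivalCurve
        sc = SurvivalCurve(np.arange(3), np.array([1.0, 0.5, 0.25]),
                           np.array([1.0, 1.0, 1.0]), 3, 3, 5)
        res = compare_groups(sc)
        assert res.regression.slope_a < 0
        assert res.regression.slope_b == pytest.approx(0.0)


class TestSpotSrfAssociation:
    def _timelines(self, counts, srfs):
        tls = []
        for i, (c, s) in enumerate(zip(counts, srfs)):
            iv = IntervalSummary(0, 1, s, s > 0)
            iv.unique_spot_count = c
            tls.append(EyeTimeline(i, False, [iv]))
        return tls

    def test_monotone_counts_r_one(self):
        res = spot_srf_association(
            self._timelines([1, 2, 3, 4, 5], [10, 20, 30, 40, 50.0]), 25)
        assert res[0].spearman_r == pytest.approx(1.0)

    def test_reversed_counts_r_minus_one(self):
        res = spot_srf_association(
            self._timelines([5, 4, 3, 2, 1], [10, 20, 30, 40, 50.0]), 25)
        assert res[0].spearman_r == pytest.approx(-1.0)

    def test_too_few_eyes_flagged(self):
        res = spot_srf_association(self._timelines([1, 2], [5.0, 10.0]), 7)
        assert math.isnan(res[0].spearman_r)


class TestCohortInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cells_sum_to_evaluable_eyes_and_spots_counted_once(self, seed):
        from darcamd.pipeline import RunConfig, run_pipeline
        rep = run_pipeline(RunConfig(synth=tiny(
            n_eyes=10, association_strength=0.3,
            spontaneous_lesion_mean=0.5, seed=seed), seed=seed))
        evaluable = sum(1 for tl in rep.timelines if not tl.baseline_srf)
        for m in rep.matrices:
            assert m.total == evaluable
        for sr in rep.spot_results:
            sids = [r.spot_id for r in sr.records if r.interval >= 0]
            assert len(sids) == len(set(sids))
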