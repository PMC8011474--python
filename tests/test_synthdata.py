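import dataclasses
import filecmp
import math

import numpy as np
import pytest

from conftest import tiny
from darcamd.fluid import visit_srf_amount
from darcamd.spotdetect import DetectorConfig, SpotSet, detect_spots
from darcamd.synthdata import (CohortConfig, Lesion, default_geometry,
                               generate_cohort, generate_srf_series,
                               rasterize_lesions, render_fundus_image,
                               write_cohort)


class TestConfigValidation:
    def test_negative_rate_named_in_error(self):
        with pytest.raises(ValueError, match="spot_count_mean"):
            CohortConfig(spot_count_mean=-1)

    def test_association_outside_unit_interval(self):
        with pytest.raises(ValueError, match="association_strength"):
            CohortConfig(association_strength=1.5)

    def test_interval_must_divide_followup(self):
        with pytest.raises(ValueError, match="interval_length"):
            CohortConfig(months_followup=36, interval_length=7)


class TestGenerateCohort:
    def test_zero_eyes_gives_empty_dataset(self):
        cohort, truth = generate_cohort(tiny(n_eyes=0))
        assert cohort.eyes == [] and truth.eyes == []

    def test_seed_determinism_byte_identical_outputs(self, tmp_path):
        cfg = tiny(n_eyes=4)
        for d in ("a", "b"):
            cohort, truth = generate_cohort(cfg)
            write_cohort(cohort, truth, tmp_path / d, write_masks=True)
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
        assert cmp.left_only == cmp.right_only == []
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", cmp.common_files, shallow=False)
        assert mismatch == [] and errors == []

    def test_spot_label_conservation(self):
        _, truth = generate_cohort(tiny(n_eyes=10))
        for eye in truth.eyes:
            counts = eye.spots["label"].value_counts()
            assert counts.sum() == len(eye.spots)
            assert set(counts.index) <= {"angiogenic", "nuisance",
                                         "autofluorescent"}

    def test_full_association_plants_spot_inside_every_lesion(self):
        cfg = tiny(n_eyes=30, association_strength=1.0, nuisance_spot_mean=0,
                   baseline_srf_fraction=0, spontaneous_lesion_mean=0, seed=3)
        _, truth = generate_cohort(cfg)
        converters = [e for e in truth.eyes if e.conversion_interval is not None]
        assert converters, "expected at least one converting eye"
        for eye in converters:
            ang = eye.spots[eye.spots.label == "angiogenic"]
            assert any(
                les.contains(x, y)
                for les in eye.lesions
                for x, y in zip(ang.x, ang.y))

    def test_conversion_interval_is_first_lesion_onset(self):
        _, truth = generate_cohort(tiny(n_eyes=20, seed=5))
        for eye in truth.eyes:
            if eye.baseline_srf:
                assert eye.conversion_interval is None
            elif eye.lesions:
                assert eye.conversion_interval == min(
                    l.onset for l in eye.lesions)

    def test_chance_overlap_under_zero_association(self):
        """With no planted association, the fraction of converting eyes
        whose lesion happens to cover an angiogenic spot must match the
        chance rate from an independent Monte-Carlo placement oracle."""
        cfg = tiny(n_eyes=200, association_strength=0.0,
                   spontaneous_lesion_mean=1.0, baseline_srf_fraction=0.0,
                   seed=11)
        _, truth = generate_cohort(cfg)
        hits, n_conv = 0, 0
        for eye in truth.eyes:
            if eye.conversion_interval is None:
                continue
            n_conv += 1
            ang = eye.spots[eye.spots.label == "angiogenic"]
            if any(les.contains(x, y) for les in eye.lesions
                   for x, y in zip(ang.x, ang.y)):
                hits += 1
        observed = hits / n_conv

        # brute-force oracle: resample the same placement distributions
        # directly, without the generator
        h, w = cfg.image_size
        max_scale = 1 + cfg.lesion_growth_per_interval * cfg.n_intervals
        margin = min(cfg.lesion_semiaxis_max * max_scale,
                     (min(h, w) - 1) / 2 - 1)
        rng = np.random.default_rng(999)
        trials = 4000
        chance = 0
        for _ in range(trials):
            n_les = 0
            while n_les == 0:
                n_les = rng.poisson(cfg.spontaneous_lesion_mean)
            lesions = [(rng.uniform(margin, w - 1 - margin),
                        rng.uniform(margin, h - 1 - margin),
                        rng.uniform(cfg.lesion_semiaxis_min,
                                    cfg.lesion_semiaxis_max),
                        rng.uniform(cfg.lesion_semiaxis_min,
                                    cfg.lesion_semiaxis_max))
                       for _ in range(n_les)]
            n_sp = rng.poisson(cfg.spot_count_mean)
            xs = rng.uniform(margin, w - 1 - margin, n_sp)
            ys = rng.uniform(margin, h - 1 - margin, n_sp)
            if any(((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1
                   for cx, cy, a, b in lesions for x, y in zip(xs, ys)):
                chance += 1
        expected = chance / trials
        se = math.sqrt(observed * (1 - observed) / n_conv
                       + expected * (1 - expected) / trials)
        assert abs(observed - expected) <= 3 * se + 1e-9


class TestRenderFundusImage:
    def test_empty_spotset_is_pure_background(self):
        cfg = tiny(background_level=20.0, background_noise_sd=5.0)
        img = render_fundus_image(SpotSet.empty(), cfg,
                                  np.random.default_rng(0))
        se = 5.0 / math.sqrt(img.size)
        assert abs(img.mean() - 20.0) < 3 * se

    def test_noiseless_spot_peaks_at_center(self):
        cfg = tiny(background_noise_sd=0.0, spot_amplitude=100.0,
                   background_level=20.0)
        img = render_fundus_image(SpotSet.from_points([(40.0, 60.0)]), cfg,
                                  np.random.default_rng(0))
        assert img[60, 40] == pytest.approx(120.0)
        assert np.unravel_index(img.argmax(), img.shape) == (60, 40)

    def test_out_of_bounds_spot_names_the_spot(self):
        cfg = tiny()
        with pytest.raises(ValueError, match="spot 1"):
            render_fundus_image(SpotSet.from_points([(5, 5), (999, 5)]), cfg,
                                np.random.default_rng(0))

    def test_planted_spots_recovered_by_detector(self, rng):
        # 20 spots at amplitude/noise = 10; the matched filter should
        # recover at least 18 of them within a pixel
        cfg = tiny(image_size=(256, 256), spot_amplitude=100.0,
                   background_noise_sd=10.0)
        pts = []
        while len(pts) < 20:
            p = rng.uniform(12, 243, 2)
            if all(np.hypot(*(p - q)) > 12 for q in pts):
                pts.append(p)
        pts = np.array(pts)
        img = render_fundus_image(SpotSet.from_points(pts), cfg, rng)
        det = detect_spots(img, DetectorConfig()).points()
        hits = sum(np.min(np.hypot(det[:, 0] - x, det[:, 1] - y)) <= 1.0
                   for x, y in pts) if det.size else 0
        assert hits >= 18


class TestGenerateSrfSeries:
    def test_no_lesions_all_masks_empty(self):
        cfg = tiny()
        series = generate_srf_series([], [-1, 0, 1, 2], cfg)
        assert all(not np.any(m) for masks in series for m in masks)

    def test_masks_empty_before_onset(self):
        cfg = tiny()
        les = Lesion(60.0, 60.0, 10.0, 10.0, onset=3, kind="spontaneous")
        series = generate_srf_series([les], [-1, 0, 1, 2, 3, 4], cfg)
        for masks, iv in zip(series, [-1, 0, 1, 2, 3, 4]):
            total = sum(np.count_nonzero(m) for m in masks)
            assert (total > 0) == (iv >= 3)

    def test_footprint_non_decreasing_with_age(self):
        cfg = tiny()
        les = Lesion(60.0, 60.0, 10.0, 12.0, onset=1, kind="seeded")
        geom = default_geometry(cfg)
        prev = rasterize_lesions([les], 1, cfg, geom)
        for iv in (2, 3, 4, 5):
            cur = rasterize_lesions([les], iv, cfg, geom)
            for a, b in zip(prev, cur):
                assert np.all(b[a])  # superset pixel-wise
            prev = cur

    def test_planted_single_slice_footprint_pixel_exact(self):
        # ellipse thin enough to hit one slice; chosen so the chord spans
        # 125 columns x 4 depth rows = 500 px in that slice
        cfg = tiny(image_size=(128, 256), slices_per_volume=32,
                   lesion_growth_per_interval=0.0)
        geom = default_geometry(cfg)  # spacing 4, rows at 2, 6, 10, ...
        les = Lesion(cx=128.0, cy=geom.slice_rows()[15], a=62.4, b=1.9,
                     onset=0, kind="spontaneous")
        masks = rasterize_lesions([les], 0, cfg, geom)
        counts = [np.count_nonzero(m) for m in masks]
        assert counts[15] == 500
        assert sum(counts) == 500

    def test_rasterization_matches_per_pixel_ellipse_test(self):
        cfg = tiny()
        geom = default_geometry(cfg)
        les = Lesion(60.0, 70.0, 11.0, 9.0, onset=0, kind="spontaneous")
        masks = rasterize_lesions([les], 2, cfg, geom)
        s = les.scale_at(2, cfg.lesion_growth_per_interval)
        rows = geom.slice_rows()
        d0 = cfg.mask_depth // 2 - cfg.lesion_thickness_px // 2
        for si, m in enumerate(masks):
            for c in range(geom.n_cols):
                inside = ((c - les.cx) / (les.a * s)) ** 2 \
                    + ((rows[si] - les.cy) / (les.b * s)) ** 2 <= 1
                assert m[d0, c] == inside

    def test_baseline_srf_visible_at_baseline_visit(self):
        cfg = tiny(n_eyes=20, baseline_srf_fraction=1.0, seed=2)
        cohort, truth = generate_cohort(cfg)
        for eye, t in zip(cohort.eyes, truth.eyes):
            assert t.baseline_srf
            assert visit_srf_amount(eye.baseline_visit) > 0
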