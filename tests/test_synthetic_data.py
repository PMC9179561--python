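"""Generator properties: shapes, calibration, rendering, cohorts."""

import dataclasses

import numpy as np
import pytest
from skimage.measure import label as cc_label

from microglioq import (
    CalibrationError,
    CellShapeParams,
    CohortSpec,
    GroupSpec,
    RoiPolygon,
    StainingModel,
    ValidationError,
    calibrate_retraction,
    generate_cohort,
    make_cell_mask,
    oracle_ri,
    render_scene,
)
from microglioq.synthetic_data import _mean_ri_at, populate_scene


def _mean_ri(params, n=50, ps=1.0, seed0=0):
    return float(np.mean([oracle_ri(make_cell_mask(params, ps, s)) for s in range(seed0, seed0 + n)]))


class TestMakeCellMask:
    def test_amoeboid_limit_is_near_convex(self):
        params = CellShapeParams(soma_radius_um=5.0, retraction=1.0)
        for seed in range(5):
            assert oracle_ri(make_cell_mask(params, 1.0, seed)) >= 0.95

    def test_ramified_cell_is_far_from_convex(self):
        params = CellShapeParams(n_processes=6, process_length_um=25.0, retraction=0.0)
        assert _mean_ri(params, n=20) < 0.7

    def test_bare_disk(self):
        params = CellShapeParams(n_processes=0, retraction=0.0)
        assert oracle_ri(make_cell_mask(params, 1.0, 0)) >= 0.95

    def test_masks_are_4_connected(self):
        params = CellShapeParams()
        for seed in range(20):
            pix = make_cell_mask(params, 1.0, seed)
            shifted = pix - pix.min(axis=0)
            canvas = np.zeros(shifted.max(axis=0) + 1, dtype=bool)
            canvas[shifted[:, 0], shifted[:, 1]] = True
            assert cc_label(canvas, connectivity=1).max() == 1

    def test_deterministic_given_seed(self):
        params = CellShapeParams()
        np.testing.assert_array_equal(make_cell_mask(params, 1.0, 11),
                                      make_cell_mask(params, 1.0, 11))

    def test_too_coarse_pixels_rejected(self):
        with pytest.raises(ValidationError):
            make_cell_mask(CellShapeParams(soma_radius_um=1.0), pixel_size_um=2.0, rng_state=0)

    def test_mean_ri_monotone_in_retraction(self):
        params = CellShapeParams()
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = [_mean_ri(dataclasses.replace(params, retraction=r)) for r in grid]
        assert all(b > a for a, b in zip(means, means[1:]))


class TestCalibration:
    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_retraction(0.995, CellShapeParams(), 1.0, rng_state=0)

    def test_self_consistency(self):
        base = CellShapeParams()
        seeds = list(range(40))
        measured = _mean_ri_at(0.5, base, 1.0, seeds)
        r = calibrate_retraction(measured, base, 1.0, rng_state=3, tol=0.01)
        assert abs(_mean_ri(dataclasses.replace(base, retraction=r), n=100) - measured) < 0.04

    def test_monotone_in_target(self):
        base = CellShapeParams()
        r_low = calibrate_retraction(0.55, base, 1.0, rng_state=5)
        r_high = calibrate_retraction(0.85, base, 1.0, rng_state=5)
        assert r_high > r_low


def _square_roi(lo, hi):
    return RoiPolygon(vertices=[(lo, lo), (hi, lo), (hi, hi), (lo, hi)])


class TestRenderScene:
    def test_zero_cells_pure_background(self):
        roi = _square_roi(10, 90)
        img, truth = render_scene([], [], (100, 100), 1.0, roi, rng_state=0)
        assert truth.true_count == 0
        assert truth.true_positive_fraction_pct == 0.0
        assert img.pixels.mean() > 150  # bright background

    def test_density_arithmetic(self):
        # 12 cells in a ~0.05 mm^2 ROI -> 240 cells/mm^2
        side = (0.05e6) ** 0.5  # px at 1 um/px
        roi = _square_roi(40.0, 40.0 + side)
        params = CellShapeParams(retraction=1.0)
        centroids = [(60.0 + 45 * i, 60.0 + 45 * j) for i in range(4) for j in range(3)]
        img, truth = render_scene(centroids, [params] * 12, (320, 320), 1.0, roi, rng_state=1)
        assert truth.true_count == 12
        assert truth.true_density_cells_per_mm2 == pytest.approx(240.0, rel=1e-6)

    def test_noiseless_scene_is_exactly_separable(self):
        roi = _square_roi(20, 180)
        stain = StainingModel(mu_fg=40, mu_bg=220, sigma=0.0)
        params = CellShapeParams(retraction=0.5)
        img, truth = populate_scene(6, roi, params, (200, 200), 1.0, 30.0, 2,
                                    stain=stain)
        assert set(np.unique(img.pixels)) == {40, 220}
        fg = img.pixels < 128
        union = np.zeros((200, 200), dtype=bool)
        for m in truth.cell_masks:
            union[m[:, 0], m[:, 1]] = True
        assert np.array_equal(fg, union)


class TestCohorts:
    SPEC = CohortSpec(
        groups=[GroupSpec(label=g, n_animals=2, target_density=60.0) for g in
                ("Ctrl", "1w", "3w", "5w")],
        seed=9, image_size_px=300, roi_margin_px=40,
    )

    def test_bookkeeping(self):
        res = generate_cohort(self.SPEC)
        assert len(res.scenes) == 8
        assert len(res.manifest) == 8
        assert list(res.manifest["group"].unique()) == ["Ctrl", "1w", "3w", "5w"]

    def test_bit_identical_under_same_seed(self):
        a = generate_cohort(self.SPEC)
        b = generate_cohort(self.SPEC)
        for sa, sb in zip(a.scenes, b.scenes):
            np.testing.assert_array_equal(sa.image.pixels, sb.image.pixels)
        assert a.manifest.equals(b.manifest)

    def test_ground_truth_consistency(self):
        res = generate_cohort(self.SPEC)
        sc = res.scenes[0]
        assert sc.truth.true_count == len(sc.truth.cell_masks) == len(sc.truth.cell_centroids)
        # recompute per-cell RI and the positive fraction from the emitted masks
        from microglioq import rasterize_roi, roi_area_mm2

        for m, ri in zip(sc.truth.cell_masks, sc.truth.true_ri_per_cell):
            assert oracle_ri(m) == pytest.approx(ri)
        roi_mask = rasterize_roi(sc.roi, sc.image.shape)
        union = np.zeros(sc.image.shape, dtype=bool)
        for m in sc.truth.cell_masks:
            union[m[:, 0], m[:, 1]] = True
        pct = 100.0 * (union & roi_mask.pixels).sum() / roi_mask.count()
        assert pct == pytest.approx(sc.truth.true_positive_fraction_pct)
        area = roi_area_mm2(sc.roi, 1.0)
        assert sc.truth.true_density_cells_per_mm2 == pytest.approx(sc.truth.true_count / area)

    def test_cohort_mean_ri_tracks_group_target(self):
        # Monte-Carlo check of the generator against its own design:
        # target 0.66, SD 0.04, n = 5 animals; cohort means stay within +-0.06
        devs = []
        for seed in range(20):
            spec = CohortSpec(
                groups=[GroupSpec(label="Ctrl", n_animals=5, target_density=70.0,
                                  target_mean_ri=0.66, ri_sd=0.04)],
                seed=seed, image_size_px=400, roi_margin_px=40,
            )
            res = generate_cohort(spec)
            cohort_mean = np.mean([sc.truth.true_mean_ri for sc in res.scenes])
            devs.append(cohort_mean - 0.66)
        assert np.max(np.abs(devs)) < 0.06
        assert abs(np.mean(devs)) < 0.02  # no systematic bias

    def test_group_spec_validation(self):
        with pytest.raises(ValidationError):
            GroupSpec(label="x", n_animals=1, target_density=50.0)
        with pytest.raises(ValidationError):
            GroupSpec(label="x", n_animals=5)  # no target at all
        with pytest.raises(ValidationError):
            GroupSpec(label="x", n_animals=5, target_mean_ri=1.2, target_density=50.0)
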