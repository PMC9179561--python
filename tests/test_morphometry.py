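"""Cell area, convex-hull projection area, RI, and grid sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microglioq import (
    BinaryMask,
    CellComponent,
    DetectionParams,
    GridSpec,
    ValidationError,
    analyze_cells,
    cell_area,
    grid_sample_cells,
    measure_cell,
    projection_area,
    ramification_index,
)
from conftest import random_mask
from oracles import hull_area_of_mask, shoelace_area

PLUS = np.array([[2, c] for c in range(5)] + [[r, 2] for r in range(5) if r != 2])


class TestAreas:
    def test_cell_area_scaling(self):
        pix = np.array([[r, c] for r in range(3) for c in range(3)])
        assert cell_area(pix, 1.0) == 9.0
        assert cell_area(pix, 0.5) == 2.25

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            cell_area(np.empty((0, 2)), 1.0)
        with pytest.raises(ValidationError):
            projection_area(np.empty((0, 2)), 1.0)

    def test_rectangle_hull_equals_area(self):
        pix = np.array([[r, c] for r in range(4) for c in range(7)])
        assert projection_area(pix, 1.0) == pytest.approx(cell_area(pix, 1.0))

    def test_plus_shape_worked_example(self):
        rec = measure_cell(PLUS, 1.0)
        assert rec.a_c_um2 == 9.0
        assert rec.a_p_um2 == pytest.approx(17.0)
        assert rec.ri == pytest.approx(9 / 17)

    def test_single_pixel(self):
        assert projection_area(np.array([[3, 5]]), 2.0) == pytest.approx(4.0)

    def test_one_pixel_wide_line_no_degeneracy(self):
        pix = np.array([[0, c] for c in range(10)])
        assert projection_area(pix, 1.0) == pytest.approx(10.0)
        assert measure_cell(pix, 1.0).ri == pytest.approx(1.0)

    def test_large_disk_ri_near_one(self):
        rr, cc = np.mgrid[0:101, 0:101]
        inside = (rr - 50) ** 2 + (cc - 50) ** 2 <= 50**2
        pix = np.argwhere(inside)
        assert measure_cell(pix, 1.0).ri >= 0.98

    def test_hull_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            pix = random_mask(rng)
            assert projection_area(pix, 1.0) == pytest.approx(
                hull_area_of_mask(pix), rel=1e-9)


class TestRamificationIndex:
    def test_bounds_and_errors(self):
        assert ramification_index(5.0, 5.0) == 1.0
        with pytest.raises(ValidationError):
            ramification_index(0.0, 1.0)
        with pytest.raises(ValidationError):
            ramification_index(2.0, 1.0)  # A_p < A_c flags a hull bug

    def test_ri_in_unit_interval_on_fuzzed_masks(self, rng):
        for _ in range(100):
            rec = measure_cell(random_mask(rng), 1.0)
            assert 0 < rec.ri <= 1.0 + 1e-12

    @given(s=st.floats(0.1, 10.0))
    @settings(derandomize=True, max_examples=25)
    def test_scale_equivariance(self, s):
        r1 = measure_cell(PLUS, 1.0)
        r2 = measure_cell(PLUS, s)
        assert r2.a_c_um2 == pytest.approx(r1.a_c_um2 * s**2)
        assert r2.a_p_um2 == pytest.approx(r1.a_p_um2 * s**2)
        assert r2.ri == pytest.approx(r1.ri)

    def test_rotation_invariance(self, rng):
        for _ in range(10):
            pix = random_mask(rng)
            grid = np.zeros((20, 20), dtype=bool)
            grid[pix[:, 0], pix[:, 1]] = True
            base = measure_cell(np.argwhere(grid), 1.0)
            for k in (1, 2, 3):
                rot = measure_cell(np.argwhere(np.rot90(grid, k)), 1.0)
                assert rot.a_c_um2 == pytest.approx(base.a_c_um2)
                assert rot.a_p_um2 == pytest.approx(base.a_p_um2)
                assert rot.ri == pytest.approx(base.ri)


def _cell_at(r, c, h=3, w=3):
    pix = np.array([[r + i, c + j] for i in range(h) for j in range(w)])
    return CellComponent(pixels=pix, centroid=(c + w / 2, r + h / 2))


class TestGridSampling:
    def test_spacing_one_selects_everything(self):
        cells = [_cell_at(2, 2), _cell_at(10, 10)]
        grid = GridSpec(spacing_px=1.0, offset_x=0.0, offset_y=0.0)
        assert len(grid_sample_cells(cells, grid, (20, 20))) == 2

    def test_lines_missing_all_cells(self):
        cells = [_cell_at(2, 2)]  # occupies rows/cols 2..4
        grid = GridSpec(spacing_px=50.0, offset_x=10.0, offset_y=10.0)
        assert grid_sample_cells(cells, grid, (20, 20)) == []

    def test_matches_brute_force_line_intersection(self, rng):
        # oracle: pixel [j, j+1) x [i, i+1) crosses x=c iff j <= c < j+1
        for _ in range(20):
            cells = []
            for _ in range(8):
                pix = random_mask(rng, window=40, max_pixels=20)
                cells.append(CellComponent(pixels=pix, centroid=(0.0, 0.0)))
            s = float(rng.uniform(3, 15))
            ox, oy = float(rng.uniform(0, s)), float(rng.uniform(0, s))
            grid = GridSpec(spacing_px=s, offset_x=ox, offset_y=oy)
            got = grid_sample_cells(cells, grid, (40, 40))
            vlines = [ox + k * s for k in range(100) if ox + k * s < 40]
            hlines = [oy + k * s for k in range(100) if oy + k * s < 40]
            expected = []
            for cell in cells:
                hit = False
                for r, c in cell.pixels:
                    if any(c <= v < c + 1 for v in vlines) or any(r <= h < r + 1 for h in hlines):
                        hit = True
                        break
                if hit:
                    expected.append(cell)
            assert [id(c) for c in got] == [id(c) for c in expected]

    def test_random_phase_requires_rng(self):
        with pytest.raises(ValidationError):
            grid_sample_cells([], GridSpec(spacing_px=5.0), (10, 10), rng=None)


class TestAnalyzeCells:
    def test_rectangular_cell_on_grid_line(self):
        px = np.zeros((40, 40), dtype=bool)
        px[10:20, 10:20] = True
        res = analyze_cells(
            BinaryMask(px), BinaryMask(np.ones((40, 40), dtype=bool)),
            DetectionParams(min_area_um2=1), GridSpec(spacing_px=5.0, offset_x=2.0, offset_y=2.0),
            pixel_size_um=1.0,
        )
        assert res.n_cells == 1
        assert res.records[0].ri == pytest.approx(1.0)

    def test_border_cells_excluded(self):
        px = np.zeros((30, 30), dtype=bool)
        px[0:6, 0:6] = True  # touches border
        px[12:18, 12:18] = True
        res = analyze_cells(
            BinaryMask(px), BinaryMask(np.ones((30, 30), dtype=bool)),
            DetectionParams(min_area_um2=1), GridSpec(spacing_px=1.0, offset_x=0.0, offset_y=0.0),
            pixel_size_um=1.0,
        )
        assert res.n_detected == 2
        assert res.n_border_excluded == 1
        assert res.n_cells == 1

    def test_empty_selection_is_valid(self):
        px = np.zeros((20, 20), dtype=bool)
        res = analyze_cells(
            BinaryMask(px), BinaryMask(np.ones((20, 20), dtype=bool)),
            DetectionParams(), GridSpec(spacing_px=5.0, offset_x=0.0, offset_y=0.0),
            pixel_size_um=1.0,
        )
        assert res.n_cells == 0 and np.isnan(res.mean_ri)
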