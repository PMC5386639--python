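"""Pseudo-cell grids, single-cell densities, and nuclei-region masks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smfishq.core import CellOutline, FieldOfViewMeta, ValidationError
from smfishq.scoring import (
    assign_spots_to_cells,
    case_score,
    cell_density,
    dilate_outline,
    grid_counts,
    mask_density,
    nuclei_mask,
    pseudocell_densities,
)
from conftest import spot_df


class TestGridCounts:
    def test_floor_binning(self, meta):
        spots = spot_df([("f0", "HER2", 300.0, 10.0, 0)])
        grid = grid_counts(spots, meta, 4, "HER2")
        assert grid.counts[0, 1] == 1  # row 0, column floor(300/256) = 1
        assert grid.counts.sum() == 1

    def test_conservation(self, meta, rng):
        n = 100
        spots = spot_df(
            [("f0", "HER2", x, y, 0) for x, y in zip(rng.uniform(0, 1024, n), rng.uniform(0, 1024, n))]
        )
        for g in (1, 9, 13, 16):
            assert grid_counts(spots, meta, g, "HER2").counts.sum() == n

    def test_g_one_is_identity(self, meta):
        spots = spot_df([("f0", "HER2", 5.0, 5.0, 0), ("f0", "HER2", 1000.0, 1000.0, 1)])
        grid = grid_counts(spots, meta, 1, "HER2")
        assert grid.counts.shape == (1, 1) and grid.counts[0, 0] == 2

    def test_boundary_spot_goes_to_higher_index(self, meta):
        spots = spot_df([("f0", "HER2", 256.0, 0.0, 0)])  # exactly on a 4-grid line
        grid = grid_counts(spots, meta, 4, "HER2")
        assert grid.counts[0, 1] == 1

    def test_foreign_field_rejected(self, meta):
        spots = spot_df([("other", "HER2", 5.0, 5.0, 0)])
        with pytest.raises(ValidationError):
            grid_counts(spots, meta, 13, "HER2")

    def test_channel_filtering(self, meta):
        spots = spot_df([("f0", "HER2", 5.0, 5.0, 0), ("f0", "ER", 6.0, 6.0, 0)])
        assert grid_counts(spots, meta, 13, "ER").counts.sum() == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1023.99), st.floats(0, 1023.99)), max_size=60),
           st.integers(1, 16))
    def test_conservation_property(self, pts, g):
        meta = FieldOfViewMeta(field_id="f0")
        spots = spot_df([("f0", "HER2", x, y, 0) for x, y in pts])
        assert grid_counts(spots, meta, g, "HER2").counts.sum() == len(pts)


class TestPseudoCellDensities:
    def test_stated_geometry_and_density(self, meta):
        spots = spot_df([("f0", "HER2", 1.0, 1.0, 0)] * 5)
        grid = pseudocell_densities(grid_counts(spots, meta, 13, "HER2"))
        assert grid.cell_area_um2 == pytest.approx((1024 / 13 * 0.125) ** 2, rel=1e-6)
        assert grid.cell_area_um2 == pytest.approx(96.95, abs=0.01)
        assert grid.depth_um == pytest.approx(1.6)
        assert grid.densities[0, 0] == pytest.approx(0.03224, abs=2e-5)

    def test_zero_count_zero_density(self, meta):
        grid = pseudocell_densities(grid_counts(spot_df([]), meta, 13, "HER2"))
        assert np.all(grid.densities == 0.0)

    def test_doubling_depth_halves_density(self):
        m5 = FieldOfViewMeta(field_id="f0", n_planes=5)
        m9 = FieldOfViewMeta(field_id="f0", n_planes=9)
        spots = spot_df([("f0", "HER2", 10.0, 10.0, 0)] * 4)
        d5 = pseudocell_densities(grid_counts(spots, m5, 13, "HER2")).densities
        d9 = pseudocell_densities(grid_counts(spots, m9, 13, "HER2")).densities
        np.testing.assert_allclose(d9, d5 / 2)


class TestCaseScore:
    def _grid(self, meta, counts_xy):
        spots = spot_df([("f0", "HER2", x, y, 0) for x, y in counts_xy])
        return grid_counts(spots, meta, 2, "HER2")

    def test_all_zero_threshold_zero(self, meta):
        grid = grid_counts(spot_df([]), meta, 13, "HER2")
        cs = case_score([grid], 0)
        assert cs.score == 0.0 and not cs.flagged

    def test_exclusion_policy_keeps_only_passing(self, meta):
        # counts {0, 0, 0, 4}: one pseudo-cell with 4 spots, threshold 3
        pts = [(600.0, 600.0)] * 4
        grid = self._grid(meta, pts)
        cs = case_score([grid], 3)
        vol = grid.cell_area_um2 * grid.depth_um
        assert cs.n_passing == 1
        assert cs.score == pytest.approx(4 / vol)

    def test_threshold_zero_is_plain_mean(self, meta):
        pts = [(10.0, 10.0), (600.0, 600.0), (600.0, 601.0)]
        grid = self._grid(meta, pts)
        cs = case_score([grid], 0)
        dens = pseudocell_densities(grid).densities
        assert cs.score == pytest.approx(dens.mean())

    def test_zero_policy_divides_by_all(self, meta):
        pts = [(600.0, 600.0)] * 4 + [(10.0, 10.0)]
        grid = self._grid(meta, pts)
        vol = grid.cell_area_um2 * grid.depth_um
        cs = case_score([grid], 3, policy="zero")
        assert cs.score == pytest.approx((4 / vol) / 4)

    def test_nothing_passing_is_flagged(self, meta):
        grid = grid_counts(spot_df([]), meta, 2, "HER2")
        cs = case_score([grid], 1)
        assert cs.flagged and cs.score == 0.0

    def test_no_fields_is_error(self):
        with pytest.raises(ValidationError):
            case_score([], 0)


class TestDilation:
    def test_margin_zero_identity(self, unit_square):
        assert dilate_outline(unit_square, 0).equals(unit_square.polygon)

    def test_minkowski_area_of_square(self):
        square = CellOutline(
            cell_id="s", field_id="f0",
            vertices=((100.0, 100.0), (110.0, 100.0), (110.0, 110.0), (100.0, 110.0)),
        )
        expected = 100 + 4 * 10 * 20 + math.pi * 20**2
        assert dilate_outline(square, 20).area == pytest.approx(expected, rel=1e-3)

    def test_area_strictly_increases_with_margin(self, unit_square):
        areas = [dilate_outline(unit_square, m).area for m in (0, 5, 15, 20, 25)]
        assert all(b > a for a, b in zip(areas, areas[1:]))

    def test_clipped_at_field_border(self, meta):
        corner = CellOutline(
            cell_id="c", field_id="f0",
            vertices=((0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)),
        )
        clipped = dilate_outline(corner, 20, meta)
        unclipped = dilate_outline(corner, 20)
        assert clipped.area < unclipped.area
        assert clipped.bounds[0] >= 0 and clipped.bounds[1] >= 0


class TestAssignment:
    def _two_squares(self):
        a = CellOutline(cell_id="a", field_id="f0",
                        vertices=((0.0, 0.0), (20.0, 0.0), (20.0, 20.0), (0.0, 20.0)))
        b = CellOutline(cell_id="b", field_id="f0",
                        vertices=((30.0, 0.0), (50.0, 0.0), (50.0, 20.0), (30.0, 20.0)))
        return [a, b]

    def test_unique_containment(self, meta):
        spots = spot_df([("f0", "HER2", 10.0, 10.0, 0)])
        out = assign_spots_to_cells(spots, self._two_squares(), meta, margin_px=5)
        assert list(out) == ["a"]

    def test_overlap_resolved_by_nearest_nucleus_boundary(self, meta):
        # (24, 10) is 4 px from a's boundary (x=20), 6 px from b's (x=30)
        spots = spot_df([("f0", "HER2", 24.0, 10.0, 0)])
        out = assign_spots_to_cells(spots, self._two_squares(), meta, margin_px=15)
        assert list(out) == ["a"]

    def test_stroma_spot_unassigned(self, meta):
        spots = spot_df([("f0", "HER2", 500.0, 500.0, 0)])
        out = assign_spots_to_cells(spots, self._two_squares(), meta, margin_px=15)
        assert list(out) == [""]


class TestCellDensity:
    def test_prism_formula(self, meta):
        # 100 px^2 = 1.5625 um^2; depth 1.6 um; 5 dots -> 5 / 2.5 = 2.0
        square = CellOutline(
            cell_id="s", field_id="f0",
            vertices=((100.0, 100.0), (110.0, 100.0), (110.0, 110.0), (100.0, 110.0)),
        )
        cd = cell_density({"HER2": 5}, square, meta, margin_px=0)
        assert cd.polygon_area_um2 == pytest.approx(1.5625)
        assert cd.density["HER2"] == pytest.approx(2.0)

    def test_zero_dots_zero_density(self, meta, unit_square):
        cd = cell_density({"HER2": 0}, unit_square, meta, margin_px=0)
        assert cd.density["HER2"] == 0.0

    def test_doubled_area_halves_density(self, meta):
        sq = lambda s: CellOutline(  # noqa: E731
            cell_id="s", field_id="f0",
            vertices=((100.0, 100.0), (100.0 + s, 100.0), (100.0 + s, 110.0), (100.0, 110.0)),
        )
        d1 = cell_density({"HER2": 6}, sq(10.0), meta, margin_px=0).density["HER2"]
        d2 = cell_density({"HER2": 6}, sq(20.0), meta, margin_px=0).density["HER2"]
        assert d2 == pytest.approx(d1 / 2)


class TestNucleiMask:
    def test_constant_image_gives_empty_mask(self, small_meta):
        img = np.full((100, 100), 7.0)
        rm = nuclei_mask(img, small_meta, det_threshold=1e-6)
        assert not rm.mask.any()

    def test_non_2d_input_rejected(self, small_meta):
        with pytest.raises(ValidationError):
            nuclei_mask(np.zeros((2, 10, 10)), small_meta)

    def test_intensity_scaling_homogeneity(self, small_meta, rng):
        img = rng.random((100, 100)) * 50
        rm1 = nuclei_mask(img, small_meta, det_threshold=10.0)
        c = 3.0
        rm2 = nuclei_mask(c * img, small_meta, det_threshold=10.0 * c**4)
        np.testing.assert_allclose(rm2.det, rm1.det * c**4, rtol=1e-8)
        assert np.array_equal(rm1.mask, rm2.mask)

    def test_rendered_nuclei_fixture_coverage(self):
        from skimage.draw import polygon as draw_polygon
        from smfishq.synthetic import SimulationParams, render_nuclei_image, simulate_fov

        params = SimulationParams(width_px=512, height_px=512, n_cells_mean=8, n_cells_sd=0)
        fov = simulate_fov(params, seed=11)
        dapi = render_nuclei_image(fov.outlines, fov.meta, seed=12)
        rm = nuclei_mask(dapi, fov.meta)  # automatic valley threshold
        truth = np.zeros(dapi.shape, dtype=bool)
        for o in fov.outlines:
            v = np.asarray(o.vertices)
            rr, cc = draw_polygon(v[:, 1], v[:, 0], shape=dapi.shape)
            truth[rr, cc] = True
        assert rm.mask[truth].mean() >= 0.90
        assert rm.mask[~truth].mean() <= 0.10


class TestMaskDensity:
    def test_full_field_mask_equals_field_density(self, meta, rng):
        n = 200
        spots = spot_df(
            [("f0", "HER2", x, y, 0) for x, y in zip(rng.uniform(0, 1024, n), rng.uniform(0, 1024, n))]
        )
        md = mask_density(spots, np.ones((1024, 1024), bool), meta)
        assert md.density == pytest.approx(n / meta.volume_um3)

    def test_empty_mask_flagged(self, meta):
        md = mask_density(spot_df([]), np.zeros((1024, 1024), bool), meta)
        assert md.flagged and math.isnan(md.density)

    def test_half_mask_holding_all_spots_doubles_density(self, meta, rng):
        n = 100
        spots = spot_df(
            [("f0", "HER2", x, y, 0) for x, y in zip(rng.uniform(0, 500, n), rng.uniform(0, 1024, n))]
        )
        half = np.zeros((1024, 1024), bool)
        half[:, :512] = True
        md_half = mask_density(spots, half, meta)
        md_full = mask_density(spots, np.ones((1024, 1024), bool), meta)
        assert md_half.density == pytest.approx(2 * md_full.density)
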