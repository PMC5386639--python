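"""Diversity indices, neighbor statistics, scaling, and co-expression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smfishq.core import FieldOfViewMeta
from smfishq.heterogeneity import (
    coexpression,
    distance_expression_scaling,
    diversity_dispersion,
    global_diversity,
    interregional_variability,
    local_diversity,
    neighbor_differences,
    nucleus_area_contrast,
)
from smfishq.scoring import PseudoCellGrid


def make_grid(counts, field_id="f0", side_px=1024):
    counts = np.asarray(counts, dtype=int)
    g = counts.shape[0]
    side_um = side_px / g * 0.125
    return PseudoCellGrid(
        field_id=field_id, channel="HER2", g=g, counts=counts,
        cell_side_um=side_um, cell_area_um2=side_um**2, depth_um=1.6,
        width_px=side_px, height_px=side_px, pixel_size_um=0.125,
    )


def brute_force_entropy(values):
    """Histogram + direct sum oracle for the Shannon index (bits)."""
    values = list(values)
    h = 0.0
    for level in set(values):
        p = values.count(level) / len(values)
        h -= p * math.log2(p)
    return h


class TestLocalDiversity:
    def test_two_symmetric_levels(self):
        d = local_diversity(make_grid([[3, 5], [3, 5]]), dot_threshold=3)
        assert d.n_levels == 2
        assert d.entropy_bits == pytest.approx(1.0)
        assert d.index == pytest.approx(1.0)

    def test_single_level_zero_by_convention(self):
        d = local_diversity(make_grid([[4, 4], [4, 0]]), dot_threshold=3)
        assert d.n_levels == 1 and d.entropy_bits == 0.0 and d.index == 0.0

    def test_hand_computed_three_levels(self):
        d = local_diversity(make_grid([[3, 3], [5, 7]]), dot_threshold=3)
        assert d.entropy_bits == pytest.approx(1.5)
        assert d.index == pytest.approx(1.5 / math.log2(3))

    def test_no_passing_pseudocells_flagged(self):
        d = local_diversity(make_grid([[0, 1], [2, 0]]), dot_threshold=3)
        assert d.flagged and math.isnan(d.index)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 12), min_size=4, max_size=36))
    def test_matches_brute_force_oracle(self, values):
        side = int(math.isqrt(len(values)))
        values = values[: side * side]
        if not values:
            return
        grid = make_grid(np.array(values).reshape(side, side))
        d = local_diversity(grid, dot_threshold=1)
        passing = [v for v in values if v >= 1]
        if not passing:
            assert d.flagged
            return
        assert d.entropy_bits == pytest.approx(brute_force_entropy(passing))
        assert 0.0 <= d.index <= 1.0 + 1e-12
        assert d.entropy_bits <= math.log2(max(d.n_levels, 1)) + 1e-12

    def test_shift_invariance_of_entropy(self):
        base = np.array([[3, 5, 7], [3, 9, 5], [7, 7, 3]])
        d0 = local_diversity(make_grid(base), dot_threshold=0)
        d1 = local_diversity(make_grid(base + 10), dot_threshold=0)
        assert d0.entropy_bits == pytest.approx(d1.entropy_bits)
        assert d0.index == pytest.approx(d1.index)


class TestGlobalDiversity:
    def test_identical_fields_match_local(self):
        g = make_grid([[3, 5], [3, 5]])
        gd = global_diversity([g, g], dot_threshold=3)
        ld = local_diversity(g, dot_threshold=3)
        assert gd.index == pytest.approx(ld.index)

    def test_single_field_is_identity(self):
        g = make_grid([[3, 3], [5, 7]])
        assert global_diversity([g], 3) == local_diversity(g, 3)

    def test_disjoint_single_levels_diverge(self):
        a = make_grid([[4, 4], [4, 4]])
        b = make_grid([[6, 6], [6, 6]], field_id="f1")
        assert local_diversity(a, 3).index == 0.0
        assert local_diversity(b, 3).index == 0.0
        assert global_diversity([a, b], 3).index == pytest.approx(1.0)

    def test_pooling_cannot_lose_levels(self, rng):
        grids = [make_grid(rng.integers(0, 8, (4, 4))) for _ in range(5)]
        gd = global_diversity(grids, 1)
        max_local = max(local_diversity(g, 1).n_levels for g in grids)
        assert gd.n_levels >= max_local


class TestDispersion:
    def test_identical_indices_zero_cv(self):
        d = diversity_dispersion([0.8, 0.8, 0.8])
        assert d.cv == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        d = diversity_dispersion([0.6, 1.0])
        assert d.mean == pytest.approx(0.8)
        assert d.cv == pytest.approx(0.35355, abs=1e-4)

    def test_single_field_flagged(self):
        assert diversity_dispersion([0.7]).flagged


class TestNeighborDifferences:
    def test_two_by_two_all_pairs(self):
        nd = neighbor_differences(make_grid([[3, 5], [4, 9]]), dot_threshold=3)
        assert sorted(nd.diffs.tolist()) == [1, 1, 2, 4, 5, 6]
        assert nd.mean == pytest.approx(19 / 6)

    def test_threshold_drops_pairs_with_failing_member(self):
        nd = neighbor_differences(make_grid([[3, 5], [4, 9]]), dot_threshold=4)
        assert sorted(nd.diffs.tolist()) == [1, 4, 5]

    def test_uniform_grid_all_zero(self):
        nd = neighbor_differences(make_grid(np.full((4, 4), 6)), dot_threshold=0)
        assert nd.mean == 0.0
        # 8-neighborhood pair count on a 4x4 grid: 2*(3*4) + 2*9 = 42
        assert nd.n_pairs == 42

    def test_shift_invariance(self):
        base = np.array([[3, 5, 8], [4, 9, 3], [6, 2, 7]])
        a = neighbor_differences(make_grid(base), 0)
        b = neighbor_differences(make_grid(base + 5), 0)
        assert sorted(a.diffs.tolist()) == sorted(b.diffs.tolist())


class TestScaling:
    def test_collinear_concordant_counts_give_rho_one(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0], counts[0, 1], counts[0, 2] = 3, 4, 5
        res = distance_expression_scaling([make_grid(counts)], "HER2", 3)
        assert res.rho == pytest.approx(1.0)

    def test_constant_counts_flagged(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, :] = 4
        res = distance_expression_scaling([make_grid(counts)], "HER2", 3)
        assert res.flagged

    def test_fewer_than_two_passing_everywhere_flagged(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[1, 1] = 9
        res = distance_expression_scaling([make_grid(counts)], "HER2", 3)
        assert res.flagged

    def test_segmented_cell_variant_concordant(self):
        cells = pd.DataFrame(
            {
                "field_id": ["f0"] * 3,
                "cell_id": ["a", "b", "c"],
                "centroid_x_um": [0.0, 10.0, 20.0],
                "centroid_y_um": [0.0, 0.0, 0.0],
                "count_HER2": [3, 4, 5],
                "density_HER2": [0.3, 0.4, 0.5],
            }
        )
        res = distance_expression_scaling(cells, "HER2", 0, unit="cell")
        assert res.rho == pytest.approx(1.0)
        res_d = distance_expression_scaling(cells, "HER2", 0, unit="cell", use_density=True)
        assert res_d.rho == pytest.approx(1.0)


class TestInterregional:
    def _table(self, field_means):
        rows = []
        for i, (fid, mean) in enumerate(field_means):
            rows.append({"field_id": fid, "cell_id": f"c{i}", "density_HER2": mean})
        return pd.DataFrame(rows)

    def test_equal_field_means_zero_cv(self):
        res = interregional_variability(self._table([("f0", 0.1), ("f1", 0.1)]), "HER2")
        assert res.cv == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        res = interregional_variability(self._table([("f0", 0.05), ("f1", 0.15)]), "HER2")
        assert res.cv == pytest.approx(math.sqrt(2) / 2, abs=1e-4)

    def test_cell_free_fields_reported_as_skipped(self):
        res = interregional_variability(
            self._table([("f0", 0.05), ("f1", 0.15)]), "HER2",
            field_ids=["f0", "f1", "f2"],
        )
        assert res.n_fields_skipped == 1 and not res.flagged


class TestCoexpression:
    def _table(self, dens_a, dens_b, counts_a=None, counts_b=None):
        n = len(dens_a)
        return pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "count_HER2": counts_a if counts_a is not None else [10] * n,
                "count_ER": counts_b if counts_b is not None else [10] * n,
                "density_HER2": dens_a,
                "density_ER": dens_b,
            }
        )

    def test_identical_channels_rho_one(self):
        dens = [0.1, 0.4, 0.2, 0.8, 0.05]
        res = coexpression(self._table(dens, dens), "HER2", "ER")
        assert res.rho == pytest.approx(1.0)

    def test_sub_threshold_counts_zero_the_density(self):
        table = self._table([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], counts_b=[0, 10, 10])
        res = coexpression(table, "HER2", "ER", dot_thresholds={"ER": 1})
        assert res.scatter["density_ER"].tolist() == [0.0, 0.2, 0.3]

    def test_zero_variance_undefined(self):
        res = coexpression(self._table([0.1] * 4, [0.1, 0.2, 0.3, 0.4]), "HER2", "ER")
        assert math.isnan(res.rho)


class TestNucleusAreaContrast:
    def test_identical_distributions_not_significant(self):
        areas = [60.0, 62.0, 64.0, 66.0, 68.0, 70.0] * 2
        dens = [0.5] * 6 + [0.01] * 6  # same areas in both strata
        table = pd.DataFrame(
            {"cell_id": range(12), "density_HER2": dens, "nucleus_area_um2": areas * 1}
        )
        table["nucleus_area_um2"] = areas[:6] + areas[:6]
        res = nucleus_area_contrast(table, "HER2", density_split=0.1)
        assert res.p_value >= 0.99

    def test_empty_stratum_flagged(self):
        table = pd.DataFrame(
            {"cell_id": [0, 1], "density_HER2": [0.5, 0.6], "nucleus_area_um2": [60.0, 70.0]}
        )
        res = nucleus_area_contrast(table, "HER2", density_split=0.1)
        assert res.flagged
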