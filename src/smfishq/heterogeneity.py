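"""Spatial heterogeneity metrics: Shannon diversity, neighbor differences,
distance-expression scaling, inter-regional variability, co-expression.

An *expression level* is a distinct integer spot count observed among the
pseudo-cells of a field (or of the pooled case) that pass the per-channel
dot threshold (>= 3 dots for HER2, >= 1 for ER by convention). With
p_l the fraction of passing pseudo-cells at level l, the Shannon diversity
of field i is ``H_i = -sum_l p_l log2 p_l`` and the local diversity index is
its normalization ``H_i / log2 L_i`` (defined as 0 when only one level is
present). The global index applies the same computation to all pseudo-cells
of a case pooled across fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError
from .scoring import PseudoCellGrid
from .calibration import compare_groups, rank_correlation

__all__ = [
    "DiversityIndex",
    "DiversityDispersion",
    "NeighborDifferences",
    "ScalingResult",
    "InterregionalVariability",
    "CoexpressionResult",
    "NucleusAreaContrast",
    "local_diversity",
    "global_diversity",
    "diversity_dispersion",
    "neighbor_differences",
    "distance_expression_scaling",
    "interregional_variability",
    "coexpression",
    "nucleus_area_contrast",
]

#: Conventional per-channel pseudo-cell dot thresholds for the diversity and
#: topography analyses.
DIVERSITY_THRESHOLDS = {"HER2": 3, "ER": 1}


@dataclass(frozen=True)
class DiversityIndex:
    """Shannon diversity of thresholded pseudo-cell expression levels."""

    n_levels: int  # L: number of distinct counts among passing pseudo-cells
    entropy_bits: float  # H
    index: float  # H / log2 L, in [0, 1]; 0 when L <= 1
    n_passing: int
    flagged: bool  # True when no pseudo-cell passed the threshold


def _diversity_from_counts(passing_counts: np.ndarray) -> DiversityIndex:
    n = passing_counts.size
    if n == 0:
        return DiversityIndex(0, float("nan"), float("nan"), 0, True)
    _, freq = np.unique(passing_counts, return_counts=True)
    p = freq / n
    h = float(-(p * np.log2(p)).sum())
    levels = len(freq)
    index = h / math.log2(levels) if levels > 1 else 0.0
    return DiversityIndex(levels, h, index, n, False)


def local_diversity(grid: PseudoCellGrid, dot_threshold: int) -> DiversityIndex:
    """Diversity of one field's pseudo-cell counts passing the threshold."""
    counts = grid.counts.ravel()
    return _diversity_from_counts(counts[counts >= dot_threshold])


def global_diversity(
    grids: Sequence[PseudoCellGrid], dot_threshold: int
) -> DiversityIndex:
    """Diversity of the pooled pseudo-cell counts of all fields of a case."""
    if not grids:
        raise ValidationError("global_diversity requires at least one grid")
    counts = np.concatenate([g.counts.ravel() for g in grids])
    return _diversity_from_counts(counts[counts >= dot_threshold])


@dataclass(frozen=True)
class DiversityDispersion:
    mean: float
    cv: float  # sample sd (n - 1) / mean
    n_fields: int
    flagged: bool  # undefined: < 2 fields or zero mean


def diversity_dispersion(local_indices: Sequence[float]) -> DiversityDispersion:
    """Mean and coefficient of variation of per-field local diversity indices."""
    vals = np.asarray([v for v in local_indices if not np.isnan(v)], dtype=float)
    if len(vals) < 2 or vals.mean() == 0:
        m = float(vals.mean()) if len(vals) else float("nan")
        return DiversityDispersion(m, float("nan"), len(vals), True)
    return DiversityDispersion(
        float(vals.mean()), float(vals.std(ddof=1) / vals.mean()), len(vals), False
    )


@dataclass(frozen=True)
class NeighborDifferences:
    diffs: np.ndarray  # absolute count differences over adjacent passing pairs
    mean: float
    n_pairs: int


def neighbor_differences(grid: PseudoCellGrid, dot_threshold: int) -> NeighborDifferences:
    """Absolute count differences between 8-adjacent passing pseudo-cells.

    Pairs are unordered and counted once; border pseudo-cells contribute
    only the neighbors that exist; pairs where either member fails the
    threshold are dropped.
    """
    c = grid.counts
    passing = c >= dot_threshold
    diffs: list[int] = []
    g = grid.g
    # right, down-left, down, down-right cover each unordered pair once
    offsets = ((0, 1), (1, -1), (1, 0), (1, 1))
    for dr, dc in offsets:
        r0 = slice(0, g - dr)
        r1 = slice(dr, g)
        c0 = slice(max(0, -dc), g - max(0, dc))
        c1 = slice(max(0, dc), g - max(0, -dc))
        both = passing[r0, c0] & passing[r1, c1]
        d = np.abs(c[r0, c0] - c[r1, c1])[both]
        diffs.append(d.ravel())
    all_diffs = np.concatenate(diffs) if diffs else np.zeros(0, dtype=int)
    mean = float(all_diffs.mean()) if all_diffs.size else float("nan")
    return NeighborDifferences(all_diffs, mean, int(all_diffs.size))


@dataclass(frozen=True)
class ScalingResult:
    rho: float
    p_value: float
    n_pairs: int
    flagged: bool  # undefined: < 2 passing units everywhere or zero variance


def _pairs_from_points(
    positions_um: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    n = len(values)
    if n < 2:
        return np.zeros(0), np.zeros(0)
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(positions_um[iu] - positions_um[ju], axis=1)
    dv = np.abs(values[iu] - values[ju])
    # round away last-bit noise so that geometrically equal separations tie
    # exactly in the rank statistics (Spearman is invariant to the rounding)
    return np.round(d, 9), np.round(dv, 12)


def distance_expression_scaling(
    case_data: Sequence[PseudoCellGrid] | pd.DataFrame,
    channel: str,
    dot_threshold: int,
    unit: str = "pseudo-cell",
    use_density: bool = False,
) -> ScalingResult:
    """How expression differences scale with physical separation.

    For each field, all pairs of threshold-passing units (pseudo-cells or
    segmented cells) contribute one Euclidean distance (um, between
    pseudo-cell centers or cell centroids) and one absolute difference of
    transcript counts (or densities with ``use_density``); the per-case
    vectors concatenated across fields are tested for Spearman correlation.
    """
    dists: list[np.ndarray] = []
    diffs: list[np.ndarray] = []
    if unit == "pseudo-cell":
        for grid in case_data:
            c = grid.counts.ravel()
            passing = c >= dot_threshold
            if passing.sum() < 2:
                continue
            pos = grid.centers_um().reshape(-1, 2)[passing]
            vals = c[passing].astype(float)
            if use_density:
                vals = vals / grid.volume_um3
            d, dv = _pairs_from_points(pos, vals)
            dists.append(d)
            diffs.append(dv)
    elif unit == "cell":
        for _, sub in case_data.groupby("field_id"):
            counts = sub[f"count_{channel}"].to_numpy()
            passing = counts >= dot_threshold
            if passing.sum() < 2:
                continue
            pos = sub.loc[passing, ["centroid_x_um", "centroid_y_um"]].to_numpy()
            col = f"density_{channel}" if use_density else f"count_{channel}"
            vals = sub.loc[passing, col].to_numpy(dtype=float)
            d, dv = _pairs_from_points(pos, vals)
            dists.append(d)
            diffs.append(dv)
    else:
        raise ValidationError("unit must be 'pseudo-cell' or 'cell'")
    if not dists:
        return ScalingResult(float("nan"), float("nan"), 0, True)
    d = np.concatenate(dists)
    dv = np.concatenate(diffs)
    if len(d) < 3 or np.std(dv) == 0 or np.std(d) == 0:
        return ScalingResult(float("nan"), float("nan"), len(d), True)
    rho, p = rank_correlation(d, dv)
    return ScalingResult(rho, p, len(d), False)


@dataclass(frozen=True)
class InterregionalVariability:
    cv: float
    field_means: pd.Series  # per-field mean single-cell density
    n_fields_skipped: int  # fields with no segmented cells
    flagged: bool


def interregional_variability(
    cell_table: pd.DataFrame, channel: str, field_ids: Sequence[str] | None = None
) -> InterregionalVariability:
    """CV across fields of the per-field mean single-cell density.

    Fields listed in ``field_ids`` but absent from the cell table (no
    segmented cells) are skipped and reported in ``n_fields_skipped``.
    """
    col = f"density_{channel}"
    means = cell_table.groupby("field_id")[col].mean()
    skipped = int(means.isna().sum())
    if field_ids is not None:
        skipped += len(set(field_ids) - set(means.index))
    means = means.dropna()
    if len(means) < 2 or means.mean() == 0:
        return InterregionalVariability(float("nan"), means, skipped, True)
    cv = float(means.std(ddof=1) / means.mean())
    return InterregionalVariability(cv, means, skipped, False)


@dataclass(frozen=True)
class CoexpressionResult:
    rho: float
    p_value: float
    n_cells: int
    scatter: pd.DataFrame  # per-cell thresholded densities of both channels


def coexpression(
    cell_table: pd.DataFrame,
    channel_a: str,
    channel_b: str,
    dot_thresholds: Mapping[str, int] | None = None,
) -> CoexpressionResult:
    """Single-cell correlation between two channels' densities.

    Counts below a channel's per-cell dot threshold zero that channel's
    density for the cell (default thresholds: 0 for HER2, 1 for ER); the
    Spearman correlation is computed over all segmented cells of the case.
    """
    thr = {channel_a: 0, channel_b: 0}
    thr.update({"HER2": 0, "ER": 1})
    if dot_thresholds:
        thr.update(dot_thresholds)
    scatter = pd.DataFrame({"cell_id": cell_table["cell_id"]})
    for ch in (channel_a, channel_b):
        dens = cell_table[f"density_{ch}"].to_numpy(dtype=float).copy()
        dens[cell_table[f"count_{ch}"].to_numpy() < thr.get(ch, 0)] = 0.0
        scatter[f"density_{ch}"] = dens
    a = scatter[f"density_{channel_a}"].to_numpy()
    b = scatter[f"density_{channel_b}"].to_numpy()
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return CoexpressionResult(float("nan"), float("nan"), len(a), scatter)
    rho, p = rank_correlation(a, b)
    return CoexpressionResult(rho, p, len(a), scatter)


@dataclass(frozen=True)
class NucleusAreaContrast:
    areas_high: np.ndarray
    areas_low: np.ndarray
    u_statistic: float
    p_value: float
    flagged: bool  # one stratum empty


def nucleus_area_contrast(
    cell_table: pd.DataFrame, channel: str, density_split: float
) -> NucleusAreaContrast:
    """Compare nucleus areas of highly vs lowly expressing cells.

    Cells are partitioned at ``density_split`` (dots/um^3) on the channel's
    single-cell density; undilated nucleus areas of the two strata are
    compared with the two-tailed Mann-Whitney test.
    """
    dens = cell_table[f"density_{channel}"].to_numpy(dtype=float)
    areas = cell_table["nucleus_area_um2"].to_numpy(dtype=float)
    high = areas[dens >= density_split]
    low = areas[dens < density_split]
    if len(high) == 0 or len(low) == 0:
        return NucleusAreaContrast(high, low, float("nan"), float("nan"), True)
    u, p = compare_groups(high, low)
    return NucleusAreaContrast(high, low, u, p, False)
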