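"""ROC-based diagnostic calibration and nonparametric group statistics.

The smFISH score (per-case mean thresholded pseudo-cell density) is compared
against the clinical reference test (IHC / DNA FISH positivity) on a fixed
grid of 200 cutoffs t = 0.001 k, k = 1..200 dots/um^3: at each cutoff a case
is called positive when its score is >= t, giving TP/FP/TN/FN and hence
sensitivity and specificity.

Two AUC conventions are provided. ``conventional`` (default) is the
trapezoidal area under the (1 - specificity, sensitivity) polyline with
(0,0) and (1,1) appended — the scale on which AUC = 0.5 means chance and
values above 0.9 excellent discrimination. ``diagonal`` is the area between
the curve and the chance diagonal (conventional minus 0.5), retained because
some reports define AUC that way literally.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .scoring import case_score, grid_counts

__all__ = [
    "ROC_CUTOFFS",
    "ROCResult",
    "SweepMatrix",
    "roc_curve",
    "auc",
    "best_operating_point",
    "parameter_sweep",
    "compare_groups",
    "rank_correlation",
]

#: The fixed cutoff grid: 0.001 * k for k = 1..200 (dots/um^3). Scores above
#: 0.2 are called positive at every cutoff.
ROC_CUTOFFS = np.arange(1, 201) * 0.001

#: Combined sample size at or below which the Mann-Whitney P value is
#: computed by exact enumeration of all group assignments.
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class ROCResult:
    """ROC counts and rates of one score/label set on the fixed cutoff grid."""

    table: pd.DataFrame  # columns: cutoff, tp, fp, tn, fn, sensitivity, specificity
    n_positive: int
    n_negative: int

    @property
    def cutoffs(self) -> np.ndarray:
        return self.table["cutoff"].to_numpy()


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """Sweep the fixed 200-cutoff grid over per-case scores.

    ``labels`` holds the reference-test result per case (True = positive).
    A case is called positive at cutoff t when its score is >= t.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and equally long")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0:
        raise ValidationError("no positive cases: ROC undefined (missing class: positive)")
    if n_neg == 0:
        raise ValidationError("no negative cases: ROC undefined (missing class: negative)")
    rows = []
    for t in ROC_CUTOFFS:
        called = s >= t
        tp = int((called & y).sum())
        fp = int((called & ~y).sum())
        tn = int((~called & ~y).sum())
        fn = int((~called & y).sum())
        rows.append(
            {
                "cutoff": t,
                "tp": tp,
                "fp": fp,
                "tn": tn,
                "fn": fn,
                "sensitivity": tp / (tp + fn),
                "specificity": tn / (tn + fp),
            }
        )
    return ROCResult(table=pd.DataFrame(rows), n_positive=n_pos, n_negative=n_neg)


def auc(roc: ROCResult, mode: str = "conventional") -> float:
    """Area under the ROC curve.

    ``conventional``: trapezoidal area under the (1 - specificity,
    sensitivity) polyline with (0, 0) and (1, 1) appended, points sorted by
    x then y. ``diagonal``: the area between the curve and the chance
    diagonal, i.e. conventional minus 0.5.
    """
    if mode not in ("conventional", "diagonal"):
        raise ValidationError("auc mode must be 'conventional' or 'diagonal'")
    x = 1.0 - roc.table["specificity"].to_numpy()
    ysens = roc.table["sensitivity"].to_numpy()
    pts = np.vstack([np.column_stack([x, ysens]), [[0.0, 0.0], [1.0, 1.0]]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return area - 0.5 if mode == "diagonal" else area


def best_operating_point(roc: ROCResult) -> tuple[float, float, float]:
    """Cutoff minimizing the distance to the top-left ROC corner.

    Returns (cutoff, sensitivity, specificity) of the point closest to
    (0, 1) in (1 - specificity, sensitivity) space; ties break to the
    smallest cutoff.
    """
    x = 1.0 - roc.table["specificity"].to_numpy()
    ysens = roc.table["sensitivity"].to_numpy()
    d2 = x**2 + (1.0 - ysens) ** 2
    i = int(np.argmin(d2))  # argmin takes the first (= smallest cutoff) on ties
    row = roc.table.iloc[i]
    return float(row["cutoff"]), float(row["sensitivity"]), float(row["specificity"])


@dataclass(frozen=True)
class SweepMatrix:
    """AUC over a grid of scoring settings (grid orders x dot thresholds)."""

    table: pd.DataFrame  # index: axis1 (grid order or margin), columns: thresholds
    axis1_name: str

    @property
    def argmax(self) -> tuple[object, object, float]:
        """(axis1 value, threshold, AUC) of the best-performing combination."""
        arr = self.table.to_numpy()
        i, j = np.unravel_index(int(np.argmax(arr)), arr.shape)
        return self.table.index[i], self.table.columns[j], float(arr[i, j])


def parameter_sweep(
    case_fields: Mapping[str, Sequence[tuple[pd.DataFrame, object]]],
    labels: Mapping[str, bool],
    channel: str,
    grid_orders: Sequence[int] = (9, 10, 11, 12, 13, 14, 16),
    thresholds: Sequence[int] = (0, 1, 2, 3),
    auc_mode: str = "conventional",
    policy: str = "exclude",
) -> SweepMatrix:
    """Recompute case scores and AUC for every grid-order/threshold pair.

    ``case_fields`` maps case_id to its fields, each a (spot table, field
    meta) pair; ``labels`` maps case_id to the reference-test result.
    """
    case_ids = list(case_fields)
    lab = [bool(labels[c]) for c in case_ids]
    rows = []
    for g in grid_orders:
        grids_by_case = {
            c: [grid_counts(spots, meta, g, channel) for spots, meta in case_fields[c]]
            for c in case_ids
        }
        row = {}
        for thr in thresholds:
            scores = [
                case_score(grids_by_case[c], thr, policy=policy).score for c in case_ids
            ]
            row[thr] = auc(roc_curve(scores, lab), mode=auc_mode)
        rows.append(row)
    table = pd.DataFrame(rows, index=list(grid_orders), columns=list(thresholds))
    table.index.name = "grid_order"
    table.columns.name = "dot_threshold"
    return SweepMatrix(table=table, axis1_name="grid_order")


# ---------------------------------------------------------------------------
# Nonparametric statistics


def _mw_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of sample a via mid-rank summation."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2)


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney test.

    Returns (U, P) where U is the statistic of the first sample. For a
    combined sample size of at most 12 the P value comes from exact
    enumeration of all group assignments (valid with ties); larger samples
    use the normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    u = _mw_u(a, b)
    n, m = len(a), len(b)
    if n + m <= EXACT_MW_MAX_N:
        pooled = np.concatenate([a, b])
        us = np.array(
            [
                _mw_u(pooled[list(idx)], np.delete(pooled, list(idx)))
                for idx in itertools.combinations(range(n + m), n)
            ]
        )
        eps = 1e-9
        p_low = float((us <= u + eps).mean())
        p_high = float((us >= u - eps).mean())
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mu = n * m / 2.0
        pooled = np.concatenate([a, b])
        _, tie_counts = np.unique(pooled, return_counts=True)
        nm = n + m
        tie_term = (tie_counts**3 - tie_counts).sum() / (nm * (nm - 1))
        sigma2 = n * m / 12.0 * (nm + 1 - tie_term)
        if sigma2 <= 0:
            return u, 1.0
        z = (u - mu - math.copysign(0.5, u - mu)) / math.sqrt(sigma2) if u != mu else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(1.0, p)
    return u, p


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a Student-t two-tailed P value.

    rho is the Pearson correlation of mid-ranks; P comes from
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n - 2 degrees of freedom.
    Zero-variance input leaves the correlation undefined (NaN, NaN).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be 1-D and equally long")
    n = len(xa)
    if n < 3:
        raise ValidationError("rank correlation needs at least 3 observations")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return math.copysign(1.0, rho), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p
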