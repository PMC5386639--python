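# smfishq

Quantification of single-molecule RNA FISH (smFISH) signals in
formalin-fixed, paraffin-embedded (FFPE) tumor sections, built around the
two breast-cancer biomarkers HER2 and ER.

In smFISH every mRNA molecule appears as one diffraction-limited fluorescent
spot, so transcript abundance can be counted absolutely, cell by cell and
region by region. `smfishq` implements the quantitative machinery needed to
turn per-field spot tables (and, optionally, raw image stacks) into
diagnostic scores and spatial-heterogeneity metrics:

- **Pseudo-cell scoring** — each 1,024 × 1,024 px field (125 nm/px, 5 focal
  planes 0.4 µm apart) is partitioned into a regular g × g grid of square
  *pseudo-cells*; the per-pseudo-cell density is
  `count / ((n_planes − 1) · Δz · cell_area)` in dots/µm³, and the per-case
  **smFISH score** is the mean density over all pseudo-cells with at least a
  small dot threshold (defaults g = 13 with ≥ 3 dots for HER2, ≥ 1 for ER).
- **Single-cell scoring** — nucleus polygons dilated by a constant margin
  (default 20 px = 2.5 µm) define approximate cells; spots are assigned by
  point-in-polygon with nearest-nucleus tie-breaking and densities use the
  same prism-volume convention.
- **Nuclei-region scoring** — textured (nuclei-rich) regions are detected on
  DAPI z-projections by thresholding the determinant of the gradient
  structure tensor (σ_gradient = 250 nm, σ_tensor = 875 nm).
- **Diagnostic calibration** — ROC analysis on a fixed grid of 200 cutoffs
  (t = 0.001·k dots/µm³, k = 1…200) against reference IHC / DNA FISH
  positivity (HER2+: IHC 3+ or 2+ amplified; ER+: ≥ 1%), with trapezoidal
  AUC, best operating point, and parameter sweeps over grid orders and dot
  thresholds; St. Gallen surrogate subtype derivation; exact/approximate
  Mann-Whitney and Spearman statistics.
- **Intra-tumor topography** — Shannon diversity of pseudo-cell expression
  levels, `H_i = −Σ_l p_l log₂ p_l`, normalized to the local diversity
  index `H̄_i = H_i / log₂ L_i ∈ [0, 1]` per field and globally per case;
  8-neighbor transcript differences; distance-vs-expression-difference
  scaling; inter-regional CV; two-channel single-cell co-expression.
- **Spot calling** — scale-normalized Laplacian-of-Gaussian detection with
  non-maximum suppression, cross-plane merging and sub-pixel refinement.
- **Registration** — placement of high-magnification fields into stitched
  scans by normalized cross-correlation (transform A1: scaling +
  translation), least-squares affine mapping onto an H&E scan from
  reference points (A2), and spot transfer `D' = A2·A1·D`.
- **Synthetic cohorts** — a generator producing fields, cases and cohorts
  with known ground truth (non-overlapping convex nuclei, negative-binomial
  on/off expression, spatial clone patterns, stromal spot-free regions,
  background dots, rendered image stacks) for validation of the entire
  pipeline.

## Worked example

```python
import numpy as np
from smfishq import (
    CohortSpec, simulate_cohort, grid_counts, case_score, roc_curve, auc,
    best_operating_point, compare_groups,
)

cohort = simulate_cohort(CohortSpec(n_positive=5, n_negative=5, n_fov_per_case=8), seed=42)

scores, labels = [], []
for case in cohort.cases:
    grids = [grid_counts(f.spots, f.meta, g=13, channel="HER2") for f in case.fovs]
    scores.append(case_score(grids, dot_threshold=3).score)
    labels.append(cohort.positive["HER2"][case.case_id])

roc = roc_curve(scores, labels)
```

Printing the summary of this run gives:

```
HER2 smFISH scores (dots/um^3): positive mean = 0.127, negative mean = 0.033
Mann-Whitney U = 25, two-tailed P = 0.0079
AUC = 1.000
best cutoff t = 0.049 dots/um^3 (sensitivity 1.00, specificity 1.00)
```

The positive group's mean pseudo-cell transcript density (0.127 dots/µm³)
sits well above the negative group's (0.033 dots/µm³); the Mann-Whitney test
confirms the group separation, the ROC sweep finds a cutoff near
0.05 dots/µm³ that classifies every case correctly, and the AUC of 1.0
reflects perfect discrimination on this small synthetic cohort.

## Command line

All analyses are also exposed as a thin CLI (`smfishq --help`):
`simulate` (YAML scenario → CSV/JSON cohort artifacts), `detect` (TIFF stack
→ spot CSV), `score` (spots + metadata → pseudo-cell / per-cell / per-case
CSVs), `roc`, `diversity`, `topography`, and `register`. Reruns with the
same seed and configuration produce byte-identical outputs.

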