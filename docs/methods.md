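# Methods

This note documents the models, conventions and design choices behind
`smfishq`, in the spirit of a methods section: what is computed, under which
assumptions, and what the synthetic validation does and does not show.

## Coordinate and geometry conventions

Coordinates are 0-based and continuous with pixel centers at integer
positions; `x` is the column (rightward), `y` the row (downward). Plane
indices are 0-based with physical depth `z = plane · Δz`. Because cells are
never imaged through their full thickness, all densities use the prism
convention: the imaged volume over a base of area `A` is
`A · (n_planes − 1) · Δz` — with the default 5 planes spaced 0.4 µm, a
1.6 µm slab. At the default 125 nm/px, 1 px = 0.125 µm.

Tabular data is CSV (UTF-8, mandatory header); outlines are JSON with
GeoJSON-style polygon geometry accepted on input; stacks are multi-page
grayscale TIFF. Spot coordinates are accepted at either integer or
sub-pixel precision.

## Pseudo-cell scoring

A field is split into a regular g × g grid whose squares ("pseudo-cells")
have exact fractional-pixel sides `width_px / g`, so all g² pseudo-cells
share one area — the single `cell_area` term the density formula assumes.
A spot at (x, y) belongs to column `floor(x / (width_px/g))`; boundary spots
fall into the higher-index cell except at the last edge, which clamps.
The per-case smFISH score is the mean pseudo-cell density over all fields,
restricted to pseudo-cells with at least `dot_threshold` spots — a guard
against sparse background dots. Sub-threshold pseudo-cells are *excluded*
from the mean rather than zeroed; the alternative reading is available as
`policy="zero"` (the two coincide at threshold 0). Default settings follow
the calibrated optimum: g = 13 with thresholds 3 (HER2) and 1 (ER).

## Single-cell scoring

Nucleus polygons are dilated by a Euclidean round-join buffer (default
20 px = 2.5 µm) to capture cytoplasmic transcripts, and clipped at field
borders, since no spot can be observed outside the field. A spot inside
exactly one dilated polygon belongs to that cell; inside several, it goes
to the cell whose *undilated* nucleus boundary is nearest (ties to the
lowest cell id); outside all, it stays unassigned (stroma). The single-cell
density divides the assigned count by the prism volume over the dilated,
clipped polygon — the same footprint within which spots were collected.
Using the undilated nucleus as the base is available via `base="nucleus"`.

## Nuclei-region detection

Cell-containing regions are found on the DAPI z-projection from the
gradient structure tensor: Gaussian derivatives at σ_gradient = 250 nm
(2 px) form the per-pixel 2 × 2 tensor, its components are smoothed at
σ_tensor = 875 nm (7 px), and the mask is `det > threshold`. The
determinant is homogeneous of degree 4 in image intensity, so the automatic
threshold applies Otsu to `det^(1/4)` (linear in intensity) and raises the
result to the 4th power; a manually chosen common threshold can be passed
instead. The mask is region-level by design, not an instance segmentation.

## Diagnostic calibration

ROC analysis uses a fixed cutoff grid t = 0.001·k dots/µm³, k = 1…200; a
case is called positive when its score is ≥ t. Scores above 0.2 dots/µm³
are therefore positive at every cutoff. TP/FP/TN/FN, sensitivity and
specificity follow the four standard definitions against the clinical
reference (HER2+: IHC 3+ or IHC 2+ with DNA-FISH amplification; ER+: ≥ 1%).
Two AUC conventions are provided: the default `conventional` trapezoidal
area under the (1 − specificity, sensitivity) polyline with (0,0) and (1,1)
appended — the scale on which 0.5 is chance — and `diagonal`, the area
between the curve and the chance diagonal (conventional − 0.5), for reports
that define AUC literally that way. The best operating point minimizes the
Euclidean distance to the top-left corner, ties to the smallest cutoff.

Surrogate molecular subtypes follow the St. Gallen IHC rules: triple-
negative (ER−/PR−/HER2−), HER2 (ER−/HER2+), Luminal B/HER2-pos (ER+/HER2+),
Luminal B/HER2-neg (ER+/HER2− with Ki67 > 14% and/or PR < 20%), otherwise
Luminal A; "Ki67-low" means ≤ 14%.

### Statistics

Group comparisons use the two-tailed Mann-Whitney test, implemented
in-package so the tie and small-sample policies are explicit: for combined
n ≤ 12 the P value comes from exact enumeration of all group assignments on
mid-ranks (valid under ties, with the two-tailed value
`min(1, 2·min(P(U ≤ u), P(U ≥ u)))`); larger samples use the normal
approximation with tie correction and continuity correction. Spearman ρ is
the Pearson correlation of mid-ranks, with the two-tailed P from
`t = ρ·sqrt((n−2)/(1−ρ²))` on n − 2 degrees of freedom; zero-variance input
is flagged undefined. Both are cross-checked against scipy in the test
suite; scipy is deliberately not the implementation because its exact
Mann-Whitney path refuses ties.

## Intra-tumor topography

An *expression level* is a distinct integer spot count among pseudo-cells
passing the per-channel threshold (≥ 3 for HER2, ≥ 1 for ER); the index is
only well defined on discrete counts. With p_l the fraction of passing
pseudo-cells at level l, the Shannon diversity is
`H = −Σ p_l log₂ p_l` and the normalized index `H̄ = H / log₂ L`, set to 0
when a single level is present (a single level is zero diversity) and
flagged undefined when nothing passes. The local index is per field, the
global index pools all pseudo-cells of a case; pooling can only add levels,
so global L ≥ max local L. Dispersion across fields is summarized by the
CV (sample sd / mean) of the local indices.

Neighbor differences are absolute count differences over unordered
8-neighborhood pairs in which *both* members pass the threshold; border
pseudo-cells contribute only existing neighbors. Distance-expression
scaling collects, within each field, all pairs of passing units — pseudo-
cell centers or segmented-cell centroids, distances in µm — with their
absolute count differences (densities optional), concatenates the per-case
vectors across fields, and tests Spearman correlation. Pair distances are
rounded at 10⁻⁹ µm so geometrically equal separations tie exactly in the
ranks. Spearman ρ is invariant to the distance unit; µm is used for
reporting. Co-expression correlates two channels' single-cell densities
after zeroing counts below the per-channel cell thresholds (defaults 0 for
HER2, 1 for ER).

## Spot calling

Each plane is filtered with a scale-normalized Laplacian of Gaussian
(default σ = 1.3 px, matching a diffraction-limited PSF at 125 nm/px);
local maxima above the threshold survive non-maximum suppression within
`min_separation_px` (default 3 px). When the threshold is not given it is
chosen per stack by Otsu's method on the positive filtered response — a
histogram-valley heuristic that separates the spot mode from noise maxima.
Maxima of the same molecule on adjacent planes within the separation radius
merge onto the brightest (on by default: densities divide by the full stack
depth, so a molecule must count once per stack). Positions are refined by
independent quadratic fits along x and y in the 3 × 3 neighborhood, clamped
to ±0.5 px. Matching to ground truth is greedy one-to-one nearest-pair
within a tolerance.

## Registration

A1 places a high-magnification field into a stitched scan: the field is
rescaled to the scan's pixel size (bilinear with anti-aliasing) and slid
over the scan with normalized cross-correlation (zero-mean, unit-variance
within the template support); A1 is restricted to scaling + integer-pixel
translation to the correlation peak — residual rotation/shear correction is
deferred to A2, a least-squares affine fitted from ≥ 3 non-collinear
manually selected reference point pairs. Sub-pixel peak refinement exists
but is off by default. Spots transform as homogeneous 2-D points,
`D' = A2·A1·D`; the peak correlation is reported as placement confidence
and flagged below a floor (default 0.5).

## Synthetic-data generator

The generator emulates the acquisition geometry (1,024 × 1,024 px fields at
125 nm/px; 5 planes, 0.4 µm apart) and the statistical structure of tumor
fields: ~19 ± 10 cells per field (truncated ≥ 1) as convex, non-overlapping
nucleus polygons (perturbed ellipses with 8–14 vertices, dart-throw packed;
area ~65 ± 13 µm²), a spot-free stromal band covering 25% of the field,
per-cell counts from a negative binomial with variance `m + φm²` (φ = 0.3
by default; Poisson in the φ → 0 limit, matching overdispersed single-cell
expression), spot positions uniform in the dilated cell footprint, planes
uniform, and uniform background dots at 0.001 dots/µm³ — enough to exercise
the dot-count thresholds. Expression is bimodal on/off per channel;
`unimodal` draws every cell from the 'on' component.

Spatial patterns at case level: `homogeneous` draws one state per channel
for the whole case; `mixed` is i.i.d. per cell; `segregated` lays Voronoi
clone patches over a virtual mosaic of the case's fields so whole fields
tend to be 'hot' or 'cold' — clone states are deterministic (a fraction
`on_fraction` of clones is 'on', with at least one 'on' and one 'off' clone
whenever 0 < f < 1 and ≥ 2 clones) so the pattern actually segregates;
`gradient` raises the on-probability linearly along x within each field
(`p = clip(2f·u, 0, 1)` over the tumor span, preserving the mean).

Cohorts assign per-channel positive/negative labels deterministically
(channel blocks rotated so two channels do not share one label vector) and
inject case-level biological variability via a lognormal multiplier
(σ = 0.25) on the channel means. The default expression models were
calibrated once so that, at the standard scoring settings, group mean
pseudo-cell densities land near 0.13 vs 0.04 dots/µm³ (HER2) and
0.04 vs ~0.015–0.02 dots/µm³ (ER) — the regime the scoring and ROC defaults
are designed for. Reference labels are constructed consistently (IHC 3+
amplified vs 1+ non-amplified; ER 80% vs 0%).

Rendering draws each spot as an isotropic 2-D Gaussian (default σ = 1.3 px,
peak 200 over background 100) on its plane, with Poisson shot noise plus
Gaussian read noise. The DAPI channel fills nucleus polygons and modulates
them with a smoothed lognormal texture field emulating chromatin
granularity — without interior texture the structure tensor would respond
only at nucleus boundaries. Everything is bit-reproducible from the seed
through a `SeedSequence` tree.

### What the synthetic validation does not show

The generator omits FFPE autofluorescence texture, optical z-blur (spots
live on exactly one plane), nucleus shape irregularity beyond perturbed
ellipses, segmentation error (truth outlines are exact), and cell crowding
with touching membranes. Passing tests therefore demonstrate internal
consistency and correct implementation of the formulas and recovery of the
generator's structure — not performance on real FFPE images, where spot
calling and segmentation quality dominate.

### Topography scenario

Recovering *spatial* signatures needs fields in which large-scale structure
is not masked by short-range cell-core/rim contrast: in sparsely seeded
fields a pseudo-cell covering a cell core sits next to one covering its rim
or a gap, which makes nearby pseudo-cell pairs maximally different and
biases the distance-expression correlation negative. The topography
scenarios therefore use densely tiled fields (60 ± 5 cells), mild
overdispersion (φ = 0.1) and a coarser 9 × 9 grid whose pseudo-cells
average over whole cells. On that scenario, segregated cases show a
markedly higher CV of local diversity (and a larger |global − mean local|
divergence) than homogeneous cases, gradient cases show a positive
distance-expression ρ with P < 0.05, and mixed cases show |ρ| < 0.05.

## Problem sizes

The validation cohort is 20 positive + 20 negative cases with 32 fields
each (the lower end of the 32–79 fields-per-case range the assay targets);
topography scenarios use 16 fields per case; bimodality checks pool ≥ 1,000
segmented cells; spot-calling fixtures use 50-spot 256 px fields at high
signal-to-noise; the registration round trip embeds a rendered 512 px field
into a 400 px scan at scale 0.4. These sizes make the full suite and the
acceptance script run in a few minutes on one CPU while keeping every
statistical check well-powered.

## Known limitations

- The spot caller is a principled reimplementation (LoG + NMS + z-merge);
  equivalence with any particular legacy caller cannot be asserted, only
  performance against synthetic truth.
- The structure-tensor mask is region-level; it does not separate touching
  nuclei.
- No confidence intervals on AUC and no cross-validation are provided.
- A1 ignores rotation between field and scan; tissue that rotated between
  acquisitions would need the residual absorbed into A2.
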