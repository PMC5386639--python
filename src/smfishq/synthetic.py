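"""Synthetic fields of view, cases, and cohorts with known ground truth.

The generator emulates the statistical structure the scoring and
heterogeneity analyses assume: 1024 x 1024 px fields at 125 nm/px imaged in
5 focal planes 0.4 um apart, ~19 +/- 10 tumor cells per field with nucleus
areas around 65 um^2, per-cell transcript counts drawn from a (possibly
bimodal on/off) negative-binomial expression model, spot-free stromal
regions, spatial clone structure, and cohorts of positive and negative cases
whose group mean pseudo-cell densities bracket the diagnostic decision
boundary.

Everything is reproducible at bit level from the integer seed: all draws go
through a :class:`numpy.random.Generator` tree spawned from a single
``SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .core import CaseRecord, CellOutline, FieldOfViewMeta, ValidationError

__all__ = [
    "ExpressionModel",
    "SimulationParams",
    "SyntheticTruth",
    "FovBundle",
    "CaseBundle",
    "ChannelCohortSpec",
    "CohortSpec",
    "Cohort",
    "PackingError",
    "simulate_fov",
    "simulate_case",
    "simulate_cohort",
    "correlated_state_assigner",
    "render_spot_stack",
    "render_nuclei_image",
]

SPATIAL_PATTERNS = ("homogeneous", "mixed", "segregated", "gradient")


class PackingError(RuntimeError):
    """Nucleus polygons could not be packed into the field without overlap."""


@dataclass(frozen=True)
class ExpressionModel:
    """Per-channel, per-cell transcript count model.

    ``bimodal`` cells are either transcriptionally 'on' (negative binomial
    with mean ``on_mean_spots``) or 'off' (mean ``off_mean_spots``); the
    probability of 'on' is ``on_fraction``. ``unimodal`` draws every cell
    from the 'on' component. ``overdispersion`` is the negative-binomial
    shape parameter phi with variance ``m + phi * m**2`` (phi -> 0 recovers
    the Poisson limit).
    """

    mode: str = "bimodal"
    on_fraction: float = 0.5
    on_mean_spots: float = 30.0
    off_mean_spots: float = 2.0
    overdispersion: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("unimodal", "bimodal"):
            raise ValidationError(f"unknown expression mode {self.mode!r}")
        if not 0.0 <= self.on_fraction <= 1.0:
            raise ValidationError("on_fraction must be in [0, 1]")
        if self.on_mean_spots < 0 or self.off_mean_spots < 0:
            raise ValidationError("mean spot counts must be >= 0")
        if self.overdispersion < 0:
            raise ValidationError("overdispersion must be >= 0")


def _default_expression() -> dict[str, ExpressionModel]:
    return {
        "HER2": ExpressionModel(on_fraction=0.8, on_mean_spots=30.0, off_mean_spots=3.0),
        "ER": ExpressionModel(on_fraction=0.7, on_mean_spots=10.0, off_mean_spots=1.0),
    }


@dataclass(frozen=True)
class SimulationParams:
    """Generative assumptions for one field of view (and, by sharing, a case)."""

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_nm: float = 125.0
    n_planes: int = 5
    plane_spacing_um: float = 0.4
    n_cells_mean: float = 19.0
    n_cells_sd: float = 10.0
    nucleus_area_um2_mean: float = 65.0
    nucleus_area_um2_sd: float = 13.0
    dilation_margin_px: float = 20.0
    expression: Mapping[str, ExpressionModel] = field(default_factory=_default_expression)
    spatial_pattern: str = "mixed"
    n_clones: int = 2
    stroma_fraction: float = 0.25
    background_spot_rate: float = 0.001  # spurious dots per um^3

    def __post_init__(self) -> None:
        if self.spatial_pattern not in SPATIAL_PATTERNS:
            raise ValidationError(
                f"spatial_pattern must be one of {SPATIAL_PATTERNS}"
            )
        if not 0.0 <= self.stroma_fraction < 1.0:
            raise ValidationError("stroma_fraction must be in [0, 1)")
        if self.background_spot_rate < 0:
            raise ValidationError("background_spot_rate must be >= 0")
        if self.n_clones < 1:
            raise ValidationError("n_clones must be >= 1")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.expression)

    def meta(self, field_id: str, case_id: str = "") -> FieldOfViewMeta:
        return FieldOfViewMeta(
            field_id=field_id,
            width_px=self.width_px,
            height_px=self.height_px,
            pixel_size_nm=self.pixel_size_nm,
            n_planes=self.n_planes,
            plane_spacing_um=self.plane_spacing_um,
            case_id=case_id,
        )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated field.

    ``cells`` has one row per cell: clone label, per-channel on/off state and
    true spot count, centroid, nucleus area. ``spot_source`` is aligned with
    the rows of the emitted spot table and names the owning cell ('' for
    background spots). ``n_background`` counts background spots per channel.
    """

    cells: pd.DataFrame
    spot_source: np.ndarray
    n_background: dict[str, int]


@dataclass
class FovBundle:
    meta: FieldOfViewMeta
    outlines: list[CellOutline]
    spots: pd.DataFrame
    truth: SyntheticTruth


@dataclass
class CaseBundle:
    case_id: str
    params: SimulationParams
    fovs: list[FovBundle]

    @property
    def spots(self) -> pd.DataFrame:
        return pd.concat([f.spots for f in self.fovs], ignore_index=True)

    @property
    def metas(self) -> dict[str, FieldOfViewMeta]:
        return {f.meta.field_id: f.meta for f in self.fovs}


# ---------------------------------------------------------------------------
# Nucleus geometry


def _random_nucleus(
    rng: np.random.Generator,
    area_px2: float,
) -> np.ndarray:
    """Convex polygon (n, 2) around the origin with roughly the given area.

    Built as a perturbed ellipse with 8-14 vertices; the convex hull of the
    perturbed ring guarantees convexity.
    """
    n_vert = int(rng.integers(8, 15))
    ratio = rng.uniform(0.65, 1.0)  # minor/major axis
    a = math.sqrt(area_px2 / (math.pi * ratio))
    b = ratio * a
    base = 2 * math.pi * np.arange(n_vert) / n_vert
    theta = base + rng.uniform(-0.3, 0.3, n_vert) * (2 * math.pi / n_vert)
    radial = rng.uniform(0.88, 1.12, n_vert)
    x = a * np.cos(theta) * radial
    y = b * np.sin(theta) * radial
    phi = rng.uniform(0, 2 * math.pi)
    rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
    pts = np.column_stack([x, y]) @ rot.T
    hull = shapely.convex_hull(shapely.multipoints(pts))
    return np.asarray(hull.exterior.coords)[:-1]


def _pack_nuclei(
    rng: np.random.Generator, params: SimulationParams, n_cells: int
) -> list[np.ndarray]:
    """Dart-throw non-overlapping convex nuclei into the tumor partition."""
    px_um = params.pixel_size_nm / 1000.0
    stroma_x = params.stroma_fraction * params.width_px
    polygons: list[Polygon] = []
    vertex_lists: list[np.ndarray] = []
    max_tries = 300 * n_cells
    tries = 0
    while len(polygons) < n_cells:
        if tries >= max_tries:
            raise PackingError(
                f"placed only {len(polygons)}/{n_cells} nuclei after {tries} tries; "
                "reduce cell count or nucleus area"
            )
        tries += 1
        area_um2 = max(15.0, rng.normal(params.nucleus_area_um2_mean, params.nucleus_area_um2_sd))
        verts = _random_nucleus(rng, area_um2 / px_um**2)
        r_max = float(np.max(np.hypot(verts[:, 0], verts[:, 1])))
        lo_x, hi_x = stroma_x + r_max, params.width_px - r_max
        lo_y, hi_y = r_max, params.height_px - r_max
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        center = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
        cand = Polygon(verts + center)
        if any(cand.intersects(p) for p in polygons):
            continue
        polygons.append(cand)
        vertex_lists.append(verts + center)
    return vertex_lists


# ---------------------------------------------------------------------------
# Expression states and counts


def _nb_draw(rng: np.random.Generator, mean: float, phi: float, size: int) -> np.ndarray:
    """Negative-binomial counts with variance m + phi m^2 (Poisson as phi->0)."""
    if size == 0:
        return np.zeros(0, dtype=int)
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if phi <= 0:
        return rng.poisson(mean, size).astype(int)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi, size=size)
    return rng.poisson(lam).astype(int)


StateAssigner = Callable[[np.ndarray, np.random.Generator], tuple[np.ndarray, dict[str, np.ndarray]]]


def _field_state_assigner(params: SimulationParams) -> StateAssigner:
    """Default per-field interpretation of the spatial pattern."""

    def assign(centroids: np.ndarray, rng: np.random.Generator):
        n = len(centroids)
        clones = np.zeros(n, dtype=int)
        states: dict[str, np.ndarray] = {}
        stroma_x = params.stroma_fraction * params.width_px
        if params.spatial_pattern == "segregated":
            seeds = np.column_stack(
                [
                    rng.uniform(stroma_x, params.width_px, params.n_clones),
                    rng.uniform(0, params.height_px, params.n_clones),
                ]
            )
            d = np.linalg.norm(centroids[:, None, :] - seeds[None, :, :], axis=2)
            clones = np.argmin(d, axis=1)
        for ch, model in params.expression.items():
            if model.mode == "unimodal":
                states[ch] = np.ones(n, dtype=bool)
            elif params.spatial_pattern == "homogeneous":
                states[ch] = np.full(n, rng.random() < model.on_fraction)
            elif params.spatial_pattern == "mixed":
                states[ch] = rng.random(n) < model.on_fraction
            elif params.spatial_pattern == "segregated":
                clone_on = _clone_states(params.n_clones, model.on_fraction)
                states[ch] = clone_on[clones]
            else:  # gradient: on-probability increases linearly along x
                span = max(params.width_px - stroma_x, 1.0)
                p = np.clip(2 * model.on_fraction * (centroids[:, 0] - stroma_x) / span, 0, 1)
                states[ch] = rng.random(n) < p
        return clones, states

    return assign


def _clone_states(n_clones: int, on_fraction: float) -> np.ndarray:
    """Deterministic clone expression states: a fraction of clones is 'on'.

    Clones represent stable subpopulations; assigning exactly
    round(on_fraction * n_clones) of them to the 'on' state keeps the
    expected on-fraction while guaranteeing that distinct clones differ in
    state whenever 0 < on_fraction < 1 with >= 2 clones.
    """
    n_on = int(round(on_fraction * n_clones))
    if 0 < on_fraction < 1:
        n_on = min(max(n_on, 1), n_clones - 1) if n_clones >= 2 else n_on
    states = np.zeros(n_clones, dtype=bool)
    states[n_clones - n_on :] = True  # higher-index clones are 'on'
    return states


def correlated_state_assigner(
    channels: Sequence[str], p_shared: float = 0.3, p_independent: float = 0.1
) -> StateAssigner:
    """State assigner with a subpopulation co-expressing all channels.

    A fraction ``p_shared`` of cells is 'on' in every channel simultaneously
    (clone label 1); the remaining cells turn each channel on independently
    with probability ``p_independent``. Used to emulate tumors harboring a
    sub-population with correlated biomarker expression.
    """

    def assign(centroids: np.ndarray, rng: np.random.Generator):
        n = len(centroids)
        shared = rng.random(n) < p_shared
        states = {ch: shared | (rng.random(n) < p_independent) for ch in channels}
        return shared.astype(int), states

    return assign


# ---------------------------------------------------------------------------
# Point sampling


def _sample_points_in_polygon(
    poly: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = np.zeros((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(poly, xs, ys)
        take = min(int(keep.sum()), n - got)
        out[got : got + take, 0] = xs[keep][:take]
        out[got : got + take, 1] = ys[keep][:take]
        got += take
    return out


# ---------------------------------------------------------------------------
# Simulation entry points


def simulate_fov(
    params: SimulationParams,
    seed: int | np.random.Generator | None = None,
    field_id: str = "fov_000",
    case_id: str = "case_0",
    n_cells: int | None = None,
    state_assigner: StateAssigner | None = None,
) -> FovBundle:
    """Simulate one field of view with ground truth.

    Nucleus polygons are packed without overlap into the tumor partition of
    the field (the leftmost ``stroma_fraction`` of the width is spot- and
    cell-free stroma). Per-cell counts follow the channel's expression model;
    spot positions are uniform within the cell's dilated footprint clipped to
    the field, with the focal plane uniform over planes. Background spots are
    uniform over the whole field volume.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meta = params.meta(field_id, case_id)
    if n_cells is None:
        n_cells = max(1, int(round(rng.normal(params.n_cells_mean, params.n_cells_sd))))
    vertex_lists = _pack_nuclei(rng, params, n_cells)
    px_um = meta.pixel_size_um

    outlines = [
        CellOutline(
            cell_id=f"{field_id}_c{i:03d}",
            field_id=field_id,
            vertices=tuple(map(tuple, verts)),
            dilation_margin_px=params.dilation_margin_px,
        )
        for i, verts in enumerate(vertex_lists)
    ]
    centroids = np.array([[o.polygon.centroid.x, o.polygon.centroid.y] for o in outlines])

    assign = state_assigner or _field_state_assigner(params)
    clones, states = assign(centroids, rng)

    field_box = box(0.0, 0.0, float(meta.width_px), float(meta.height_px))
    dilated = [
        o.polygon.buffer(params.dilation_margin_px).intersection(field_box)
        if params.dilation_margin_px > 0
        else o.polygon
        for o in outlines
    ]

    cell_rows = []
    spot_records: list[tuple] = []
    sources: list[str] = []
    counts_per_channel: dict[str, np.ndarray] = {}
    for ch, model in params.expression.items():
        means = np.where(states[ch], model.on_mean_spots, model.off_mean_spots)
        counts = np.array(
            [_nb_draw(rng, m, model.overdispersion, 1)[0] for m in means], dtype=int
        )
        counts_per_channel[ch] = counts
        for i, o in enumerate(outlines):
            pts = _sample_points_in_polygon(dilated[i], counts[i], rng)
            planes = rng.integers(0, meta.n_planes, counts[i])
            for (x, y), pl in zip(pts, planes):
                spot_records.append((field_id, ch, float(x), float(y), int(pl)))
                sources.append(o.cell_id)

    n_background: dict[str, int] = {}
    for ch in params.expression:
        n_bg = int(rng.poisson(params.background_spot_rate * meta.volume_um3))
        n_background[ch] = n_bg
        xs = rng.uniform(0, meta.width_px, n_bg)
        ys = rng.uniform(0, meta.height_px, n_bg)
        planes = rng.integers(0, meta.n_planes, n_bg)
        for x, y, pl in zip(xs, ys, planes):
            spot_records.append((field_id, ch, float(x), float(y), int(pl)))
            sources.append("")

    for i, o in enumerate(outlines):
        row = {
            "cell_id": o.cell_id,
            "field_id": field_id,
            "clone": int(clones[i]),
            "centroid_x_px": centroids[i, 0],
            "centroid_y_px": centroids[i, 1],
            "nucleus_area_um2": o.area_px2 * px_um**2,
        }
        for ch in params.expression:
            row[f"{ch}_state"] = bool(states[ch][i])
            row[f"{ch}_count"] = int(counts_per_channel[ch][i])
        cell_rows.append(row)

    spots = pd.DataFrame(
        spot_records, columns=["field_id", "channel", "x_px", "y_px", "plane"]
    )
    truth = SyntheticTruth(
        cells=pd.DataFrame(cell_rows),
        spot_source=np.array(sources, dtype=object),
        n_background=n_background,
    )
    return FovBundle(meta=meta, outlines=outlines, spots=spots, truth=truth)


def simulate_case(
    params: SimulationParams,
    n_fov: int,
    seed: int | np.random.SeedSequence = 0,
    case_id: str = "case_0",
) -> CaseBundle:
    """Simulate ``n_fov`` independent fields sharing case-level parameters.

    Spatial pattern interpretation at case level: ``homogeneous`` draws one
    expression state per channel for the whole case; ``mixed`` assigns states
    i.i.d. per cell; ``segregated`` lays Voronoi clone patches over a virtual
    mosaic of all the case's fields so that whole fields tend to be 'hot' or
    'cold'; ``gradient`` raises the on-probability linearly along x within
    each field.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    case_rng_seed, *fov_seeds = ss.spawn(n_fov + 1)
    case_rng = np.random.default_rng(case_rng_seed)

    assigner: StateAssigner | None = None
    if params.spatial_pattern == "homogeneous":
        case_states = {
            ch: (m.mode == "unimodal") or (case_rng.random() < m.on_fraction)
            for ch, m in params.expression.items()
        }

        def assigner(centroids, rng, _states=case_states):  # noqa: F811
            n = len(centroids)
            return np.zeros(n, dtype=int), {
                ch: np.full(n, on, dtype=bool) for ch, on in _states.items()
            }

    elif params.spatial_pattern == "segregated":
        ncols = int(math.ceil(math.sqrt(n_fov)))
        n_patches = max(params.n_clones, int(math.ceil(n_fov / 2)))
        patch_xy = np.column_stack(
            [
                case_rng.uniform(0, ncols * params.width_px, n_patches),
                case_rng.uniform(0, math.ceil(n_fov / ncols) * params.height_px, n_patches),
            ]
        )
        patch_clone = case_rng.permutation(
            np.arange(n_patches) % params.n_clones
        )
        clone_on = {
            ch: (np.ones(params.n_clones, dtype=bool) if m.mode == "unimodal"
                 else _clone_states(params.n_clones, m.on_fraction))
            for ch, m in params.expression.items()
        }
        fov_origin: dict[int, np.ndarray] = {
            k: np.array([(k % ncols) * params.width_px, (k // ncols) * params.height_px])
            for k in range(n_fov)
        }
        current_fov = {"k": 0}

        def assigner(centroids, rng):  # noqa: F811
            origin = fov_origin[current_fov["k"]]
            gpos = centroids + origin
            d = np.linalg.norm(gpos[:, None, :] - patch_xy[None, :, :], axis=2)
            clones = patch_clone[np.argmin(d, axis=1)]
            states = {ch: on[clones] for ch, on in clone_on.items()}
            return clones, states

    fovs = []
    for k in range(n_fov):
        if params.spatial_pattern == "segregated":
            current_fov["k"] = k
        fovs.append(
            simulate_fov(
                params,
                seed=np.random.default_rng(fov_seeds[k]),
                field_id=f"{case_id}_fov{k:03d}",
                case_id=case_id,
                state_assigner=assigner,
            )
        )
    return CaseBundle(case_id=case_id, params=params, fovs=fovs)


# ---------------------------------------------------------------------------
# Cohorts


def _default_channel_specs() -> dict[str, "ChannelCohortSpec"]:
    # Defaults are calibrated so that, with the standard scoring settings
    # (13 x 13 grid with >= 3 dots for HER2; >= 1 dot for ER), positive and
    # negative group mean pseudo-cell densities land near 0.13 vs 0.04
    # dots/um^3 for HER2 and 0.04 vs 0.02 dots/um^3 for ER.
    return {
        "HER2": ChannelCohortSpec(
            positive=ExpressionModel(on_fraction=0.8, on_mean_spots=58.0, off_mean_spots=2.5),
            negative=ExpressionModel(on_fraction=0.015, on_mean_spots=58.0, off_mean_spots=2.5),
        ),
        "ER": ChannelCohortSpec(
            positive=ExpressionModel(on_fraction=0.7, on_mean_spots=30.0, off_mean_spots=4.0),
            negative=ExpressionModel(on_fraction=0.04, on_mean_spots=30.0, off_mean_spots=4.0),
        ),
    }


@dataclass(frozen=True)
class ChannelCohortSpec:
    """Expression models used for positive and negative cases of one channel."""

    positive: ExpressionModel
    negative: ExpressionModel


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and per-channel group-level expression targets."""

    n_positive: int = 20
    n_negative: int = 20
    n_fov_per_case: int = 32
    channels: Mapping[str, ChannelCohortSpec] = field(default_factory=_default_channel_specs)
    base_params: SimulationParams = field(default_factory=SimulationParams)
    case_level_sigma: float = 0.25  # lognormal sd of per-case mean multiplier

    @property
    def n_cases(self) -> int:
        return self.n_positive + self.n_negative


@dataclass
class Cohort:
    spec: CohortSpec
    cases: list[CaseBundle]
    records: dict[str, CaseRecord]
    positive: dict[str, dict[str, bool]]  # channel -> case_id -> label


def _cohort_labels(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Deterministic per-channel positive/negative assignment.

    Channel j's positive block is rotated by ``j * n_cases // 2`` so that
    channels do not share an identical label vector (with two channels the
    HER2-positive half is ER-negative, mimicking HER2-enriched vs luminal
    disease) while every channel keeps exactly ``n_positive`` positives.
    """
    n = spec.n_cases
    labels = {}
    for j, ch in enumerate(spec.channels):
        shift = (j * (n // 2)) % max(n, 1)
        idx = (np.arange(n) + shift) % n
        labels[ch] = idx < spec.n_positive
    return labels


def simulate_cohort(spec: CohortSpec, seed: int = 0) -> Cohort:
    """Generate a cohort of positive/negative cases with reference labels.

    Case-to-case biological variability is injected by scaling each case's
    channel means with an independent lognormal multiplier
    (sigma = ``case_level_sigma``). Reference :class:`CaseRecord` labels are
    constructed to be consistent with the generated channel status (IHC 3+
    amplified for HER2-positive, 1+ non-amplified otherwise; ER 80% vs 0%).
    """
    ss = np.random.SeedSequence(seed)
    label_by_channel = _cohort_labels(spec)
    mult_rng = np.random.default_rng(ss.spawn(1)[0])
    case_seeds = ss.spawn(spec.n_cases)

    cases: list[CaseBundle] = []
    records: dict[str, CaseRecord] = {}
    positive: dict[str, dict[str, bool]] = {ch: {} for ch in spec.channels}
    for k in range(spec.n_cases):
        case_id = f"case_{k:03d}"
        expression = {}
        for ch, chspec in spec.channels.items():
            model = chspec.positive if label_by_channel[ch][k] else chspec.negative
            m = mult_rng.lognormal(mean=0.0, sigma=spec.case_level_sigma)
            expression[ch] = replace(
                model,
                on_mean_spots=model.on_mean_spots * m,
                off_mean_spots=model.off_mean_spots * m,
            )
            positive[ch][case_id] = bool(label_by_channel[ch][k])
        params = replace(spec.base_params, expression=expression)
        cases.append(
            simulate_case(params, spec.n_fov_per_case, seed=case_seeds[k], case_id=case_id)
        )
        her2_pos = positive.get("HER2", {}).get(case_id, False)
        er_pos = positive.get("ER", {}).get(case_id, False)
        records[case_id] = CaseRecord(
            case_id=case_id,
            her2_ihc="3+" if her2_pos else "1+",
            her2_amplified=her2_pos,
            er_percent=80.0 if er_pos else 0.0,
            pr_percent=30.0 if er_pos else 5.0,
            ki67_percent=20.0,
        )
    return Cohort(spec=spec, cases=cases, records=records, positive=positive)


# ---------------------------------------------------------------------------
# Image rendering


def render_spot_stack(
    spots: pd.DataFrame,
    meta: FieldOfViewMeta,
    psf_sigma_px: float = 1.3,
    amplitude: float = 200.0,
    background: float = 100.0,
    poisson_noise: bool = True,
    read_noise_sd: float = 2.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render spots of one channel as 2-D Gaussians on their focal planes.

    Returns a float ``(n_planes, height, width)`` stack. Each spot adds an
    isotropic Gaussian of peak ``amplitude`` and width ``psf_sigma_px`` to
    its plane; the noise model is Poisson shot noise on the expected photon
    image plus additive Gaussian read noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stack = np.full((meta.n_planes, meta.height_px, meta.width_px), float(background))
    r = int(math.ceil(5 * psf_sigma_px))
    for _, row in spots.iterrows():
        x, y, plane = float(row["x_px"]), float(row["y_px"]), int(row["plane"])
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - r, 0), min(cx + r + 1, meta.width_px)
        y0, y1 = max(cy - r, 0), min(cy + r + 1, meta.height_px)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        gx = np.exp(-((xs - x) ** 2) / (2 * psf_sigma_px**2))
        gy = np.exp(-((ys - y) ** 2) / (2 * psf_sigma_px**2))
        stack[plane, y0:y1, x0:x1] += amplitude * np.outer(gy, gx)
    if poisson_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    if read_noise_sd > 0:
        stack = stack + rng.normal(0.0, read_noise_sd, stack.shape)
    return stack


def render_nuclei_image(
    outlines: Sequence[CellOutline],
    meta: FieldOfViewMeta,
    amplitude: float = 400.0,
    background: float = 100.0,
    texture_sd: float = 0.35,
    texture_scale_px: float = 1.5,
    poisson_noise: bool = True,
    read_noise_sd: float = 2.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render a DAPI-like 2-D image from filled nucleus polygons.

    Nuclei are filled at ``amplitude`` and modulated by a smoothed lognormal
    texture field emulating chromatin granularity, so that local intensity
    structure is high inside nuclei — the property the structure-tensor
    region detector keys on.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.draw import polygon as draw_polygon

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.full((meta.height_px, meta.width_px), float(background))
    inside = np.zeros(img.shape, dtype=bool)
    for o in outlines:
        verts = np.asarray(o.vertices)
        rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=img.shape)
        inside[rr, cc] = True
    if texture_sd > 0:
        noise = rng.normal(0.0, 1.0, img.shape)
        noise = gaussian_filter(noise, texture_scale_px)
        noise = noise / max(noise.std(), 1e-12)
        texture = np.exp(texture_sd * noise - texture_sd**2 / 2)
    else:
        texture = np.ones(img.shape)
    img[inside] += amplitude * texture[inside]
    if poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if read_noise_sd > 0:
        img = img + rng.normal(0.0, read_noise_sd, img.shape)
    return img
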