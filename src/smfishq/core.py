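"""Domain types, coordinate conventions, clinical label rules, and file I/O.

Coordinate convention used throughout the package: 0-based, ``x`` is the
column index (increases rightward), ``y`` is the row index (increases
downward), both continuous with pixel centers at integer coordinates.
Focal-plane indices are 0-based; the physical z position of plane ``k`` is
``k * plane_spacing_um`` micrometers.

Tabular data (spots, field metadata, case records, per-cell results) is
stored as UTF-8 CSV with a mandatory header row. Nucleus outlines are stored
as JSON, one record per cell; GeoJSON-style polygon geometry is accepted on
input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "FormatError",
    "ValidationError",
    "FieldOfViewMeta",
    "CellOutline",
    "CaseRecord",
    "SPOT_COLUMNS",
    "SUBTYPES",
    "HER2_IHC_SCORES",
    "validate_spot_table",
    "load_spot_table",
    "write_spot_table",
    "load_cell_outlines",
    "write_cell_outlines",
    "load_fov_table",
    "write_fov_table",
    "load_case_table",
    "write_case_table",
    "derive_positivity",
    "derive_subtype",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout (missing columns, bad JSON)."""


class ValidationError(ValueError):
    """Well-formed data violates a domain invariant (bounds, geometry, labels)."""


#: Required columns of a spot table; ``intensity`` is optional.
SPOT_COLUMNS = ("field_id", "channel", "x_px", "y_px", "plane")

HER2_IHC_SCORES = ("0", "1+", "2+", "3+")

SUBTYPES = ("LumA", "LumB/HER2-neg", "LumB/HER2-pos", "HER2", "Triple-neg")


@dataclass(frozen=True)
class FieldOfViewMeta:
    """Geometry of one imaged field of view.

    Parameters
    ----------
    field_id
        Unique identifier of the field.
    width_px, height_px
        Image size in pixels.
    pixel_size_nm
        Lateral pixel size in nanometers (125 nm at 100X in the default
        acquisition setup).
    n_planes
        Number of focal planes in the z-stack (>= 2, since the imaged depth
        is ``(n_planes - 1) * plane_spacing_um``).
    plane_spacing_um
        Distance between adjacent focal planes in micrometers.
    case_id
        Identifier of the tumor/case this field belongs to.
    """

    field_id: str
    width_px: int = 1024
    height_px: int = 1024
    pixel_size_nm: float = 125.0
    n_planes: int = 5
    plane_spacing_um: float = 0.4
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValidationError("image dimensions must be >= 1 px")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")
        if self.n_planes < 2:
            raise ValidationError("n_planes must be >= 2")
        if self.plane_spacing_um <= 0:
            raise ValidationError("plane_spacing_um must be positive")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def depth_um(self) -> float:
        """Imaged axial depth: (number of planes - 1) x plane spacing."""
        return (self.n_planes - 1) * self.plane_spacing_um

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_size_um

    @property
    def volume_um3(self) -> float:
        """Imaged prism volume of the whole field in cubic micrometers."""
        return self.width_um * self.height_um * self.depth_um


@dataclass(frozen=True)
class CellOutline:
    """Nucleus segmentation polygon of one cell plus its dilation margin.

    The polygon approximates the nucleus boundary; dilating it by
    ``dilation_margin_px`` (Euclidean buffer) yields an approximate cell
    boundary that captures cytoplasmic transcripts.
    """

    cell_id: str
    field_id: str
    vertices: tuple[tuple[float, float], ...]
    dilation_margin_px: float = 0.0

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValidationError(
                f"cell {self.cell_id!r}: polygon needs >= 3 vertices"
            )
        if self.dilation_margin_px < 0:
            raise ValidationError("dilation margin must be non-negative")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValidationError(
                f"cell {self.cell_id!r}: polygon is self-intersecting or degenerate"
            )
        if poly.area <= 0:
            raise ValidationError(f"cell {self.cell_id!r}: polygon has zero area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_px2(self) -> float:
        return self.polygon.area

    def area_um2(self, meta: FieldOfViewMeta) -> float:
        return self.area_px2 * meta.pixel_size_um**2

    def with_margin(self, margin_px: float) -> "CellOutline":
        return replace(self, dilation_margin_px=margin_px)


@dataclass
class CaseRecord:
    """Clinical reference labels of one case and its derived classification.

    ``her2_ihc`` is the ordinal immunohistochemistry score (0/1+/2+/3+);
    ``her2_amplified`` is the DNA FISH result. ER/PR/Ki67 are percentages of
    positive nuclei. ``smfish_score`` maps channel name to the per-case
    transcript density in dots/um^3 once computed.
    """

    case_id: str
    her2_ihc: str
    her2_amplified: bool
    er_percent: float
    pr_percent: float
    ki67_percent: float
    smfish_score: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.her2_ihc not in HER2_IHC_SCORES:
            raise ValidationError(
                f"case {self.case_id!r}: her2_ihc must be one of {HER2_IHC_SCORES}"
            )
        for name in ("er_percent", "pr_percent", "ki67_percent"):
            v = getattr(self, name)
            if v is None or not (0.0 <= float(v) <= 100.0):
                raise ValidationError(
                    f"case {self.case_id!r}: {name} must be in [0, 100], got {v!r}"
                )

    @property
    def her2_positive(self) -> bool:
        return derive_positivity(self)[0]

    @property
    def er_positive(self) -> bool:
        return derive_positivity(self)[1]

    @property
    def subtype(self) -> str:
        return derive_subtype(self)


def derive_positivity(record: CaseRecord) -> tuple[bool, bool]:
    """HER2/ER positivity per ASCO/CAP-style rules.

    HER2-positive: IHC 3+, or IHC 2+ with DNA-FISH amplification.
    ER-positive: >= 1% positive nuclei.
    """
    her2 = record.her2_ihc == "3+" or (
        record.her2_ihc == "2+" and record.her2_amplified
    )
    er = record.er_percent >= 1.0
    return her2, er


def derive_subtype(record: CaseRecord) -> str:
    """St. Gallen IHC surrogate molecular subtype.

    Triple-negative: ER-/PR-/HER2-. HER2: ER-/HER2+. Luminal B/HER2-pos:
    ER+/HER2+. Luminal B/HER2-neg: ER+/HER2- with Ki67 > 14% and/or
    PR < 20%. Luminal A otherwise (ER+/PR+/HER2-/Ki67-low, where Ki67-low
    means <= 14%).
    """
    her2_pos, er_pos = derive_positivity(record)
    pr_pos = record.pr_percent > 20.0
    if not er_pos and not pr_pos and not her2_pos:
        return "Triple-neg"
    if not er_pos and her2_pos:
        return "HER2"
    if er_pos and her2_pos:
        return "LumB/HER2-pos"
    if er_pos and not her2_pos and (record.ki67_percent > 14.0 or record.pr_percent < 20.0):
        return "LumB/HER2-neg"
    return "LumA"


# ---------------------------------------------------------------------------
# Spot tables


def validate_spot_table(
    df: pd.DataFrame, fovs: Mapping[str, FieldOfViewMeta]
) -> pd.DataFrame:
    """Check a spot table against its fields' geometry.

    Every referenced ``field_id`` must exist in ``fovs``; coordinates must lie
    in ``[0, width) x [0, height)`` and plane indices in ``[0, n_planes)``.
    Raises :class:`ValidationError` listing the offending row indices.
    """
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spot table is missing columns: {missing}")
    bad_rows: list[str] = []
    unknown = set(df["field_id"].astype(str)) - set(fovs)
    if unknown:
        raise ValidationError(f"spot table references unknown fields: {sorted(unknown)}")
    for idx, row in df.iterrows():
        meta = fovs[str(row["field_id"])]
        x, y, plane = float(row["x_px"]), float(row["y_px"]), int(row["plane"])
        if not (0 <= x < meta.width_px and 0 <= y < meta.height_px):
            bad_rows.append(f"row {idx}: coordinate ({x}, {y}) outside field bounds")
        if not (0 <= plane < meta.n_planes):
            bad_rows.append(f"row {idx}: plane {plane} outside [0, {meta.n_planes})")
    if bad_rows:
        raise ValidationError("spot table bound violations:\n" + "\n".join(bad_rows))
    out = df.copy()
    out["field_id"] = out["field_id"].astype(str)
    out["channel"] = out["channel"].astype(str)
    out["plane"] = out["plane"].astype(int)
    out[["x_px", "y_px"]] = out[["x_px", "y_px"]].astype(float)
    return out


def load_spot_table(
    path: str | Path, fovs: Mapping[str, FieldOfViewMeta]
) -> pd.DataFrame:
    """Read a spot CSV and validate it against the field registry."""
    df = pd.read_csv(path)
    return validate_spot_table(df, fovs)


def write_spot_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in df.columns if c in SPOT_COLUMNS or c == "intensity"]
    df.to_csv(path, index=False, columns=cols)


# ---------------------------------------------------------------------------
# Cell outlines (JSON)


def _vertices_from_record(rec: dict) -> list[tuple[float, float]]:
    if "vertices" in rec:
        verts = [(float(x), float(y)) for x, y in rec["vertices"]]
    elif "geometry" in rec:  # GeoJSON-style polygon
        geom = rec["geometry"]
        if geom.get("type") != "Polygon":
            raise FormatError(f"unsupported geometry type {geom.get('type')!r}")
        ring = geom["coordinates"][0]
        verts = [(float(x), float(y)) for x, y in ring]
        if len(verts) > 1 and verts[0] == verts[-1]:
            verts = verts[:-1]  # drop GeoJSON ring closure
    else:
        raise FormatError("outline record has neither 'vertices' nor 'geometry'")
    return verts


def load_cell_outlines(path: str | Path) -> list[CellOutline]:
    """Read nucleus outlines from a JSON file (list of per-cell records)."""
    with open(path, encoding="utf-8") as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise FormatError("outline file must contain a JSON array of records")
    outlines = []
    for rec in records:
        outlines.append(
            CellOutline(
                cell_id=str(rec["cell_id"]),
                field_id=str(rec["field_id"]),
                vertices=tuple(map(tuple, _vertices_from_record(rec))),
                dilation_margin_px=float(rec.get("dilation_margin_px", 0.0)),
            )
        )
    return outlines


def write_cell_outlines(outlines: Iterable[CellOutline], path: str | Path) -> None:
    records = [
        {
            "cell_id": o.cell_id,
            "field_id": o.field_id,
            "vertices": [[x, y] for x, y in o.vertices],
            "dilation_margin_px": o.dilation_margin_px,
        }
        for o in outlines
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=1)


# ---------------------------------------------------------------------------
# Field and case metadata (CSV)

_FOV_COLUMNS = (
    "field_id",
    "width_px",
    "height_px",
    "pixel_size_nm",
    "n_planes",
    "plane_spacing_um",
    "case_id",
)


def load_fov_table(path: str | Path) -> dict[str, FieldOfViewMeta]:
    df = pd.read_csv(path)
    missing = [c for c in _FOV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"field table is missing columns: {missing}")
    fovs: dict[str, FieldOfViewMeta] = {}
    for _, row in df.iterrows():
        meta = FieldOfViewMeta(
            field_id=str(row["field_id"]),
            width_px=int(row["width_px"]),
            height_px=int(row["height_px"]),
            pixel_size_nm=float(row["pixel_size_nm"]),
            n_planes=int(row["n_planes"]),
            plane_spacing_um=float(row["plane_spacing_um"]),
            case_id=str(row["case_id"]),
        )
        if meta.field_id in fovs:
            raise ValidationError(f"duplicate field_id {meta.field_id!r}")
        fovs[meta.field_id] = meta
    return fovs


def write_fov_table(fovs: Mapping[str, FieldOfViewMeta] | Iterable[FieldOfViewMeta], path: str | Path) -> None:
    items = fovs.values() if isinstance(fovs, Mapping) else fovs
    rows = [{c: getattr(m, c) for c in _FOV_COLUMNS} for m in items]
    pd.DataFrame(rows, columns=list(_FOV_COLUMNS)).to_csv(path, index=False)


_CASE_COLUMNS = (
    "case_id",
    "her2_ihc",
    "her2_amplified",
    "er_percent",
    "pr_percent",
    "ki67_percent",
)

_TRUTHY = {"true", "1", "yes", "amp", "amplified"}
_FALSY = {"false", "0", "no", "not amp", "notamp", "not_amplified"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise FormatError(f"cannot interpret {value!r} as a boolean")


def load_case_table(path: str | Path) -> dict[str, CaseRecord]:
    df = pd.read_csv(path, dtype={"her2_ihc": str})
    missing = [c for c in _CASE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"case table is missing columns: {missing}")
    cases: dict[str, CaseRecord] = {}
    for _, row in df.iterrows():
        rec = CaseRecord(
            case_id=str(row["case_id"]),
            her2_ihc=str(row["her2_ihc"]).strip(),
            her2_amplified=_parse_bool(row["her2_amplified"]),
            er_percent=float(row["er_percent"]),
            pr_percent=float(row["pr_percent"]),
            ki67_percent=float(row["ki67_percent"]),
        )
        if rec.case_id in cases:
            raise ValidationError(f"duplicate case_id {rec.case_id!r}")
        cases[rec.case_id] = rec
    return cases


def write_case_table(
    cases: Mapping[str, CaseRecord] | Iterable[CaseRecord], path: str | Path
) -> None:
    items = cases.values() if isinstance(cases, Mapping) else cases
    rows = []
    for rec in items:
        row = {c: getattr(rec, c) for c in _CASE_COLUMNS}
        row["her2_positive"] = rec.her2_positive
        row["er_positive"] = rec.er_positive
        row["subtype"] = rec.subtype
        for channel, score in sorted(rec.smfish_score.items()):
            row[f"smfish_score_{channel}"] = score
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
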