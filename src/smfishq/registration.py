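"""Affine registration of high-magnification fields onto tissue scans.

The chain has two stages. A1 places each high-magnification (100X) field
into the stitched lower-magnification (40X) scan: the field is downscaled to
the scan's pixel size and located by normalized cross-correlation, so A1 is
a pure scaling followed by a translation to the correlation peak. A2 maps
the 40X scan onto the 10X H&E scan from a few manually selected reference
point pairs by least-squares affine fitting. Spot coordinates are carried
through as homogeneous 2-D points: D' = A2 A1 D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template
from skimage.transform import rescale

from .core import ValidationError

__all__ = [
    "AffineTransform",
    "RegistrationResult",
    "register_highmag",
    "fit_affine",
    "map_spots",
]


@dataclass(frozen=True)
class AffineTransform:
    """2-D affine transform as a 3 x 3 homogeneous matrix acting on (x, y)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError("affine matrix must be 3 x 3")
        if not np.allclose(m[2], [0.0, 0.0, 1.0]):
            raise ValidationError("bottom row of an affine matrix must be (0, 0, 1)")
        if abs(np.linalg.det(m[:2, :2])) < 1e-12:
            raise ValidationError("affine matrix is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3))

    @classmethod
    def from_scale_translation(
        cls, scale: float, tx: float, ty: float
    ) -> "AffineTransform":
        m = np.array([[scale, 0.0, tx], [0.0, scale, ty], [0.0, 0.0, 1.0]])
        return cls(m)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: returns the transform applying other first."""
        return AffineTransform(self.matrix @ other.matrix)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array of (x, y) points."""
        pts = np.asarray(points, dtype=float)
        squeeze = pts.ndim == 1
        pts = np.atleast_2d(pts)
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = (self.matrix @ hom.T).T[:, :2]
        return out[0] if squeeze else out


@dataclass(frozen=True)
class RegistrationResult:
    transform: AffineTransform
    correlation: float  # NCC peak value, the placement confidence
    low_confidence: bool


def register_highmag(
    fov_image: np.ndarray,
    scan_image: np.ndarray,
    scale_ratio: float,
    confidence_floor: float = 0.5,
) -> RegistrationResult:
    """Place a high-magnification field inside a lower-magnification scan.

    ``scale_ratio`` is scan pixels per field pixel (= field pixel size /
    scan pixel size; < 1 downscales the field). The rescaled field is slid
    over the scan with normalized cross-correlation (zero-mean, unit-
    variance within the template support); the returned transform maps field
    pixel coordinates to scan pixel coordinates via scaling then translation
    to the correlation peak. Peaks below ``confidence_floor`` are flagged.
    """
    fov = np.asarray(fov_image, dtype=float)
    scan = np.asarray(scan_image, dtype=float)
    if fov.ndim != 2 or scan.ndim != 2:
        raise ValidationError("both images must be 2-D")
    if scale_ratio <= 0:
        raise ValidationError("scale_ratio must be positive")
    template = rescale(fov, scale_ratio, anti_aliasing=scale_ratio < 1, order=1)
    if template.shape[0] > scan.shape[0] or template.shape[1] > scan.shape[1]:
        raise ValidationError("rescaled field is larger than the scan")
    ncc = match_template(scan, template, pad_input=False)
    peak = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    corr = float(ncc[peak])
    ty, tx = float(peak[0]), float(peak[1])
    transform = AffineTransform.from_scale_translation(scale_ratio, tx, ty)
    return RegistrationResult(transform, corr, corr < confidence_floor)


def fit_affine(
    source_points: np.ndarray, target_points: np.ndarray
) -> tuple[AffineTransform, float]:
    """Least-squares affine from >= 3 non-collinear point pairs.

    Minimizes sum ||A p - q||^2 over the six affine parameters; returns the
    transform and the RMS residual in target pixels.
    """
    p = np.asarray(source_points, dtype=float)
    q = np.asarray(target_points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape != q.shape:
        raise ValidationError("point arrays must both be (n, 2)")
    if len(p) < 3:
        raise ValidationError("affine fit needs at least 3 point pairs")
    design = np.column_stack([p, np.ones(len(p))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValidationError("point pairs are collinear; affine fit is degenerate")
    coef, *_ = np.linalg.lstsq(design, q, rcond=None)
    m = np.eye(3)
    m[:2, :] = coef.T
    transform = AffineTransform(m)
    residual = transform.apply(p) - q
    rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1)))) if len(p) else 0.0
    return transform, rms


def map_spots(
    spots_xy: np.ndarray, a1: AffineTransform, a2: AffineTransform
) -> np.ndarray:
    """Carry spot coordinates through the two-stage chain: A2 applied after A1."""
    return a2.compose(a1).apply(np.asarray(spots_xy, dtype=float))
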