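"""Reference-chart polynomial color correction and CIELAB conversion.

A 24-patch reference chart photographed with the subject is used to
estimate a quadratic polynomial map from the camera's RGB values to the
chart's known target values.  Per output channel the model is

    c' = a0 + a1*R + a2*G + a3*B + a4*RG + a5*GB + a6*RB
            + a7*R^2 + a8*G^2 + a9*B^2

fitted by minimum-norm least squares (pseudoinverse) over the 24 patches
and applied pixel-wise to the whole image, which is then converted to
CIELAB (sRGB primaries, D65 white, 2 degree observer).

All images are H x W x 3 float arrays with channels in [0, 1]; 8-bit
images are divided by 255 on load.  The polynomial family is not scale
invariant in its quadratic terms, so the [0, 1] convention is part of the
model contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.transform import ProjectiveTransform

from .errors import DataError, GeometryError

#: Order of the 10 polynomial basis terms (rows of the coefficient table).
TERM_ORDER = ("1", "R", "G", "B", "RG", "GB", "RB", "R2", "G2", "B2")

#: Relative singular-value cutoff for the pseudoinverse fit.
PINV_RCOND = 1e-10


def _as_image(pixels) -> np.ndarray:
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DataError(f"expected an H x W x 3 image, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ChartLayout:
    """Placement of the 4 x 6 reference chart inside an image.

    ``quad`` holds the four chart corners in pixel coordinates (x, y),
    ordered top-left, top-right, bottom-right, bottom-left of the chart's
    own frame.  Supplying the corners in a rotated cyclic order rotates
    the sampled patch order accordingly (an upside-down chart yields the
    colors in reversed row-major order).
    """

    quad: np.ndarray
    rows: int = 4
    cols: int = 6
    center_fraction: float = 0.5

    def __post_init__(self):
        quad = np.asarray(self.quad, dtype=float)
        if quad.shape != (4, 2) or not np.all(np.isfinite(quad)):
            raise GeometryError("quad must be four finite (x, y) points")
        object.__setattr__(self, "quad", quad)
        if self.rows * self.cols != 24:
            raise GeometryError("chart must have 24 patches (rows * cols)")
        if not 0.0 < self.center_fraction <= 1.0:
            raise GeometryError("center_fraction must lie in (0, 1]")
        poly = _ShapelyPolygon(quad)
        if not poly.is_valid or poly.area <= 0.0:
            raise GeometryError("quad is degenerate or self-intersecting")


@dataclass(frozen=True)
class TargetChart:
    """The 24 known (target) chart colors, row-major over the 4 x 6 grid."""

    colors: np.ndarray

    def __post_init__(self):
        colors = np.asarray(self.colors, dtype=float)
        if colors.shape != (24, 3):
            raise DataError(f"target chart needs 24 RGB triples, got {colors.shape}")
        if not np.all(np.isfinite(colors)):
            raise DataError("target chart contains non-finite values")
        if colors.min() < 0.0 or colors.max() > 1.0:
            raise DataError("target chart values must lie in [0, 1]")
        object.__setattr__(self, "colors", colors)


@dataclass(frozen=True)
class PatchSampleSet:
    """Mean RGB of each patch's central region, row-major over the grid."""

    samples: np.ndarray

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.shape != (24, 3):
            raise DataError(f"expected 24 sampled triples, got {samples.shape}")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class PolynomialCorrectionModel:
    """10 x 3 coefficient table; columns are corrected R, G, B.

    Row order follows :data:`TERM_ORDER`.
    """

    coefficients: np.ndarray
    term_order: tuple = field(default=TERM_ORDER)

    def __post_init__(self):
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (10, 3):
            raise DataError(f"coefficient table must be 10 x 3, got {coef.shape}")
        if not np.all(np.isfinite(coef)):
            raise DataError("coefficient table contains non-finite values")
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "term_order", tuple(self.term_order))

    @classmethod
    def identity(cls) -> "PolynomialCorrectionModel":
        coef = np.zeros((10, 3))
        coef[1, 0] = coef[2, 1] = coef[3, 2] = 1.0
        return cls(coef)


def expand_polynomial(rgb) -> np.ndarray:
    """Expand RGB values into the 10 polynomial basis terms.

    Accepts a single triple or any (..., 3) array; returns (..., 10) in
    the order [1, R, G, B, RG, GB, RB, R^2, G^2, B^2].
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise DataError("last axis must hold R, G, B")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    return np.stack(
        [np.ones_like(r), r, g, b, r * g, g * b, r * b, r * r, g * g, b * b],
        axis=-1,
    )


def sample_chart_patches(image, layout: ChartLayout, grid_points: int = 8) -> PatchSampleSet:
    """Sample the mean color of each patch's central region.

    The chart quad is rectified by a projective map onto a ``cols x rows``
    grid; for each cell the central ``center_fraction``-sized sub-square is
    sampled on a ``grid_points x grid_points`` lattice (bilinear
    interpolation) and averaged.  Patches are returned row-major.
    """
    img = _as_image(image)
    h, w = img.shape[:2]
    quad = layout.quad
    if (quad[:, 0].min() < 0 or quad[:, 0].max() > w
            or quad[:, 1].min() < 0 or quad[:, 1].max() > h):
        raise GeometryError("chart quad extends outside the image bounds")

    src = np.array(
        [[0, 0], [layout.cols, 0], [layout.cols, layout.rows], [0, layout.rows]],
        dtype=float,
    )
    tform = ProjectiveTransform.from_estimate(src, quad)
    if not tform:
        raise GeometryError("could not estimate projective map for quad")

    f = layout.center_fraction
    # offsets of the sampling lattice within a unit cell, centred
    t = (np.arange(grid_points) + 0.5) / grid_points  # in (0, 1)
    off = (t - 0.5) * f
    ou, ov = np.meshgrid(off, off, indexing="xy")

    samples = np.empty((24, 3))
    k = 0
    for r in range(layout.rows):
        for c in range(layout.cols):
            u = (c + 0.5) + ou
            v = (r + 0.5) + ov
            pts = tform(np.column_stack([u.ravel(), v.ravel()]))
            # map_coordinates expects (row, col) = (y, x); pixel centres at +0.5
            coords = np.vstack([pts[:, 1] - 0.5, pts[:, 0] - 0.5])
            for ch in range(3):
                vals = map_coordinates(img[:, :, ch], coords, order=1, mode="nearest")
                samples[k, ch] = vals.mean()
            k += 1
    return PatchSampleSet(samples)


def fit_correction(samples: PatchSampleSet, target: TargetChart) -> PolynomialCorrectionModel:
    """Fit the quadratic correction by minimum-norm least squares.

    Builds the 24 x 10 design from the sampled patch colors and solves
    ``coef = pinv(C) @ target`` per channel; for a rank-deficient design
    the pseudoinverse returns the least-squares solution of smallest
    Euclidean norm.
    """
    s = np.asarray(samples.samples, dtype=float)
    if not np.all(np.isfinite(s)):
        raise DataError("sampled patch colors contain non-finite values")
    design = expand_polynomial(s)  # (24, 10)
    coef = np.linalg.pinv(design, rcond=PINV_RCOND) @ target.colors
    return PolynomialCorrectionModel(coef)


def apply_correction(image, model: PolynomialCorrectionModel) -> np.ndarray:
    """Apply the polynomial model pixel-wise; output clipped to [0, 1]."""
    img = _as_image(image)
    corrected = expand_polynomial(img) @ model.coefficients
    return np.clip(corrected, 0.0, 1.0)


# sRGB (IEC 61966-2-1) linear-RGB -> XYZ matrix, D65 primaries.
_SRGB_TO_XYZ = np.array([
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
])
# Reference white taken as the matrix's own image of RGB (1, 1, 1) so
# that the gray axis maps exactly to a* = b* = 0.
_WHITE_XYZ = _SRGB_TO_XYZ @ np.ones(3)

_DELTA = 6.0 / 29.0


def rgb_to_lab(image) -> np.ndarray:
    """Convert an sRGB image (channels in [0, 1]) to CIELAB.

    Standard sRGB decoding -> linear RGB -> XYZ (D65, 2 degree
    observer) -> CIELAB.  Relative colorimetry uses the sRGB matrix's
    own white, so any gray (g, g, g) maps to a* = b* = 0 exactly and
    (1, 1, 1) to L* = 100.
    """
    img = _as_image(image)
    if img.min() < 0.0 or img.max() > 1.0:
        raise DataError("RGB channels must lie in [0, 1]")
    linear = np.where(img <= 0.04045, img / 12.92,
                      ((img + 0.055) / 1.055) ** 2.4)
    xyz = linear @ _SRGB_TO_XYZ.T
    t = xyz / _WHITE_XYZ
    f = np.where(t > _DELTA ** 3, np.cbrt(t), t / (3 * _DELTA ** 2) + 4.0 / 29.0)
    lab = np.empty_like(f)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab
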