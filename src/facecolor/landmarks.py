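"""Facial fiducial points and region-of-interest geometry.

The pipeline works from 79 named 2D points on a frontal face.  Points
1-68 follow the standard 68-point annotation (1-17 jawline, 18-27
eyebrows, 28-36 nose, 37-48 eyes, 49-68 mouth); points 69-73 trace the
upper forehead boundary left to right and 74-79 the upper eyebrow
boundaries.  All coordinates are (x, y) with x = column and y = row on
the 0-based pixel grid.

Seven skin regions are circles defined by fixed affine combinations of
landmarks and distance-proportional radii; the lip and the whole face
are closed periodic cubic-spline polygons, the whole face carrying holes
for the lip, nose tip, eyes and eyebrows.  Left/right region names
follow image coordinates: the subject's right cheek has low x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import GeometryError

#: Spline samples generated per control-point interval.
SPLINE_SAMPLES_PER_SEGMENT = 40

CIRCLE_REGION_NAMES = (
    "forehead",
    "upper_cheek_right",
    "upper_cheek_left",
    "lower_cheek_right",
    "lower_cheek_left",
    "nose",
    "chin",
)

HOLE_NAMES = ("lip_outer", "nose_tip", "eye_right", "eye_left",
              "eyebrow_right", "eyebrow_left")


@dataclass(frozen=True)
class LandmarkSet:
    """79 ordered facial fiducial points plus the host image dimensions."""

    points: np.ndarray
    image_width: int
    image_height: int
    extrapolated: bool = False

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (79, 2):
            raise GeometryError(f"expected 79 (x, y) points, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def pt(self, i: int) -> np.ndarray:
        """Return point ``i`` (1-based, matching the annotation numbering)."""
        if not 1 <= i <= 79:
            raise GeometryError(f"landmark index {i} outside 1..79")
        return self.points[i - 1]

    def pts(self, first: int, last: int) -> np.ndarray:
        """Points ``first..last`` inclusive (1-based), as an (n, 2) array."""
        if not (1 <= first <= 79 and 1 <= last <= 79):
            raise GeometryError("landmark range outside 1..79")
        if first <= last:
            return self.points[first - 1:last]
        return self.points[last - 1:first][::-1]


@dataclass(frozen=True)
class CircleROI:
    name: str
    center: np.ndarray
    radius: float

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float)
        if center.shape != (2,) or not np.all(np.isfinite(center)):
            raise GeometryError("circle center must be a finite (x, y) point")
        object.__setattr__(self, "center", center)
        if not self.radius > 0.0:
            raise GeometryError(f"circle '{self.name}' has non-positive radius")


@dataclass(frozen=True)
class PolygonROI:
    name: str
    outer: np.ndarray
    holes: tuple = field(default=())

    def __post_init__(self):
        outer = np.asarray(self.outer, dtype=float)
        if outer.ndim != 2 or outer.shape[1] != 2 or outer.shape[0] < 3:
            raise GeometryError("polygon outer boundary needs >= 3 (x, y) points")
        object.__setattr__(self, "outer", outer)
        object.__setattr__(
            self, "holes", tuple(np.asarray(h, dtype=float) for h in self.holes)
        )


@dataclass(frozen=True)
class ROIMaskSet:
    """Named boolean rasters, all of one H x W shape.

    ``masks`` carries the analysis regions (seven circles, lip, whole
    face); ``holes`` the exclusion rings cut out of the whole face.
    """

    masks: dict
    holes: dict
    height: int
    width: int


def _dist(a, b) -> float:
    return float(np.hypot(*(np.asarray(a, float) - np.asarray(b, float))))


def circle_rois(landmarks: LandmarkSet) -> list:
    """Construct the seven circular skin regions from the landmarks.

    Centers are fixed affine combinations of named points; each radius is
    a fixed multiple of the distance from the center to a named point
    (1.4 for the nose, 0.7 forehead and lower cheeks, 0.8 elsewhere).
    """
    p = landmarks.pt
    spec = {
        "forehead": ((p(20) + p(25)) / 2 + 0.2 * (p(28) - p(63)), p(22), 0.7),
        "upper_cheek_right": (0.4 * p(31) + 0.3 * (p(2) + p(3)), p(42), 0.8),
        "upper_cheek_left": (0.4 * p(31) + 0.3 * (p(15) + p(16)), p(47), 0.8),
        "lower_cheek_right": (0.25 * p(31) + 0.75 * p(5), p(5), 0.7),
        "lower_cheek_left": (0.25 * p(31) + 0.75 * p(13), p(13), 0.7),
        "nose": ((p(30) + p(31)) / 2, p(31), 1.4),
        "chin": (0.4 * p(9) + 0.6 * p(58), p(58), 0.8),
    }
    rois = []
    for name in CIRCLE_REGION_NAMES:
        center, anchor, factor = spec[name]
        radius = factor * _dist(center, anchor)
        if radius <= 0.0:
            raise GeometryError(f"region '{name}': radius collapsed to zero "
                                "(coincident landmarks)")
        rois.append(CircleROI(name, center, radius))
    return rois


def spline_closed(control_points, n_samples: int | None = None) -> np.ndarray:
    """Closed periodic cubic spline through the control points, in order.

    Parametrised uniformly by control-point index; sampled at
    ``n_samples`` parameter values (default: 40 per segment).  The curve
    passes through every control point.
    """
    pts = np.asarray(control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise GeometryError("spline needs at least 3 control points")
    m = pts.shape[0]
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    if np.any(np.all(seg == 0.0, axis=1)):
        raise GeometryError("duplicate consecutive control points")
    if n_samples is None:
        n_samples = SPLINE_SAMPLES_PER_SEGMENT * m
    if n_samples < m:
        raise GeometryError("n_samples must be at least the control point count")
    cs = CubicSpline(np.arange(m + 1), closed, bc_type="periodic", axis=0)
    t = np.arange(n_samples) * (m / n_samples)
    return cs(t)


def lip_region(landmarks: LandmarkSet) -> PolygonROI:
    """Lip annulus: outer spline through pts 49-60, inner hole 61-68."""
    outer = spline_closed(landmarks.pts(49, 60))
    inner = spline_closed(landmarks.pts(61, 68))
    annulus = _ShapelyPolygon(outer, [inner])
    if not annulus.is_valid or annulus.area <= 0.0:
        raise GeometryError("degenerate lip annulus: inner boundary must lie "
                            "strictly inside the outer boundary")
    return PolygonROI("lip", outer, (inner,))


def whole_face_region(landmarks: LandmarkSet) -> PolygonROI:
    """Whole-face polygon with exclusion holes.

    The outer loop is one closed spline through the jawline (pts 1-17)
    followed by the forehead line traversed right-to-left (pts 73-69).
    Holes: lip outer ring, nose tip (31-36), eyes (37-42, 43-48) and
    eyebrows (18-22 with 74-76, 23-27 with 77-79).
    """
    loop = np.vstack([landmarks.pts(1, 17), landmarks.pts(73, 69)])
    outer = spline_closed(loop)
    holes = tuple(
        spline_closed(ring) for ring in _hole_control_rings(landmarks).values()
    )
    return PolygonROI("whole_face", outer, holes)


def _hole_control_rings(landmarks: LandmarkSet) -> dict:
    """Control-point rings of the whole-face exclusion holes, by name."""
    return {
        "lip_outer": landmarks.pts(49, 60),
        "nose_tip": landmarks.pts(31, 36),
        "eye_right": landmarks.pts(37, 42),
        "eye_left": landmarks.pts(43, 48),
        "eyebrow_right": np.vstack([landmarks.pts(18, 22), landmarks.pts(76, 74)]),
        "eyebrow_left": np.vstack([landmarks.pts(23, 27), landmarks.pts(79, 77)]),
    }


def _contains(ring: np.ndarray, height: int, width: int) -> np.ndarray:
    """Even-odd containment of all pixel centres in one simple ring."""
    xs = np.arange(width) + 0.5
    ys = np.arange(height) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    poly = _ShapelyPolygon(ring)
    if not poly.is_valid:
        poly = poly.buffer(0)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
    return inside.reshape(height, width)


def rasterize(roi, height: int, width: int) -> np.ndarray:
    """Rasterise a circle or polygon ROI onto an H x W boolean grid.

    A pixel (r, c) belongs to a circle iff its centre (c+0.5, r+0.5) lies
    within the radius (inclusive); polygon membership is the even-odd
    rule on the pixel centre, holes removed.  Geometry beyond the image
    is cropped silently.
    """
    if height <= 0 or width <= 0:
        raise GeometryError("raster dimensions must be positive")
    if isinstance(roi, CircleROI):
        xs = np.arange(width) + 0.5
        ys = np.arange(height) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        return (gx - roi.center[0]) ** 2 + (gy - roi.center[1]) ** 2 <= roi.radius ** 2
    if isinstance(roi, PolygonROI):
        mask = _contains(roi.outer, height, width)
        for hole in roi.holes:
            mask &= ~_contains(hole, height, width)
        return mask
    raise TypeError(f"cannot rasterize {type(roi).__name__}")


def build_masks(landmarks: LandmarkSet, height: int | None = None,
                width: int | None = None) -> ROIMaskSet:
    """Rasterise every analysis region and exclusion hole for one face."""
    h = int(height if height is not None else landmarks.image_height)
    w = int(width if width is not None else landmarks.image_width)
    masks = {}
    for roi in circle_rois(landmarks):
        masks[roi.name] = rasterize(roi, h, w)
    masks["lip"] = rasterize(lip_region(landmarks), h, w)
    masks["whole_face"] = rasterize(whole_face_region(landmarks), h, w)
    holes = {
        name: _contains(spline_closed(ring), h, w)
        for name, ring in _hole_control_rings(landmarks).items()
    }
    return ROIMaskSet(masks=masks, holes=holes, height=h, width=w)


def extend_landmarks(points_68, image_width: int, image_height: int) -> LandmarkSet:
    """Extend a standard 68-point annotation to the 79-point set.

    A documented heuristic for real photographs: forehead points 69-73
    are the chin-bottom neighbourhood (pts 7-11) reflected across the
    eye line, ordered left to right; eyebrow-top points 74-79 offset the
    middle brow points (19-21, 24-26) upward by 0.3x the eyebrow-to-eye
    distance.  The output is flagged ``extrapolated``.  A 79-point input
    is passed through unchanged.
    """
    pts = np.asarray(points_68, dtype=float)
    if pts.shape == (79, 2):
        return LandmarkSet(pts, image_width, image_height)
    if pts.shape != (68, 2):
        raise GeometryError(f"expected 68 (x, y) points, got shape {pts.shape}")

    def p(i):  # 1-based accessor into the 68-point array
        return pts[i - 1]

    eye_r = pts[36:42].mean(axis=0)
    eye_l = pts[42:48].mean(axis=0)
    # reflect chin-bottom arc across the line through the eye centres
    d = eye_l - eye_r
    d = d / np.linalg.norm(d)
    forehead = []
    for i in (7, 8, 9, 10, 11):
        v = p(i) - eye_r
        refl = eye_r + 2.0 * np.dot(v, d) * d - v
        forehead.append(refl)
    forehead = np.array(sorted(forehead, key=lambda q: q[0]))

    brow_r = pts[17:22].mean(axis=0)
    brow_l = pts[22:27].mean(axis=0)
    lift_r = 0.3 * np.linalg.norm(brow_r - eye_r)
    lift_l = 0.3 * np.linalg.norm(brow_l - eye_l)
    up = np.array([0.0, -1.0])
    brow_top = [p(i) + lift_r * up for i in (19, 20, 21)]
    brow_top += [p(i) + lift_l * up for i in (24, 25, 26)]

    all_pts = np.vstack([pts, forehead, brow_top])
    return LandmarkSet(all_pts, image_width, image_height, extrapolated=True)
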