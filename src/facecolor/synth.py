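"""Synthetic fixtures for every pipeline stage.

This module generates, from code alone, everything the pipeline needs
to be exercised end to end: a 24-patch reference chart image under a
known color distortion, a schematic frontal face with exactly known
landmark coordinates and per-region colors, labeled skin/non-skin
pixel samples, and subject cohorts whose cold-pattern scores follow a
stated linear model in the color features.

The face render is deliberately schematic (ellipses and spline
polygons, flat colors): every downstream operation consumes only
colors, masks and landmark coordinates, none of which require
photorealism.  All generators are pure functions of their spec and
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .correction import (PolynomialCorrectionModel, ChartLayout, TargetChart,
                         apply_correction, expand_polynomial)
from .errors import DataError, GeometryError
from .landmarks import LandmarkSet, _contains, circle_rois, rasterize, spline_closed

# Nominal sRGB values of the classic 24-patch checker (row-major 4 x 6),
# on the 0-255 scale; divided by 255 below.  These are the widely
# published nominal colors, used here only as a self-consistent target
# table -- tests never depend on vendor-certified values.
_CHART_NOMINAL_255 = np.array([
    [115, 82, 68], [194, 150, 130], [98, 122, 157], [87, 108, 67],
    [133, 128, 177], [103, 189, 170],
    [214, 126, 44], [80, 91, 166], [193, 90, 99], [94, 60, 108],
    [157, 188, 64], [224, 163, 46],
    [56, 61, 150], [70, 148, 73], [175, 54, 60], [231, 199, 31],
    [187, 86, 149], [8, 133, 161],
    [243, 243, 242], [200, 200, 200], [160, 160, 160], [122, 122, 122],
    [85, 85, 85], [52, 52, 52],
], dtype=float)


def make_target_chart() -> TargetChart:
    """The built-in nominal 24-color target table (row-major 4 x 6)."""
    return TargetChart(_CHART_NOMINAL_255 / 255.0)


def render_chart_image(target: TargetChart | None = None, patch_size: int = 24,
                       margin: int = 8) -> tuple:
    """Render a flat-patch 4 x 6 chart image.

    Returns ``(image, layout)`` where ``layout.quad`` frames the patch
    grid exactly (axis-aligned).
    """
    if target is None:
        target = make_target_chart()
    rows, cols = 4, 6
    h = rows * patch_size + 2 * margin
    w = cols * patch_size + 2 * margin
    img = np.full((h, w, 3), 0.5)
    for r in range(rows):
        for c in range(cols):
            y0 = margin + r * patch_size
            x0 = margin + c * patch_size
            img[y0:y0 + patch_size, x0:x0 + patch_size] = target.colors[r * cols + c]
    x1, y1 = margin, margin
    x2, y2 = margin + cols * patch_size, margin + rows * patch_size
    layout = ChartLayout(quad=np.array([[x1, y1], [x2, y1], [x2, y2], [x1, y2]],
                                       dtype=float))
    return img, layout


def distort_colors(image, model: PolynomialCorrectionModel) -> np.ndarray:
    """Apply a 10-term polynomial model as a ground-truth color distortion."""
    return apply_correction(image, model)


def random_affine_distortion(rng: np.random.Generator,
                             colors: np.ndarray | None = None,
                             max_tries: int = 200) -> PolynomialCorrectionModel:
    """Random invertible affine member of the 10-term model family.

    Diagonal gains in [0.75, 1.1], small channel mixing and offsets,
    zero quadratic coefficients.  Candidates are rejected (and redrawn
    from the same stream) until every reference color stays strictly
    inside (0, 1) after distortion, so that gamut clipping never breaks
    the exact fit/correct round trip.  The affine subfamily is used
    because it is closed under inversion; see the methods note.
    """
    if colors is None:
        colors = make_target_chart().colors
    for _ in range(max_tries):
        gain = np.diag(rng.uniform(0.75, 1.1, size=3))
        mix = rng.uniform(-0.06, 0.06, size=(3, 3))
        np.fill_diagonal(mix, 0.0)
        linear = gain + mix
        offset = rng.uniform(-0.04, 0.06, size=3)
        if abs(np.linalg.det(linear)) < 1e-3:
            continue
        coef = np.zeros((10, 3))
        coef[0] = offset
        coef[1:4] = linear.T  # rows R,G,B of the basis -> columns R',G',B'
        distorted = expand_polynomial(colors) @ coef
        if distorted.min() > 0.005 and distorted.max() < 0.995:
            return PolynomialCorrectionModel(coef)
    raise RuntimeError("failed to draw a gamut-safe affine distortion")


# ---------------------------------------------------------------------------
# Schematic face rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticFaceSpec:
    """Geometry and flat colors of the schematic face render.

    Lengths are in pixels; colors are RGB triples in [0, 1].  The face
    is an ellipse centred at ``center`` with the given half axes; all
    79 landmarks are placed analytically on that geometry, so the
    returned landmark set is exact by construction.
    """

    width: int = 256
    height: int = 256
    center: tuple = (128.0, 130.0)
    face_half_width: float = 75.0
    face_half_height: float = 95.0
    skin_color: tuple = (210 / 255, 150 / 255, 120 / 255)
    lip_color: tuple = (0.75, 0.35, 0.40)
    mouth_color: tuple = (0.45, 0.20, 0.25)
    eye_color: tuple = (0.20, 0.15, 0.10)
    brow_color: tuple = (0.25, 0.18, 0.12)
    nose_tip_color: tuple = (0.60, 0.75, 0.40)
    background_color: tuple = (0.35, 0.45, 0.60)
    region_overrides: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("skin_color", "lip_color", "mouth_color", "eye_color",
                     "brow_color", "nose_tip_color", "background_color"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.shape != (3,) or c.min() < 0 or c.max() > 1:
                raise DataError(f"{name} must be an RGB triple in [0, 1]")
        cx, cy = self.center
        if (cx - self.face_half_width < 0 or cx + self.face_half_width > self.width
                or cy - self.face_half_height < 0
                or cy + self.face_half_height > self.height):
            raise GeometryError("face ellipse exceeds the image bounds")


def _face_landmarks(spec: SyntheticFaceSpec) -> np.ndarray:
    """All 79 landmark coordinates for the schematic geometry."""
    cx, cy = spec.center
    fw, fh = spec.face_half_width, spec.face_half_height

    def ellipse(theta_deg):
        t = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return np.column_stack([cx + fw * np.cos(t), cy + fh * np.sin(t)])

    pts = np.zeros((79, 2))
    # jawline 1-17 along the lower face ellipse (y grows downward)
    pts[0:17] = ellipse(180.0 - 11.25 * np.arange(17))
    # forehead boundary 69-73, left to right along the upper ellipse
    pts[68:73] = ellipse([190.0, 225.0, 270.0, 315.0, 350.0])

    def brow(x0, x1):
        xs = np.linspace(x0, x1, 5)
        ys = cy - 0.45 * fh - 0.03 * fh * np.sin(np.linspace(0, np.pi, 5))
        return np.column_stack([xs, ys])

    pts[17:22] = brow(cx - 0.62 * fw, cx - 0.22 * fw)   # right brow (low x)
    pts[22:27] = brow(cx + 0.22 * fw, cx + 0.62 * fw)   # left brow
    pts[73:76] = pts[18:21] + [0.0, -0.08 * fh]          # 74-76 above 19-21
    pts[76:79] = pts[23:26] + [0.0, -0.08 * fh]          # 77-79 above 24-26

    # nose bridge 28-31 and nostril arc 32-36
    pts[27:31] = np.column_stack([
        np.full(4, cx), cy + fh * np.array([-0.25, -0.13, -0.02, 0.10])])
    pts[31:36] = np.column_stack([
        cx + fw * np.array([-0.12, -0.06, 0.0, 0.06, 0.12]),
        cy + fh * np.array([0.14, 0.155, 0.16, 0.155, 0.14])])

    def eye(ex):
        ey = cy - 0.25 * fh
        hw, hh = 0.16 * fw, 0.07 * fh
        return np.array([
            [ex - hw, ey], [ex - hw / 2, ey - hh], [ex + hw / 2, ey - hh],
            [ex + hw, ey], [ex + hw / 2, ey + hh], [ex - hw / 2, ey + hh]])

    pts[36:42] = eye(cx - 0.42 * fw)   # right eye (low x)
    pts[42:48] = eye(cx + 0.42 * fw)   # left eye

    def mouth_ring(hw, hh, n):
        t = np.deg2rad(180.0 + 360.0 / n * np.arange(n))
        mx, my = cx, cy + 0.55 * fh
        return np.column_stack([mx + hw * np.cos(t), my + hh * np.sin(t)])

    pts[48:60] = mouth_ring(0.28 * fw, 0.08 * fh, 12)    # outer lip 49-60
    pts[60:68] = mouth_ring(0.16 * fw, 0.035 * fh, 8)    # inner lip 61-68
    return pts


#: Truth-table mapping from feature region names to rendered colors.
_POOLED_TRUTH = {
    "upper_cheek": ("upper_cheek_right", "upper_cheek_left"),
    "lower_cheek": ("lower_cheek_right", "lower_cheek_left"),
}


def render_synthetic_face(spec: SyntheticFaceSpec | None = None) -> tuple:
    """Render the schematic face.

    Returns ``(image, landmarks, region_truth, part_colors)`` where
    ``region_truth`` maps each feature region (whole_face, forehead,
    upper_cheek, lower_cheek, nose, chin, lip) to its exact rendered
    RGB color and ``part_colors`` maps part names (skin, lip, mouth,
    eye, brow, nose_tip, background, plus any overrides) to the flat
    colors used -- convenient for building labeled skin/non-skin
    training pixels.
    """
    if spec is None:
        spec = SyntheticFaceSpec()
    h, w = spec.height, spec.width
    cx, cy = spec.center
    fw, fh = spec.face_half_width, spec.face_half_height
    pts = _face_landmarks(spec)
    landmarks = LandmarkSet(pts, image_width=w, image_height=h)

    img = np.empty((h, w, 3))
    img[:] = spec.background_color

    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    face = ((gx - cx) / fw) ** 2 + ((gy - cy) / fh) ** 2 <= 1.0
    img[face] = spec.skin_color

    # per-region color overrides, painted as the circle ROIs themselves
    rois = {r.name: r for r in circle_rois(landmarks)}
    override_colors = {}
    for region, color in spec.region_overrides.items():
        names = _POOLED_TRUTH.get(region, (region,))
        for name in names:
            if name not in rois:
                raise DataError(f"unknown override region '{region}'")
            img[rasterize(rois[name], h, w)] = color
        override_colors[region] = tuple(np.asarray(color, float))

    def paint(ring, color):
        img[_contains(spline_closed(ring), h, w)] = color

    lm = landmarks
    paint(np.vstack([lm.pts(18, 22), lm.pts(76, 74)]), spec.brow_color)
    paint(np.vstack([lm.pts(23, 27), lm.pts(79, 77)]), spec.brow_color)
    paint(lm.pts(37, 42), spec.eye_color)
    paint(lm.pts(43, 48), spec.eye_color)
    paint(lm.pts(31, 36), spec.nose_tip_color)
    paint(lm.pts(49, 60), spec.lip_color)
    paint(lm.pts(61, 68), spec.mouth_color)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    skin = tuple(np.asarray(spec.skin_color, float))
    region_truth = {"whole_face": skin, "lip": tuple(np.asarray(spec.lip_color,
                                                               float))}
    for region in ("forehead", "upper_cheek", "lower_cheek", "nose", "chin"):
        region_truth[region] = override_colors.get(region, skin)

    part_colors = {"skin": skin,
                   "lip": tuple(np.asarray(spec.lip_color, float)),
                   "mouth": tuple(np.asarray(spec.mouth_color, float)),
                   "eye": tuple(np.asarray(spec.eye_color, float)),
                   "brow": tuple(np.asarray(spec.brow_color, float)),
                   "nose_tip": tuple(np.asarray(spec.nose_tip_color, float)),
                   "background": tuple(np.asarray(spec.background_color, float))}
    part_colors.update({f"override_{k}": v for k, v in override_colors.items()})
    return img, landmarks, region_truth, part_colors


def labeled_pixels_for_face(part_colors: dict, n_per_color: int = 200,
                            skin_parts: tuple = ("skin",)) -> pd.DataFrame:
    """Labeled 8-bit training pixels from a render's flat part colors.

    Override part colors are treated as skin.  Returns the documented
    labeled-pixel table (columns R, G, B, label).
    """
    rows = []
    for part, color in part_colors.items():
        label = "skin" if (part in skin_parts
                           or part.startswith("override_")) else "nonskin"
        rgb = np.clip(np.rint(np.asarray(color) * 255.0), 0, 255).astype(int)
        rows += [{"R": rgb[0], "G": rgb[1], "B": rgb[2], "label": label}] * n_per_color
    return pd.DataFrame(rows, columns=["R", "G", "B", "label"])


# ---------------------------------------------------------------------------
# Labeled skin / non-skin pixel database
# ---------------------------------------------------------------------------

_SKIN_MEAN = np.array([210.0, 150.0, 120.0])
_SKIN_SD = 20.0


def simulate_skin_patches(n_skin: int, n_nonskin: int, seed: int) -> pd.DataFrame:
    """Labeled pixel database: Gaussian skin cloud vs off-skin uniforms.

    Skin pixels follow a per-channel truncated Gaussian around
    (210, 150, 120) with sd 20 (truncated to 0-255); non-skin pixels
    are uniform on the 24-bit cube excluding the skin Gaussian's
    +/- 2 sd box.  Fully reproducible from the seed.
    """
    if n_skin < 1 or n_nonskin < 1:
        raise DataError("need at least one pixel per class")
    rng = np.random.default_rng(seed)
    skin = np.empty((n_skin, 3))
    for ch in range(3):
        a = (0.0 - _SKIN_MEAN[ch]) / _SKIN_SD
        b = (255.0 - _SKIN_MEAN[ch]) / _SKIN_SD
        skin[:, ch] = truncnorm.rvs(a, b, loc=_SKIN_MEAN[ch], scale=_SKIN_SD,
                                    size=n_skin, random_state=rng)
    skin = np.rint(skin).astype(int)

    lo = _SKIN_MEAN - 2 * _SKIN_SD
    hi = _SKIN_MEAN + 2 * _SKIN_SD
    nonskin = np.empty((0, 3), dtype=int)
    while nonskin.shape[0] < n_nonskin:
        cand = rng.integers(0, 256, size=(2 * n_nonskin + 16, 3))
        inside = np.all((cand >= lo) & (cand <= hi), axis=1)
        nonskin = np.vstack([nonskin, cand[~inside]])
    nonskin = nonskin[:n_nonskin]

    df = pd.DataFrame(np.vstack([skin, nonskin]), columns=["R", "G", "B"])
    df["label"] = ["skin"] * n_skin + ["nonskin"] * n_nonskin
    return df


# ---------------------------------------------------------------------------
# Cohort simulation (generative twin of the association analysis)
# ---------------------------------------------------------------------------

#: Attainable cold-pattern score range under the 1-4 item scale.
CPS_ATTAINABLE = (8, 32)

#: Per-region CIELAB feature means and sds used by the cohort generator
#: (realistic cohort values for the facial regions of middle-aged adults).
REGION_COLOR_DISTRIBUTIONS = {
    "whole_face":  {"L_star": (65.5, 3.2), "a_star": (13.0, 1.5), "b_star": (22.2, 2.2)},
    "forehead":    {"L_star": (73.3, 3.8), "a_star": (11.3, 1.9), "b_star": (24.2, 2.8)},
    "upper_cheek": {"L_star": (66.0, 3.5), "a_star": (14.8, 1.7), "b_star": (22.8, 2.3)},
    "lower_cheek": {"L_star": (60.7, 3.3), "a_star": (15.0, 1.7), "b_star": (23.0, 2.4)},
    "nose":        {"L_star": (78.0, 3.8), "a_star": (11.8, 2.0), "b_star": (20.5, 2.9)},
    "chin":        {"L_star": (57.5, 5.2), "a_star": (16.9, 2.1), "b_star": (22.2, 3.0)},
    "lip":         {"L_star": (46.2, 3.7), "a_star": (24.2, 2.4), "b_star": (12.3, 1.8)},
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of a study cohort.

    ``effects`` maps region -> channel -> linear coefficient on the
    (continuous) cold pattern score; sex enters as +``sex_effect`` for
    female, age as ``age_effect`` per year.  The intercept is chosen so
    the expected score equals ``mean_cps``.  Scores are rounded and
    truncated to the attainable 8-32 range, then item responses are
    back-filled by a seeded greedy allocation so the eight 1-4 items
    sum exactly to the score.
    """

    n_subjects: int = 64
    effects: dict = field(default_factory=lambda: {"whole_face": {"a_star": -1.0}})
    sex_effect: float = 2.2
    age_effect: float = 0.0
    noise_sd: float = 3.0
    age_range: tuple = (35, 44)
    mean_cps: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 10:
            raise DataError("cohort needs at least 10 subjects")
        if not self.noise_sd > 0:
            raise DataError("noise sd must be positive")
        for region, chans in self.effects.items():
            if region not in REGION_COLOR_DISTRIBUTIONS:
                raise DataError(f"unknown region '{region}' in effects")
            for ch in chans:
                if ch not in ("L_star", "a_star", "b_star"):
                    raise DataError(f"unknown channel '{ch}' in effects")


def simulate_cohort(spec: CohortSpec | None = None) -> tuple:
    """Draw one cohort; returns ``(features, questionnaire)`` tables.

    ``features`` is the long-format color table (subject_id, region,
    L_star, a_star, b_star, n_pixels); ``questionnaire`` has
    subject_id, sex, age, item1..item8.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    ids = [f"S{i:03d}" for i in range(1, n + 1)]

    sex01 = np.zeros(n, dtype=int)
    sex01[n // 2:] = 1
    rng.shuffle(sex01)
    age = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n)

    feat_rows = []
    values = {}  # (region, channel) -> vector
    for region, chans in REGION_COLOR_DISTRIBUTIONS.items():
        cols = {}
        for ch, (mu, sd) in chans.items():
            cols[ch] = rng.normal(mu, sd, size=n)
            values[(region, ch)] = cols[ch]
        npix = rng.integers(500, 5000, size=n)
        for i in range(n):
            feat_rows.append({"subject_id": ids[i], "region": region,
                              "L_star": cols["L_star"][i],
                              "a_star": cols["a_star"][i],
                              "b_star": cols["b_star"][i],
                              "n_pixels": int(npix[i])})
    features = pd.DataFrame(feat_rows)

    intercept = spec.mean_cps - spec.sex_effect * 0.5 \
        - spec.age_effect * np.mean(spec.age_range)
    linear = np.full(n, intercept, dtype=float)
    for region, chans in spec.effects.items():
        for ch, beta in chans.items():
            mu = REGION_COLOR_DISTRIBUTIONS[region][ch][0]
            linear += beta * (values[(region, ch)] - mu) + 0.0
    linear += spec.sex_effect * sex01 + spec.age_effect * (age - np.mean(spec.age_range))
    cps_cont = linear + rng.normal(0.0, spec.noise_sd, size=n)
    cps = np.rint(cps_cont).astype(int)
    n_clip = int(np.sum((cps < CPS_ATTAINABLE[0]) | (cps > CPS_ATTAINABLE[1])))
    if n_clip:
        warnings.warn(f"{n_clip} simulated scores fell outside 8..32 and were "
                      "truncated", stacklevel=2)
    cps = np.clip(cps, CPS_ATTAINABLE[0], CPS_ATTAINABLE[1])

    items = np.ones((n, 8), dtype=int)
    for i in range(n):
        remaining = cps[i] - 8
        while remaining > 0:
            open_items = np.flatnonzero(items[i] < 4)
            items[i, rng.choice(open_items)] += 1
            remaining -= 1

    questionnaire = pd.DataFrame({
        "subject_id": ids,
        "sex": np.where(sex01 == 1, "female", "male"),
        "age": age,
    })
    for j in range(8):
        questionnaire[f"item{j + 1}"] = items[:, j]
    return features, questionnaire
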