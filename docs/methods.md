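# Methods

This note records the models implemented in `facecolor`, the conventions
and numerical choices behind them, and what the synthetic fixtures do and
do not establish.

## Color model and correction

Images are H×W×3 arrays of floats in [0, 1]; 8-bit files are divided by
255 on load. The scale matters: the quadratic correction family is not
scale-covariant (only its linear terms are), so the [0, 1] convention is
part of the model contract and is applied consistently in fitting and
application.

The correction maps each pixel through the 10-term basis
[1, R, G, B, RG, GB, RB, R², G², B²] with a 10×3 coefficient table, one
column per corrected channel. Coefficients are fitted per channel over the
24 chart patches by the SVD pseudoinverse with a relative singular-value
cutoff of 1e-10, which returns the least-squares solution of smallest
Euclidean norm when the design is rank deficient (e.g. all patches equal).
Corrected values are clipped to [0, 1] before any further processing;
whether out-of-gamut values should instead be rescaled is an open
convention, and clipping was chosen as the least surprising option.

Patch sampling takes a user-supplied corner quad for the chart (top-left,
top-right, bottom-right, bottom-left of the chart frame — a rotated order
rotates the patch order correspondingly), maps a projective rectification
onto the 4×6 cell grid, and averages a bilinear-interpolated 8×8 lattice
over the central `center_fraction` (default 0.5) of each cell. Automatic
chart detection in cluttered scenes is deliberately out of scope; the quad
contract makes sampling exactly testable and lets an automatic detector be
plugged in upstream.

**Exactness of the round trip.** If a color distortion is affine and
invertible, its inverse is affine and therefore lies inside the 10-term
family, so fitting the correction on a distorted chart recovers the
targets exactly (up to floating point). This does *not* hold for a generic
quadratic member: inverting it on the 24 patches poses 24 equations in 10
unknowns per channel, which is generically unsolvable, so only approximate
recovery is possible. The seeded round-trip checks therefore draw random
invertible *affine* members (diagonal gains 0.75–1.1, small channel mixing
and offsets, rejection-sampled so no patch leaves (0, 1) and clipping never
intervenes); a separate check verifies that for fully quadratic distortions
the fit is still least-squares optimal (residual orthogonal to the design's
column space).

CIELAB conversion assumes sRGB encoding and D65/2° viewing, since camera
profiles are not modelled. The chain is the standard sRGB decode → linear
RGB → XYZ → CIELAB, with the reference white taken as the sRGB matrix's own
image of (1, 1, 1). This keeps relative colorimetry self-consistent: every
gray maps to a\* = b\* = 0 exactly and white to L\* = 100, whereas
normalising by an independently rounded tabulated white leaves grays ~1e-3
off neutral. The implementation agrees with `skimage.color.rgb2lab` to
better than 0.05 Lab units, and that library conversion is used as an
independent cross-check in the tests.

## Landmarks and region geometry

The 79-point scheme follows the standard 68-point annotation (1–17 jaw,
18–27 eyebrows, 28–36 nose, 37–48 eyes, 49–68 mouth) extended by five
upper-forehead boundary points (69–73, left to right) and six
upper-eyebrow points (74–79). Coordinates are (x, y) = (column, row) on the
0-based pixel grid; "left"/"right" region names follow image coordinates
(the subject's right cheek has low x).

The seven circles use fixed affine combinations of landmarks for their
centres and distance-proportional radii (nose 1.4, forehead and lower
cheeks 0.7, upper cheeks and chin 0.8). The upper-cheek centre weights are
read as 0.4·pt31 + 0.3·ptA + 0.3·ptB so they sum to one. These formulas are
translation- and scale-equivariant by construction, which the tests verify.

Closed boundaries are periodic cubic splines (`scipy` `CubicSpline`,
periodic end conditions) through the control points, parametrised uniformly
by index and sampled 40 points per control interval. Uniform (rather than
chord-length) parametrisation keeps the construction exactly symmetric for
symmetric control points and deterministic for any spacing. The whole-face
outer loop stitches jaw 1→17 with forehead 73→69, which yields a simple
loop for frontal faces; its holes are the lip outer ring, nose tip (31–36),
both full eye rings (37–42, 43–48) and both eyebrows (18–22 + 76–74,
23–27 + 79–77). Both complete six-point eye rings are used even though
partial rings are sometimes quoted for this construction; omitting the two
lower-lid points of one eye has no plausible rationale and full rings keep
the two sides symmetric.

Rasterisation is pixel-centre based: a pixel (r, c) lies in a circle iff
its centre (c+0.5, r+0.5) is within the radius (inclusive), and in a
polygon by the even-odd rule on the same point; geometry beyond the image
is cropped silently. Identical landmarks give bit-identical masks.

`extend_landmarks` is a documented heuristic for real photographs whose
detector emits only 68 points: forehead points are the chin-bottom arc
reflected across the eye line, eyebrow-top points offset the middle brow
points upward by 0.3× the brow-to-eye distance, and the result is flagged
`extrapolated`. Synthetic fixtures never need it — the renderer emits all
79 points exactly.

## Skin model

Histograms use 32 bins per channel with bin index ⌊v/8⌋ on 0–255 values.
The classifier compares class-conditional likelihoods only — despite the
customary "Bayesian" label no class priors enter — and breaks ties
(including bins unseen in both classes) toward nonskin. Smoothing defaults
to 0 (raw counts) and is configurable as an additive constant per bin.
Because likelihoods are normalised per class, duplicating one class's
training data never changes a decision. Models serialise to JSON
losslessly. Whether detection should run on corrected or raw RGB is not
fixed by the method; the pipeline applies it to the corrected image, which
is the image whose colors the features report.

## Features

Each region's L\*, a\*, b\* are trimmed means computed independently per
channel: sort, drop exactly ⌊n/4⌋ from each end, average the rest (all of
it when n < 4) — deterministic for every n. Left and right cheek circles
pool their pixel multisets into single upper/lower-cheek records rather
than averaging per-side means, so an unbalanced pair is weighted by pixel
count. All regions except the lip are restricted to skin-classified
pixels; the lip is exempt because lip color is by design not skin-like and
would otherwise be rejected wholesale. Regions left with zero pixels are
omitted with a logged warning rather than emitting NaNs.

The trimming gives a 25% breakdown point per tail: fewer than ⌊n/4⌋
contaminated pixels can never enter the kept window, so the result is
independent of outlier magnitude and confined to the clean remainder's
range. The quantitative "shift < 0.1 Lab units" check is meaningful for
near-flat regions (which the renderer produces); for a widely dispersed
clean distribution the kept order-statistic window itself shifts, and no
sub-0.1 bound can hold in general.

## Questionnaire and association statistics

CPS sums eight items scored 1–4, so attainable scores span 8–32 and the
validator enforces that range. Sex is coded 0 = male / 1 = female and age
is in years, uncentred; the coding is recorded in the outputs. Regressions
are OLS with intercept, two-sided t-test p-values on n−p−1 degrees of
freedom and adjusted R² = 1 − (1−R²)(n−1)/(n−p−1); a rank-deficient design
raises an error naming the offending columns (pivoted QR). Partial
correlation residualises both variables on the covariates plus intercept
and correlates the residuals, with p from t = ρ√((n−k−2)/(1−ρ²)) on n−k−2
df; the zero-residual-variance guard uses a relative tolerance (1e-10 ×
input norm) because exact collinearity still leaves ~1e-14 numerical
residuals. Raw p-values are reported throughout, matching common practice
for exploratory tables; Benjamini–Hochberg adjustment is available but off
by default. Subjects with any missing item or feature are dropped listwise.

## Synthetic data

The face render is schematic: a skin-colored ellipse with spline-drawn
eyes, eyebrows, nose tip, lips and optional per-region color overrides,
all geometry derived from the same parametric landmark layout that is
returned alongside the image — so landmarks, masks and ground-truth region
colors are exact by construction. It emulates flat region colors under
known geometry; it does not emulate shading, texture, specular highlights,
pose variation or landmark-detector noise, so passing tests establish the
correctness of the geometry, calibration and statistics, not robustness to
real photographic conditions.

The labeled-pixel generator draws skin from truncated per-channel
Gaussians around (210, 150, 120) with sd 20 and non-skin uniformly outside
the Gaussian's ±2 sd box; the two classes overlap slightly in bin space
(Gaussian tails), so held-out accuracy is ~96%, while strictly
disjoint-support constructions yield exactly 100% training accuracy.

The cohort generator is the generative twin of the association model:
region features are Gaussian with realistic CIELAB means/sds per region,
the continuous score is intercept + Σβ·(feature−mean) + sex effect + age
effect + N(0, σ), rounded and truncated to 8–32, and items are back-filled
by seeded greedy allocation so the eight 1–4 items sum exactly to the
score (only the sum is statistically meaningful downstream). Defaults: 64
subjects (32/32 sex split), ages uniform on 35–44, β = −1.0 on whole-face
a\*, sex effect +2.2 for female, age effect 0, σ = 3, intercept
auto-centred for a mean score of 20. With these values truncation is a
<4σ tail event and bias on recovered coefficients is negligible; the
truncation warning fires on the rare cohorts where it occurs.

## Problem sizes and determinism

All generators are pure functions of (spec, seed). The validation suite
uses a 256×256 face render, charts with 8–24 px patches, 500 simulated
cohorts of n = 64 for coefficient recovery, 2,000 replicates for type-I
calibration and 100 seeded distortions for the correction round trip —
sizes chosen so the full suite completes in well under a minute of
compute while keeping Monte-Carlo error an order of magnitude below every
asserted tolerance.

## Known limitations

- No automatic chart detection, camera-RAW handling or white-balance
  modelling; correction quality is bounded by the quad the caller supplies.
- The landmark detector itself is out of scope; real-photo use depends on
  an external 68-point detector plus the `extend_landmarks` heuristic.
- The skin model is not illumination-adaptive and has no parametric
  (mixture) form.
- Gloss/luster and texture features are not computed.
- Cohort statistics on synthetic data validate the estimators, not any
  empirical claim about real faces or cold pattern.
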