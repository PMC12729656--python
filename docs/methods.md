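# Methods

`sowscope` implements a non-contact body-measurement and weight-estimation
pipeline for finishing pigs from two consumer depth cameras — one 1.40 m
above the measurement zone (top view) and one 0.70 m to the side of it
(side view), both 848×480 — together with a synthetic depth-scene
generator that provides exact ground truth for validating every stage.

## Measurement model

**Depth frames.** Raw sensor output is a 2-D grid of 16-bit counts, one
count = 1 mm (`unit_scale` = 0.001 m/count). Zero counts are sensor holes
and never enter any statistic. Metric depth is `depth_m = counts × 0.001`.

**Top view (pinhole).** A reference segment of known physical length
`D_real` (cm) spanning `p` pixels at mean depth `z` (m) calibrates the
effective focal length

    f = p · z / (D_real / 100)        [px]

after which any pixel span back-projects as `D_real = p · z / f · 100`.
Body length L and width W come from probes derived from the top-view
silhouette: the length probe spans the extreme boundary points along the
mask's principal axis (second-moment eigenvector), the width probe is the
longest boundary chord perpendicular to that axis, with both chord
endpoints at the same axial position. The silhouette boundary is taken
from the 0.5-level contour of the padded mask, which is median-unbiased
against half-pixel quantization.

**Side view (scale factor).** A reference of known length at the animal's
sagittal plane fixes `k = L_real / L_pixel` (cm/px); vertical pixel spans
convert to body height H (withers to ground) and chest depth D (withers
to sternum). The scale is exact only for fronto-parallel extents at the
calibration plane; off-plane animals are a documented error source.

**Chest girth.** The chest cross-section is modelled as an ellipse with
semi-axes a = W/2 (major) and b = D/2 (minor). Four perimeter models are
compared:

| method | formula | note |
|---|---|---|
| `ramanujan` | π[3(a+b) − √((3a+b)(a+3b))] | default |
| `simple_ellipse` | π(a+b) | lower bound of the true perimeter |
| `stadium` | πD + 2(W−D) | rectangle + two semicircular caps; needs W ≥ D |
| `pig_empirical` | c₀ + c₁(W+D) | configurable affine model |

Only the Ramanujan form has a published definition for this system; the
other three names appear in the source comparison without formulas, so
the definitions above are this package's fixed interpretations, kept
behind method tags. The `pig_empirical` defaults
(c₀, c₁) = (0.1898, 1.5707) are a least-squares fit of exact quadrature
perimeters over the synthetic shape prior below — placeholders standing
in for a breed-fitted formula, not herd-derived values.

The package-internal girth oracle is adaptive quadrature of the ellipse
arc length, `C = 4∫₀^{π/2} √(a²cos²t + b²sin²t) dt` (`scipy.integrate.quad`,
tolerances 1e-12). Ramanujan's approximation agrees with it to better
than 1e-3 relative for aspect ratios b/a ≥ 0.2 and better than 1e-6 for
b/a ≥ 0.6.

**Weight.** Empirical formulas (inputs cm, output kg):

    BW1 = 0.634·C²·L/12500 + 14.6          (standard formula; default base)
    BW2 = 1.247·C·L·D/7500 + 7.4
    BW3 = 2.142·W·D·L/7200 + 6.9
    BW4 = (1.245·C·L·D·0.8 + 50·H)/1000 + 7.4

The BW4 source text is typographically garbled; the parse above is this
package's interpretation and BW4 is excluded from headline checks. The
final prediction is a single-predictor affine calibration
`BW = α·BW_base + β` fitted by OLS (QR solve) on reference weighings; the
reference herd fit is α = 0.8294, β = 11.16 on BW1. Generalization is
assessed by seeded k-fold cross-validation (default k = 5): folds of size
⌊n/k⌋/⌈n/k⌉, out-of-sample R² computed against each validation fold's own
mean (the standard definition; the source does not state one), and the
train-vs-validation R² gap reported as the overfitting check.

**Metrics.** MAE, RMSE, MAPE (reference in the denominator, in percent;
zero references rejected rather than skipped) and R² = 1 − SSE/SST.
Agreement uses the intraclass correlation coefficient in its two-way,
absolute-agreement, single-measure form ICC(A,1), computed from ANOVA
mean squares:

    ICC(A,1) = (MSR − MSE) / (MSR + (m−1)·MSE + m·(MSC − MSE)/n)

The ICC variant is not stated in the source; ICC(A,1) is the natural
choice for absolute repeatability of single measurements (it matches
pingouin's `ICC(A,1)` row, which the tests use as an independent check).

## Perspective-consistent silhouette inversion

The literal field procedure — invert a pixel span at the *average* depth
of the probed region, or multiply by a fixed scale factor — is biased on
a convex body, because a silhouette is generated by *tangent* rays, not
by rays through the widest cross-section, and because the averaged depth
of a curved back lies above the chest mid-plane. Both effects are second
order but worth several pixel-equivalents at this rig's geometry. The
pipeline therefore performs an exact inversion for the ellipsoid model:

*Top view.* For a camera at height d above a body mid-plane with
vertical semi-thickness b, the tangent ray to the extremity has direction
`tan θ = ℓ/√(d² − b²)` for a semi-extent ℓ, so the pixel span of the
silhouette corresponds to a fronto-parallel plane at

    z_eff = √(d² − b²),   d = z_near + b,

where `z_near` is the near-surface (spine) depth read from the frame (a
2 % depth quantile along the probes, robust to noise) and b = D/2 uses
the side view's chest depth — the dual-view fusion step. Inverting at
`z_eff` rather than at d removes a ≈ b²/(2d²) relative inflation.

*Side view.* The upper/lower silhouette rows of each mask column are
tangent rays to that column's cross-section ellipse (vertical semi-axis
h, depth semi-axis w, centre height z_c). A ray of slope m with apparent
height z* at the working plane is tangent iff (z* − z_c)² = h² + m²w²;
two tangents give

    z_c = (z*₁+z*₂)/2 − (m₁²−m₂²)w²/(2(z*₁−z*₂)),   h = √((z*₁−z_c)² − m₁²w²).

Each column's working distance is anchored on its own near-surface depth
plus w (so yaw and off-plane placement are absorbed), w comes from the
top view's W/2, and H and D are the 0.99-quantile of per-column top
heights z_c + h and extents 2h (a maximum that tolerates a stray column).
Since the side inversion needs W and the top view needs D, the pipeline
runs side (uncorrected) → top → side (corrected) → top; the corrections
are second order, so one refinement pass converges.

The uncorrected modes (`depth_mode="mean"`, plain scale factor) remain
available as the literal transcription of the field workflow; on the
synthetic ellipsoid the mean-depth reading understates W by roughly 10 %,
which an affine weight calibration largely absorbs — consistent with such
systems working in practice despite the bias.

With the corrected pipeline, noise-free synthetic scenes are recovered
with per-dimension mean errors of 0.2–0.5 pixel-equivalents (a
pixel-equivalent is z·100/f cm in the top view and the cm/px scale in the
side view); individual scenes at the extreme of the yaw prior can reach
≈1.05 px on one dimension, the residual being genuine second-order
perspective terms not captured by the ellipse tangent model.

## Synthetic scenes

The generator stands in for barn imagery that is not publicly available.

**Body model.** A single ellipsoid (semi-axes: length 30–57 cm, width
12–20 cm, height = width × 0.75–0.95), floating 20–30 cm above the ground
plane (the clearance plays the role of the unmodelled legs, so body
height is ground-referenced), offset ±10 cm along the zone and yawed
±8° about the vertical; draws with trunk aspect L/W outside [1.5, 4.5]
are rejected and resampled. The depth-to-width ratio < 1 keeps W the
girth ellipse's major axis, matching the measurement convention (the
stadium model is undefined for W < D). Ground truth is closed-form:
L = 2ℓ, W = 2w, D = 2h, H = clearance + 2h, and C is the quadrature
perimeter of the (w, h) ellipse — deliberately independent of the
approximations under test, so girth-model error is attributable to the
approximation alone.

**Weight.** `true_weight = 0.8294·BW1(true_C, true_L) + 11.16 + ε` with
ε ~ Normal(0, σ_w = 2 kg) truncated at ±2σ_w. The truncation mirrors the
cohort inclusion band: with the default shape prior every generated
weight stays inside 30–100 kg, the finishing-stage range the system
targets. σ_w = 2 kg was chosen as a plausible residual spread for a
girth–length weight model at this scale; it was not tuned to reproduce
any published statistic.

**Rendering.** Per pixel, depth is the distance along the optical axis
to the first ray–ellipsoid intersection, else to the ground plane (top
view, 1.40 m) or to a vertical background plane 0.30 m behind the
sagittal plane (side view, 1.00 m). The side view renders no floor: a
floor sweeping toward a side-mounted camera produces near-camera depths
that defeat depth-threshold segmentation, and the physical system reads
the ground line by geometry (`ground_row = c_y + f·z_cam/d`). An animal
whose silhouette touches the frame border raises an out-of-view error
rather than being cropped. Default focal lengths are 420 px (top) and
400 px (side) with the side camera 0.40 m above ground — values that keep
the largest animals of the prior inside the frustum at the published
standoffs. Depth counts are rounded to 1 mm.

**Noise.** Gaussian with σ(z) = σ₁ₘ·z² (σ₁ₘ default 2 mm, matching the
sensor's ≤2 mm error class; the quadratic range dependence is this
package's choice — the source does not state a noise model) plus a
`hole_rate` (default 2 %) fraction of pixels zeroed. All randomness flows
from explicit seeds; identical seeds give byte-identical cohorts, frames
and fixtures.

**What the generator does not emulate.** Articulated legs, head and ears
(ground-truth length is the trunk's long axis, not an ear-to-tail-root
tape path), non-elliptical cross-sections, pose variation beyond yaw,
pen furniture and occlusion, RGB appearance, and structured depth
artefacts (multipath, edge fattening). Passing tests therefore show the
*measurement chain* is unbiased and stable under sensor-like noise on a
convex body of known shape — not that real-animal accuracy matches the
numbers here.

## Segmentation baseline

The original system segments the side view with a trained network whose
annotated imagery is unavailable. The package defines the mask contract
(`BodyMask`, 8-bit PNG interchange) so external masks can be dropped in,
and ships a classical baseline sufficient for depth scenes: threshold at
`background_depth − margin` (margin default 0.05 m), morphological
opening then closing with a radius-1 disk, filling of enclosed holes, and
retention of the largest connected component. On synthetic side frames
the baseline recovers the true silhouette with IoU ≥ 0.98. Masks are
scored with IoU and Dice; empty-vs-empty is defined as 1.

## Numerical and design choices

- OLS via `scipy.linalg.lstsq` (QR, `gelsy`) for conditioning; constant
  predictors raise a rank-deficiency error.
- Probe rasterization is Bresenham with both endpoints included;
  mask-derived probes place endpoints on pixel boundaries (half-integer
  coordinates) so endpoint distance estimates the extent without
  half-pixel truncation.
- The withers column is the column of the topmost mask pixel, smallest
  column on ties — a deterministic stand-in for the operator's click.
- `segment_side` rejects `margin ≥ background_depth`; probes with no
  valid depth pixel raise "no depth support" rather than returning 0.
- Degenerate inputs fail loudly and name the offending argument
  (calibration inputs ≤ 0, masks under 2 px, k > n folds, unknown config
  keys).
- The pipeline evaluates girth models on the cohort's *true* axes
  against the quadrature girth (isolating model error, under which
  Ramanujan is best by construction) and separately reports measured-
  dimension accuracy and the calibrated weight model's cross-validated
  R²; at the default conditions (n = 30, σ_w = 2 kg, 2 mm noise) the
  validation R² is ≈ 0.97 with a train-validation gap under 0.01.

## Known limitations

- All side-view corrections assume the ellipse cross-section; strongly
  non-elliptical chests would re-introduce second-order bias.
- L_side shares the side view's scale assumptions and shortens with
  cos(yaw); it is reported but not used downstream (the top view owns
  body length).
- The affine fusion uses a single base formula (default BW1); whether a
  multi-formula regression was intended in the original system is
  ambiguous, and the single-predictor form matches the published
  equation.
- Real-herd accuracy tables cannot be reproduced without the original
  imagery; the synthetic regime mirrors the protocol, not the data.
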