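# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, units, scales

Images are `ndarray[y, x]`, origin at the top-left pixel centre, x
rightward, y downward; point landmarks are `(x, y)`.  Distances are
Euclidean in pixels unless a physical scale is supplied: μm/pixel for
fundus maps and OCT axial/lateral scales, mm/pixel for OCTA en-face
slabs.  Fundus calibers are reported in pixels when the map carries no
scale — the convention used when tabulating CRAE/CRVE from fundus
photographs of unknown magnification — and in μm otherwise.

## Fundus measurements

**Zones.** Measurement annuli are defined from the optic-disc *margin*:
a point at distance d from the disc centre is in the zone when
R + inner·D ≤ d < R + outer·D (R = D/2).  Zone B is (0.5, 1.0), zone C
(0.5, 2.0) disc diameters — the Parr–Hubbard/Knudtson convention.

**Widths.** Each class mask is skeletonized; width at a centerline pixel
is 2 × its Euclidean distance transform.  Each connected centerline
segment inside the zone contributes the mean of its per-point widths.  A
half-pixel correction was evaluated and rejected: against the round-cap
stroke renderer it converts a near-zero bias into a systematic
−0.6 px.  On generator strokes the estimate stays within 1 px of the
true caliber across 6–30 px.

**Knudtson reduction.** The six largest widths are combined iteratively
(largest with smallest, ŵ = k√(w₁²+w₂²), k = 0.88 arterioles / 0.95
venules; odd leftover carries unchanged).  The procedure is
permutation-invariant and scale-equivariant, which the suite checks on
random width sets.

**Tortuosity.** Arc/chord − 1 per centerline path, length-weighted.
Skeleton chains are cut at branch points, traced from endpoints, and
smoothed with a 5-point moving average (keeping the true endpoints) so
rasterization staircase does not inflate arc length.  Closed loops
(zero chord) are excluded with a warning.  This is one of several
tortuosity definitions in use; the choice is declared rather than
assumed equivalent to any particular software's variant, and gives 0
for straight vessels.

**Box-count fractal dimension.** N(ε) = number of grid boxes of side ε
intersecting the foreground, minimized over a 4×4 grid of box origins;
D = slope of log N vs log(1/ε) over dyadic ε ∈ [2, min(H, W)/8].  The
coarse cut-off at min/8 (rather than min/4) and the origin minimization
both address the saturation plateau, which otherwise biases
plane-filling patterns toward ~1.8.  At least 100 foreground pixels are
required for a reliable estimate (fewer triggers a warning).

## Ultra-widefield measurements

**Alignment.** Left eyes are mirrored about the vertical midline; the
image is rotated about its centre so the disc–fovea axis is horizontal
with the fovea on the left.  The transform (mirror flag, angle, centre)
is recorded and invertible to sub-pixel accuracy.

**Extended zone.** An axis-aligned ellipse spanning the field width with
15% of the height excluded top and bottom (eyelid/lash bands).  At the
nominal 24 mm field this encloses ≈317 mm², consistent with the ≈319 mm²
standardised region; the area in mm² is always computed from the
supplied scale, which is required metadata.

**Sandbox fractal dimension.** For 500 seed points sampled uniformly
from the foreground (seeds whose largest window would leave the image
are excluded), N(r) is the foreground count in the (2r+1)-square
window; D is the slope of log⟨N⟩ against log(2r+1).  The window *side*
is the scale variable: regressing on log r instead biases the slope
downward by ~0.1 at small radii.  Default radii are log-spaced from 4 to
min(H, W)/8 (capped at 128); radii beyond the zone are trimmed with a
warning.  The estimator is deterministic for a fixed seed, which is part
of the output contract.

**Width gradient.** Theil–Sen (median of pairwise slopes) of width (μm)
on arc position (mm), chosen for its 29% breakdown point and freedom
from tuning constants; at least 5 samples are required.  Per-quadrant
slopes (the longest unbroken profile per class per quadrant stands in
for the operator-chosen "most prominent vessel") are averaged into the
global WGa/WGv with the contributing-quadrant count reported.

## OCTA measurements

Ring densities are vessel-pixel fractions of annuli at radial bounds
1–2 mm (inner), 2–3 mm (outer) and 0–3 mm (global) around the fovea,
taking the printed bounds as radii; the bounds are configurable because
the classical ETDRS grid is specified by 1/3/6-mm *diameters* and either
reading is defensible.  The FAZ on one slice is the connected avascular
component containing the fovea after closing the vessel mask with a
25 μm disc — large enough to bridge inter-capillary gaps, an order of
magnitude below a true FAZ radius, so the zone itself survives.  A fovea
landing on a vessel pixel snaps to the nearest avascular pixel within
100 μm.  Volume is the trapezoidal integral of per-slice area over
depth; per-plexus areas average the slices labelled SVC/ICP/DCP (upper,
middle and lower thirds of the ILM–OPL span when the device labels are
unavailable).  Inputs are assumed projection-artefact-corrected
upstream.

## Choroid measurements

Thickness is the axial separation of the supplied inner (Bruch's
membrane) and outer (choroidal–scleral interface) boundary polylines
times the axial scale; boundaries are taken as given and never
re-detected.  Binarization of each B-scan inside the choroid mask:
Gaussian smoothing (σ = 0.5 px), 8-bit rescale within the mask, local
Otsu threshold in a sliding window (default 51 px, shrunk with a warning
for thin choroids), one erosion and one dilation with a 1 px disc; dark
pixels are luminal.  The pass is repeated at σ ∈ {0.5, 2, 4} and the
luminal masks are combined by union so small and large lumina are both
captured.

Two guards make the multi-scale union quantitative.  Each scale's mask
is gated by the global Otsu cut of the base-smoothed scan, preventing
blur halos at coarse scales from accreting into the union (ungated, the
union overestimates phantom fractions by ~0.12).  And a minimum
class-separation rule — the two global Otsu classes must be at least 4
within-class standard deviations apart — declares a unimodal choroid
lumen-free, since any Otsu split of pure stromal noise classifies ~half
the pixels dark.  With both guards, phantom recovery is within 0.03
across realized fractions 0.2–0.6 (contrast ≥ 80, noise SD ≤ 10), which
the acceptance suite verifies.  Polarity is a documented contract: dark
= lumen; inverted-contrast inputs are misclassified by design.

En-face maps place per-B-scan profiles at their slow-axis positions
(240 μm or 120 μm dialects) and fill intermediate rows by linear
interpolation at a pitch matching the lateral scale; rows coinciding
with B-scans reproduce the profiles exactly, and nothing is extrapolated
beyond the first/last B-scan — uncovered pixels stay NaN.  ETDRS
summaries average defined pixels per region (central 1 mm circle,
1–3 mm inner ring, 3–6 mm outer ring) and report per-region coverage;
"global" is the 6-mm disc mean, a declared choice where whole-volume
averaging would also be defensible.

### Boundary file schema

`choroid_boundaries.json`: `axial_scale_um`, `lateral_scale_um`,
`bscan_spacing_um`, `fovea` = [B-scan index, A-scan index], and
`bscans`, a list of `{"inner": [...], "outer": [...]}` giving the axial
pixel position per A-scan for each B-scan.

## Statistics

The GEE is linear with an exchangeable working correlation: iterate
(1) β from the weighted estimating equations given ρ (the exchangeable
inverse is applied in closed form per cluster), (2) dispersion and ρ
from Pearson residuals (pair products over within-cluster pairs, with a
degrees-of-freedom correction), until max|Δβ| < 1e−8 or 100 iterations.
Variance is the robust sandwich A⁻¹BA⁻¹; intervals use the 1.96 normal
multiplier, matching large-sample 95% CIs, with no small-sample df
correction by default.  With singleton clusters the estimator reduces
exactly to OLS; on clustered data the suite checks agreement with an
independent GEE implementation to ~1e−5.  Model presets mirror a
case–control design: group contrasts (Ctrl reference) unadjusted and
adjusted for IOP and hypertension, and disability models (EDSS, annual
EDSS progression) in MSnON eyes adjusted for age, sex, spherical error
and hypertension.  EDSS enters regressions as numeric, a pragmatic
simplification of an ordinal scale.

BH-FDR uses the step-up definition (adjᵢ = min over j ≥ i of p₍ⱼ₎·m/j,
capped at 1), one family per model/results table — the family assignment
is explicit, not inferred.  Wilcoxon rank-sum uses exact enumeration of
the rank-sum distribution (dynamic programming over subsets) when the
combined sample is ≤ 20 with no ties, otherwise mid-ranks with tie and
continuity-corrected normal approximation; the method used is reported.
Cohort descriptives report mean (SD), median (IQR) and range with
Kruskal–Wallis for continuous variables, counts (%) with Pearson χ²
(Fisher's exact for 2×2 tables with any expected cell < 5) for
categorical ones.

## Synthetic data: what it does and does not emulate

Generators provide every pipeline input with truth computed *by
construction* — direct pixel counting or closed form, never by the code
under test — and are bit-reproducible from one integer seed.

- **Vessel trees**: strokes radiate from the disc with per-vessel
  calibers (μm), linear taper (μm/mm), and a sinusoidal lateral wave for
  tortuosity; rendering is the union of discs along the centerline
  (round caps), so true width is well defined to ±1 px.  Truth records
  caliber, taper, the analytic arc/chord ratio, and canvas clipping.
- **Choroid phantoms**: bright stroma between smooth boundaries, dark
  non-overlapping elliptical lumina painted until a target areal
  fraction is reached; the realized painted fraction is counted exactly
  and returned (an unreachable target — the non-overlap constraint jams
  near ~0.5 with the default radius range — is flagged).  Defaults
  follow the EDI volume dialect: 25 B-scans spaced 240 μm.
- **Angiogram phantoms**: i.i.d. capillary texture at a stated density
  outside a circular avascular core per depth slice; core areas are
  πr² and the volume their depth integral.
- **Cohorts**: two eyes per subject; outcomes are linear in group and
  covariate effects with compound-symmetric Gaussian residuals
  (correlation ρ between a subject's eyes).  Covariates echo a
  case–control pattern (lower IOP, more hypertension in cases).  Default
  group sizes (25/10/6 subjects) mirror a small imaging cohort.

None of the generators emulate OCT speckle, segmentation error,
projection artefacts, illumination gradients, eye-motion artefacts or
disease-specific lesions.  Passing recovery tests therefore demonstrates
the *measurement* chain is correct and unbiased on clean geometry; it
does not certify performance on degraded clinical images, where QC and
segmentation quality dominate.

## Problem sizes

The test suite and acceptance script use scaled-down rasters chosen as a
deliberate speed/fidelity trade-off: vessel maps of 320–512 px, choroid
stacks of 2–7 B-scans at 128–256 A-scans, angiogram fields of 6.4 mm at
10 μm/px, and an end-to-end cohort of 20 subjects (40 eyes).  Monte-Carlo
statements about the GEE use 100 cohorts of 200 subjects for bias and
500+ cohorts across ρ ∈ {0, 0.3, 0.6} for sandwich-CI coverage.  All
stage parameters (window sizes, scales, radii) are the same defaults a
full-size run would use.

## Known limitations

- Artery/vein segmentation and classification are out of scope; the
  package consumes masks and inherits their errors.
- The local-Otsu window, binarization scale set and extended-zone
  template are declared defaults, not claimed equivalent to any
  proprietary software's internals; outputs should cite them.
- The GEE assumes a linear mean model and uses large-sample inference;
  with very few clusters the sandwich variance is anti-conservative and
  a small-sample correction would be advisable.
- En-face choroid maps interpolate only along the slow axis between
  acquired B-scans; regions beyond the scan pattern are reported as
  missing, and ETDRS means over partially covered regions carry a
  coverage fraction that should be inspected before comparison across
  eyes.
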