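# Methods

## Eye model and area correction

UWF angiograms are analysed after transformation to a stereographic
projection. The package models the retina as a sphere of radius
R = axial_length / 2 (default 24 mm → R = 12 mm, an emmetropic eye;
refractive error and non-spherical myopic globes are deliberately not
modelled). The projection plane is tangent at the fovea, the projection
point is the antipode of the fovea. This is the unique canonical reading of
"stereographic projection of a 24 mm eye"; the vendor's exact formulas are
proprietary and not public, and the tangent point is taken at the fovea
because the whole regional analysis is fovea-centred.

Forward map: geodesic distance d (mm along the retina) → plane radius
ρ = 2R·tan(θ/2), θ = d/R. Inverse: θ = 2·atan(ρ/2R). The projection is
conformal with linear scale sec²(θ/2) from sphere to plane, so a projected
pixel of pitch p covers true retinal area p²·cos⁴(θ/2). The area map is
validated against the closed-form spherical cap 2πR²(1 − cos(d/R)) (within
0.5 % at p = 0.05 mm) and pixel geodesics against an independent 3-D
great-circle computation.

Parameters: `axial_length` (mm, default 24); `pixel_pitch` (mm per pixel on
the tangent plane — device calibration is not published, so the default
derives from a 3900-pixel grid spanning a 200° field of view,
2R·tan(50°)/1950 ≈ 0.0147 mm/px); `fovea_pixel` (0-based row/col, defaults
to the grid centre with a logged warning, since automatic fovea detection is
out of scope).

Zone boundaries (0.5, 3, 10, 15 mm) are geodesic distances on the sphere,
not plane distances — the premise of the whole correction is that distances
and areas are physical. Pixels under 0.5 mm or outside the gradable mask are
excluded from all four zones; the sub-0.5 mm disc still counts toward TOTAL,
and every report carries the central-disc CVA that reconciles the zone sum
with TOTAL exactly.

## Segmentation

White top-hat with a disc structuring element (default radius 15 px),
global Otsu threshold on the enhanced image, connected-component area filter
(default minimum 50 px, 8-connectivity), then clipping to the gradable
region (manually outlined visible area minus eyelash/low-contrast
exclusions). The source procedure names only "top-hat filter … binarized …
noise removed"; disc + global Otsu + area filter is the standard
vessel-enhancement reading, and every element is swappable through
`SegmentationConfig` (fixed thresholds are supported; Otsu on a constant
image raises and points to them). Segmentation is deterministic — there is
no RNG anywhere in the measurement path. FA and ICGA frames are assumed
co-registered (they are acquired simultaneously); frame selection is the
caller's responsibility.

## Density accounting

CVA is a scalar area difference per region (TVA − RVA), exactly how the
densities are defined clinically; a pixelwise ICGA-minus-FA mask is exposed
for visualisation only. Negative CVA (possible when the two modalities are
binarized independently) is reported as-is with a warning, never clipped, so
data-quality problems stay visible. The denominator of a zonal CVD is that
zone's gradable area (zone ∩ visible ∩ ¬exclusions) — the only choice that
keeps zonal densities comparable when exclusion masks differ between eyes.
Two-grader mode runs the full segmentation under two config profiles and
averages the metric tables field-wise, mirroring dual human grading.

## Cohort statistics

Mann–Whitney U (midranks; exact permutation p when n₁·n₂ ≤ 400, otherwise
tie-corrected normal approximation), Pearson chi-square without continuity
correction, product-moment correlation with t-based p. Binary logistic
regression by maximum likelihood with Wald tests; both the coefficient and
its exponential are reported, because per-unit odds ratios (e.g. 1.01 per µm
of choroidal thickness) are the natural reading of small continuous-predictor
effects. The multivariate model takes exactly the predictors with univariate
p < 0.05. Perfect separation raises an informative error. No
multiple-testing correction is applied at any stage — the source analysis
used none, and adding one silently would change every reported p-value; this
is a documented property, not an oversight.

ROC: candidate cutoffs are the distinct observed scores; a case is positive
(poor responder) when its score is at or above the cutoff, higher densities
voting positive. AUC is the trapezoid over the full curve and equals the
Mann–Whitney identity U/(n₁n₂) including under ties (asserted in tests).
The optimal cutoff maximises J = sens + spec − 1; among ties the lowest
cutoff is reported, with all maximisers kept alongside.

Sample size: smallest integer n per group such that a two-sided two-sample
t-test at level α reaches the target power against Cohen's d, with power
computed from the noncentral t distribution (df = 2n − 2, noncentrality
d·√(n/2)). At d = 0.8, α = 0.05, power 0.80 this gives 26 per group; the
z-approximation closed form gives 25 because it ignores the estimated
variance — the package exposes both, and the noncentral-t answer is the
reference (it is what G*Power computes).

## Synthetic data

The image generator emulates the modality structure of the study material:
FA renders a retinal tree only; ICGA renders retinal ∪ choroidal trees.
Trees are recursive random binary branchings (per-level calibre taper,
jittered branch angles) rasterised as thick polylines via distance fields
around the centrelines. Choroidal trunk positions are scattered over the
disc with centre-heavy (linear-radial) sampling so the small macular ring is
always reachable. Per-zone density targeting rescales the choroidal
calibres by bisection until the *true* choroidal density — measured with the
same stereographic area map the pipeline uses — hits the target (default
targets are the diseased-group zonal means: MR 25.80, NPR 25.72, MPR 28.67,
FPR 29.39 %). Calibre, not branch count, is adjusted because area varies
smoothly with calibre. A frozen sub-pixel jitter raster anti-aliases the
discrete distance staircase, making zone density a continuous monotone
function of the scale; bisection converges to within 0.1 pp in ≤ 40 steps.
Targets above 60 % are refused — beyond that a branching pattern degenerates
into a blob.

Rendering order matters: ground-truth masks are frozen first, then Gaussian
PSF blur (σ = 0.4 px), radial vignetting (30 % at the edge) and additive
Gaussian noise (SD 12 on a vessel amplitude of 120, SNR 10) are applied, so
truth and raster are exactly consistent. The 512×512 grid at 0.09 mm/px
spans a ~23 mm plane half-width — enough to contain the far-peripheral ring
and the default 18 mm gradable boundary; this raster is a deliberately
down-sampled stand-in for ~3900-px clinical frames, and the PSF σ is scaled
down with it (at full resolution the optical blur is small relative to
vessel calibre; an unscaled blur would dominate the thin synthetic vessels
and bias centre-zone densities upward under vignetting).

What the generator does **not** emulate: dye kinetics and leakage,
hyperpermeability patterns, polyps/branching vascular networks, media
opacity, eyelash artefacts (exclusion masks default to empty), inter-grader
variability of the manual outline, or hemodynamically realistic vessel
topology. Passing recovery tests therefore demonstrates that the
measurement chain is unbiased on images whose contrast model it matches —
not that segmentation accuracy transfers to pathological clinical frames.

The cohort generator draws correlated Gaussian covariates per group
(means/SDs from the studied cohorts) through a Cholesky factor of a latent
correlation matrix; the binary hyperpermeability flag thresholds its latent
normal at the group incidence (34.4 % diseased, 5 % control), and responder
labels come from a logistic model on standardised total density and
choroidal thickness (coefficients −1.1, 1.1, 0.55 chosen to give roughly a
2:1 good:poor split at the group means). SFCT is emitted as Haller + inner
layer so the sublayer arithmetic holds by construction; with the reported
SDs (91.76, 22.68 µm) the latent CVD–inner correlation is set to −0.172 so
the implied CVD–SFCT correlation equals the target 0.448 while CVD–Haller
stays at 0.504. The published zonal correlation tables are internally
inconsistent at the third decimal (they are empirical); the generator
reproduces the headline links exactly and the rest approximately.

## Numerical choices and degenerate inputs

- Otsu on a constant image: error instructing a fixed threshold.
- Empty gradable region: densities are undefined → error, not NaN.
- Empty zone (raster does not reach it): areas 0, CVD = NaN in that row.
- Haller > SFCT: validation error (inconsistent calipers), never clipped.
- Bisection bounds for calibre scale: [0.02, 8]; unattainable targets raise.
- All seeds flow through one `numpy.random.Generator`; identical seeds give
  byte-identical rasters and tables.

## Problem sizes

Geometry closed-form checks use 257² grids at 0.05 mm pitch; end-to-end
recovery uses 20 pairs of 512² rasters; statistical recovery uses 200
cohorts of 62 eyes. These sizes give sampling error comfortably below the
asserted tolerances (e.g. 0.5 % cap-area agreement, ±2 pp density recovery)
while keeping the full suite in the low minutes on one CPU.

## Known limitations

- The fovea must be supplied (or defaults to the grid centre); no detection.
- Pixel pitch is a convention, not a device calibration.
- The stereographic model ignores axial-length variation between eyes.
- CVA subtraction treats retinal vessels as perfectly nested in the ICGA
  mask at the area level; pixel-level disagreement between modalities shows
  up as (reported, unclipped) negative CVA in extreme cases.
- The clinical ROC (AUC, optimal cutoff value) depends on unpublished
  per-eye data and is demonstrated on synthetic cohorts only.
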