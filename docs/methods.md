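# Methods

## Segmentation model

Each camera view is an 8-bit RGB raster. It is converted to the classic
inverse-cosine HSI colour model: intensity I = (R+G+B)/3, saturation
S = 1 − min(R,G,B)/I (0 for black), and hue the angle
θ = arccos(((R−G)+(R−B)) / 2√((R−G)² + (R−B)(G−B))), reflected to
360° − θ when B > G; achromatic pixels (S = 0) take hue 0 by convention.
HSI — rather than HSV/HSL — is used because it is the standard choice in
plant-imaging pipelines built around hue thresholding, and because its hue
channel separates green foliage (~120°) from a blue imaging screen (~240°)
almost independently of illumination.

A pixel is classed as plant when its hue lies in a configurable band
(default **[60°, 180°]**) *and* its saturation is at least a floor
(default **0.15**). The band-plus-floor formulation was chosen over a
single scalar threshold because hue is circular and scalar conventions
differ between imaging systems; the floor rejects near-achromatic pixels
(grey pot rims, specular highlights) whose hue is numerically meaningless.
No morphological cleanup is applied by default — the imaging protocol
assumes pots wrapped in blue and a clean screen — but connected components
below `min_object_size` pixels can be removed on request.

Plant pixels are counted per view, converted to mm² with a per-view
calibration factor (user-supplied; camera geometry differs per
installation), and summed over the top and two side views into the
projected shoot area A. Summing three orthogonal projections implicitly
compensates for leaves hidden behind one another in any single view; no
explicit overlap model is attempted. A two-side-only mode is available via
`view_subset`.

## Biomass models

Five forms are supported, all fitted by OLS with an intercept (the
intercept is never forced to zero): polynomial in area (degrees 1–3), a
power law fitted on the natural-log scale (log SDW ~ log A, with the
back-transformed multiplicative constant reported alongside the log-scale
intercept), and the age-aware form

SDW = c₀ + c₁·A + c₂·A·HD,

derived from the plant-specific-weight mechanism PSW = SDW/A = b₀ + b₁·HD.
Age HD is taken as supplied in the phenotype table (days after planting or
after transplant — the semantics are the caller's responsibility; the
package uses a single age axis). Standard errors use the unbiased residual
variance and the inverse normal matrix; p-values are two-sided from the
t distribution on the residual degrees of freedom. OLS is solved by QR
decomposition, which keeps the zero-noise degenerate case (data exactly in
the model family) at machine-precision residuals despite the collinearity
of A and A·HD. Rank-deficient designs raise an error naming the dependent
columns, identified by pivoted QR.

## Validation

Errors are reported as RMSE = √(mean e²) and MTE = mean e (bias), with
e = predicted − actual SDW in grams; positive MTE is over-estimation, and
RMSE² = MTE² + Var(e) (population form) by construction. Generalisation
error uses K-fold cross-validation, K = 5 by default: a seeded random
partition into near-equal folds (default seed 20110201, surfaced in the
CLI), fit on K−1 folds, evaluate on the held-out fold. Fold RMSEs are
averaged unweighted — fold sizes are equal for the default 320/5 design —
and the pooled RMSE over all held-out residuals is reported alongside,
since the two differ when n mod K ≠ 0. Two models are compared by a paired
two-sided t-test on per-observation squared held-out errors computed on the
*same* fold assignment; this is the simplest paired design for the
comparison, and `cross_validate` accepts a precomputed fold assignment to
guarantee it. Stratified reports compute RMSE/MTE within treatment,
variety or age groups plus an overall row; empty categorical strata are
omitted with a logged warning.

## Synthetic data generator

`simulate_growth_dataset` emulates a completely randomised harvest design:
320 plants, five harvests at days 15/26/34/40/43, 64 plants per harvest,
balanced over two salt treatments and two varieties. Per plant, projected
area grows exponentially, A(t) = A₀·exp(r·t), with lognormal variation
(CV 0.20) in A₀ — cereal vegetative growth is approximately exponential at
these ages; a logistic option (capacity 800 mm²) sits behind a config
switch. Defaults A₀ = 5.3 mm², r = 0.10/day give control plants ~24 mm² at
day 15 and ~390 mm² at day 43. Salt stress multiplies the growth rate by a
factor calibrated (closed form for exponential growth, root-finding for
logistic) so that final-harvest biomass is reduced by a configured
fraction, default 0.25 — moderate salinity reduces cereal growth by
roughly 10–30%.

Dry weight follows SDW = A·(b₀ + b₁·t) + ε with b₀ = 3.6×10⁻⁴ g/mm²,
b₁ = 5.9×10⁻⁵ g/(mm²·day); these were chosen once so that simulated
magnitudes are realistic for a wheat salinity trial (control SDW ~0.03 g at
day 15 to ~1.1 g at day 43) — a loose calibration, not an asserted
reproduction of any particular dataset. The noise ε is additive Gaussian,
default sd 0.02 g — comparable to within-group spread at mid-experiment
harvests — truncated below at a 0.001 g floor, which at this noise level
almost never binds; additive Gaussian noise is the simplest model
consistent with the OLS fitting assumptions. Because the PSW line depends
on age only, not on treatment, the generating process is *inside* the
age-aware model family (c₀, c₁, c₂) = (0, b₀, b₁), and an area-only fit to
the pooled data is biased by treatment exactly as in real salt trials:
at a given area, stressed plants are older, denser and heavier. Passing
tests therefore demonstrate the bias mechanism and its removal, not
robustness to features the generator lacks: heteroscedastic measurement
noise, variety-specific growth, senescent (yellowing) tissue,
non-exponential late growth, or segmentation errors on real images.

`render_plant_views` draws quadratic-Bézier "leaf" strokes (width 4 px by
default) from a basal point — bottom-centre in side views, centre in the
top view — green on blue, and guarantees an *exact* per-view plant-pixel
count: stroke pixels are accumulated in drawing order and truncated when
the per-view budget is reached. The per-view budgets are the target area
split equally across views, floored to whole pixels, with single pixels
added by largest fractional remainder while the calibrated total gets
closer to the target. With anti-aliasing on, the binary mask is smoothed
with a Gaussian (σ = 0.6 px) before compositing, so boundary pixels take
intermediate colours; the default plant/background colours cross the
120°/240° hue midpoint at exactly 50% coverage, so segmentation still
recovers the drawn counts to well within 2%. The renderer produces
plausible rosette/tiller silhouettes, not photorealistic plants.

## Numerical and design choices

- Hue intervals are closed and may wrap through 0°; a sequence of
  intervals is accepted.
- The power form requires strictly positive areas and weights; violations
  raise a domain error naming the constraint.
- `kfold_split` requires 2 ≤ K ≤ n; K = n gives leave-one-out.
- Identical prediction vectors short-circuit the paired t-test to p = 1
  (the test statistic is undefined at zero variance).
- The pixel-budget renderer refuses targets above half the frame area
  (`max_fill`) or geometries that stop making progress.
- Default seeds are fixed (20110201) so that every entry point is
  reproducible without configuration; every CLI run logs version,
  effective config, seed and input checksums.

## Problem sizes used by the test suite

Stochastic checks use 100-replicate loops at the full design size (n = 320)
for coefficient recovery, bias structure and CV ordering; the rendering
closed loop uses 20 triplets at 640×480 (the geometry is
resolution-independent, and the segmentation identities checked are exact
at any size). These sizes make the suite's pass criteria sharp while each
loop completes in seconds.

## Known limitations

- The hue threshold convention of commercial imaging software varies
  (hue may be scaled to [0, 255]); the band here is always in degrees and
  must be adapted when reproducing a platform's pipeline.
- No pot/carrier masking stage exists; the protocol assumption is that
  pots are wrapped in background-coloured material.
- Single additive noise sd cannot reproduce the strong heteroscedasticity
  of real SDW measurements across ages; stratified error magnitudes from
  the simulator are therefore not comparable to any real dataset's, only
  their structure is.
- Mixed-effects extensions (per-variety random effects), robust
  regression and fresh-weight models are out of scope.
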