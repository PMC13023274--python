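# Methods

This note documents the models, parameters, numerical choices and known
limitations of `catrange`, and what the synthetic-data studies do and do not
demonstrate about real tracking data.

## Coordinate frame

All geometry is planar, in meters. Geographic input (lon/lat fix tables) is
projected with a local tangent-plane (equirectangular) projection centered on
the fix centroid: `x = R·cos(φ₀)·Δλ`, `y = R·Δφ` with R the mean Earth
radius. For the sub-kilometer extents of owned-cat ranges the distortion of
this projection is below centimeters — far below GPS error — and it keeps the
SVM's bandwidth parameter meaningful in metric units rather than degrees.

## Fix cleaning

* **Acclimation day.** All fixes from the first calendar day (local civil
  midnight boundary) are excluded; a single-day stream is an error because
  nothing analyzable would remain.
* **Season rule.** A session is *winter* if it touches December–February, or
  contains at least one rainy day, or its mean daily maximum temperature is
  ≤ 20.0 °C (boundary inclusive); otherwise *summer*.
* **Outlier rejection.** A one-class SVM with RBF kernel, ν = 0.05 and
  γ = 0.1, fitted on per-axis z-scored coordinates. ν upper-bounds the
  fraction of training fixes left outside the decision boundary, so ~95% of
  fixes are retained; γ below the common 1/n_features heuristic gives a
  smooth boundary that is insensitive to GPS jitter. Standardization is our
  choice (the scale of raw coordinates is arbitrary); the convex-hull step
  downstream makes results robust to moderate γ variation, which the test
  suite exercises via a scale-equivariance check. Fewer than 20 fixes or a
  degenerate (coincident/collinear) cloud is an error.
* **AOI.** The roaming area is the *convex hull* of the inlier fixes (95%
  MCP) — a deliberate choice over concave outlines (α-shapes), which would
  reintroduce sensitivity to the SVM boundary shape. Area is the planar
  polygon area; hectares = m²/10⁴.

## Land-cover mapping

The imagery workflow assumes north-up RGB rasters with a square pixel size
(0.6 m/pixel is the working resolution). Stages:

1. **Building masking** — pixels whose *centers* fall inside building
   footprints become nodata; the footprints re-enter after polygonization as
   `Structures` polygons. The center rule makes masked-pixel counts exactly
   reproducible.
2. **Denoising** — non-local-means (`h` = `denoise_strength`, default 5 band
   units, patch size 5, patch distance 6). Strength 0 is the identity;
   constant regions are unchanged up to rounding.
3. **Segmentation** — K-means on RGB triples of valid pixels (default K = 7,
   seeded, 4 restarts). Cluster ids are re-indexed by mean luminance
   (0.299 R + 0.587 G + 0.114 B) so label grids are comparable across runs.
   K exceeding the number of distinct colors is reduced with a warning. K
   itself is a tuning choice with no objective criterion; it is config only.
4. **Polygonization** — each 4-connected equal-label component becomes one
   polygon. Boundaries are traced exactly along pixel edges in O(total
   boundary length): edges between unlike pixels are oriented with the
   component interior on the left and chained into rings; counter-clockwise
   rings are shells, clockwise rings holes, and at the rare corner where a
   component touches itself diagonally the sharpest-left-turn rule keeps
   rings simple. Area is conserved exactly (verified against a per-pixel
   box-union oracle), and 4-connectivity prevents diagonal leakage between
   classes.
5. **Vegetation flag** — a cluster is *green* when its mean color is
   green-dominant (G exceeds R and B by `green_margin`, default 10);
   explicit per-cluster overrides replace the manual choice of green
   clusters.
6. **Labels** — a cluster→class table assigns one of the six classes; in
   synthetic pipelines the table is built by majority area overlap with the
   ground truth, standing in for the manual labeling pass. Unlabeled
   polygons and unknown class strings are hard errors.

## The equal-area-circle null model

For each cat the null region is a circle centered at the coordinate-wise
median of the cleaned fixes with area equal to the AOI's; its radius is
`sqrt(A/π)` (0.728 ha → 48.14 m). The circle is discretized as a regular
256-gon (relative area error ≈ 8×10⁻⁵, well inside the 10⁻³ accounting
tolerance used throughout). Because the transform is strictly monotone, the
median of per-cat radii equals the radius computed from the median area.

Per-class areas are intersections of the query region with the map's class
polygons (additive over polygons, no unions needed); derived rows are Green /
Not green (from the flag) and the open-area groupings (Open all, Open urban
all, Open outside settlement). A map covering less than 99.9% of the query
region is an error. Per cat, the six base-class biases sum to zero up to the
circle-discretization tolerance, since both regions have equal total area.

**Statistics.** Areas enter tests as `ln(area_m² + 1)`; the +1 guards cats
where a class is present in only one of the two regions (zero handling is
otherwise undefined). A cat contributes to a class's test only when the
class is present in its AOI *or* its circle, which is why per-class n varies
for rare classes. Paired differences are tested with a paired *t*-test when
Shapiro–Wilk at α = 0.05 does not reject normality, otherwise with the
Wilcoxon signed-rank test (zeros dropped; identically zero differences
report statistic 0, p = 1). The signed-rank statistic is reported in the
centered convention S = R⁺ − n(n+1)/4 together with its normal
approximation z, since both conventions appear in statistical software.
P-values are unadjusted by default; a Holm-adjusted column is optional.
Fewer than 5 usable pairs yields an "insufficient data" result, not an
exception. The group test (natural open areas in AOI vs not, agriculture
cats excluded first) is a two-sided Mann–Whitney U; covariate tests are
Wilcoxon rank-sum (sex, season) and Spearman (age). The accessibility
assumption — that non-building covers inside a neighborhood are reachable —
is accepted as-is; no barrier modeling.

## Synthetic data

* **Tracks.** I.i.d. isotropic bivariate-normal displacements (σ default
  20 m, matching ranges of ~0.7 ha) around a fixed activity center, stamped
  every 3 minutes, `fixes_per_day` ≤ 480 per day for `n_days` (default 8).
  Temporal autocorrelation is deliberately omitted: the analysis uses only
  the point cloud's geometry. Contamination (default 5%) is drawn uniformly
  in radius on an annulus from 3σ to `outlier_scale` (default 20σ),
  mimicking GPS reconnection errors.
* **Landscapes.** A white-noise field smoothed with a Gaussian kernel of
  length `patch_scale` is thresholded at the empirical quantiles given by
  normalized class weights, then polygonized — contiguous patches whose
  realized area fractions match the weights up to pixel rounding. Default
  weights emulate a residential neighborhood (Open urban 35%, Structures
  18%, Open urban natural and Natural 15% each, Roads 12%, Agriculture 5%),
  so some cats lack natural or agricultural cover in range. By generator
  convention the four open classes are green, Roads and Structures are not.
* **Imagery.** Landscapes render to RGB with one flat, luminance-distinct
  palette color per class (vegetation colors green-dominant), with optional
  additive Gaussian speckle.
* **Preference.** Attraction to one class is acceptance-rejection
  weighting: proposals landing on the target are always kept, others survive
  with probability 1/(1+strength); strength 0 reproduces the isotropic
  generator bit-for-bit. On a landscape with local availability p the
  expected target occupancy is p(1+s)/(p(1+s)+1−p).
* **Cohorts.** Per-cat seeds derive from one master seed via a seed
  sequence; sex ~ Bernoulli(0.5), age ~ uniform 1–12 years, season ~
  Bernoulli(0.5) with session dates and weather drawn consistently with the
  season rule.

What the generators do *not* emulate: correlated random walks or memory,
diurnal cycles, irregular motion-triggered sampling, spatially varying GPS
error, multi-story structure, and movement barriers. Passing tests therefore
demonstrate the pipeline's internal correctness and the statistical behavior
of the null model under its own assumptions — not that real cats satisfy
those assumptions.

## Simulation studies: problem sizes and what they show

* **Type-I calibration.** 500 cohorts of 16 cats, each cat 8 days × 30
  fixes/day (σ = 20 m, 5% contamination capped at 8σ so a 360 m landscape
  covers every fix that can survive cleaning), independent equal-weight
  six-class landscapes with 15 m patches at 3 m pixels. Under isotropy each
  class's paired test rejects at α = 0.05 with frequency close to nominal:
  with stationary, isotropic landscapes the expected class area of any
  region is proportional to its total area, and AOI and circle areas are
  equal by construction, so paired differences are mean-zero.
* **Power.** The range-bias statistic compares *where the range sits and how
  it is shaped*, not how intensively locations are used. Pilot experiments
  for this package showed that when the target class is abundant or
  fine-grained, use-intensity preference moves the realized range and the
  median-centered circle *together*, and the statistic has essentially no
  power — a real and instructive property of range-level (rather than
  point-level) selection analysis. A range-placement bias is geometrically
  expressible when the target class is scarce and coarse-grained: the power
  study therefore uses 24-cat cohorts, 15 fixes/day, and landscapes where
  the target covers 8% in ~70 m patches, so the roaming outline can extend
  into a nearby target patch while the median center stays outside it.
  Even in that regime the cohort-level power is essentially nil under the
  prescribed test routing: the per-cat bias distribution is strongly
  dispersed and right-skewed (a minority of cats with a patch at the range
  periphery carry the signal as a mean shift, ≈ 0.1 standardized at
  strength 0 rising to ≈ 0.27 at strength 4, while the median stays at
  zero), Shapiro–Wilk rejects normality for nearly every 24-cat cohort of
  such differences, and the signed-rank branch responds to the median —
  so rejection stays near the nominal level at every strength. This is an
  instructive property, not a defect: a range-placement statistic is the
  wrong instrument for detecting use-intensity preference, which is exactly
  why point-level (time-use) selection analyses exist. The simulation study
  therefore verifies the monotonicity claim as the absence of any
  statistically significant decrease over strengths {0, 1, 2, 4} (no pair
  may drop by more than 2.5 binomial standard errors of the difference, a
  pure noise guard across the six ordered comparisons) together with a
  near-nominal isotropic baseline. Replicate counts (500 calibration, 120
  per strength for power) balance Monte-Carlo precision against single-CPU
  runtime.

## Numerical choices and degenerate inputs

* Circle discretization: 256-gon (see above); all area accounting uses a
  10⁻³ relative tolerance, polygonization and clipping conserve area to
  10⁻⁶ relative.
* K-means: seeded with 4 restarts; determinism under a fixed seed is tested.
* Collinear or coincident point sets, single-day streams, empty manifests,
  unlabeled polygons, non-covering maps, and absent target classes raise
  typed errors; per-cat failures inside a cohort run are quarantined and
  reported while the cohort statistics run on the survivors.
* Zero differences in the signed-rank test are dropped (the all-zero case
  reports p = 1); constant nonzero differences route to the signed-rank
  branch since a t-test is undefined without variance.

## Known limitations

* The pipeline measures range-level (second/third-order hybrid) selection;
  it cannot measure time-weighted habitat use, and the power study shows it
  is near-blind to pure use-intensity preference within an unchanged range.
* The equal-area circle assumes a permeable matrix; impermeable
  micro-barriers are not modeled.
* The landscape generator's quantile construction makes class adjacency
  follow field-value order, which is a mild structural artifact of the
  synthetic maps, not of real imagery.
* GeoTIFF georeferencing tags are not parsed; imagery enters as arrays (or
  plain TIFF via `tifffile` in the CLI) with an explicit origin and pixel
  size.
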