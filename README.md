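# catrange

Roaming-range delineation and land-cover selection analysis for GPS-tracked
pet cats.

Owned cats that roam outdoors hunt wildlife, and management measures such as
buffer zones around sensitive habitat hinge on whether cats preferentially
roam into particular land-cover types. `catrange` implements, as a tested and
reusable pipeline, the analysis chain used to answer that question from
short GPS tracking sessions and fine-scale (sub-meter) aerial imagery:

1. **Fix cleaning** — the first tracking day is dropped as harness
   acclimation; erroneous fixes are rejected with a one-class SVM (RBF
   kernel, ν = 0.05, γ = 0.1 on standardized coordinates), retaining the
   central ~95% of fixes.
2. **Roaming area (AOI)** — the 95% minimum convex polygon: the convex hull
   of the inlier fixes, with area in hectares.
3. **Land-cover mapping** — RGB imagery is converted to a labeled polygon
   map: building masking, non-local-means denoising, K-means color
   segmentation (K = 7), exact polygonization of the label grid, a binary
   vegetation ("green") flag per polygon, and labels from a six-class scheme
   (Roads, Structures, Open urban, Open urban natural, Natural, Agriculture).
4. **Range-bias null model** — for each cat an *equal-area circle* is built:
   a circle centered at the median (x, y) of the cleaned fixes with area
   equal to the AOI's, representing isotropic non-selective roaming. The
   per-class *range bias* is `area(class ∩ AOI) − area(class ∩ circle)`;
   cohort-level inference uses paired tests on `ln(area + 1)` (paired *t*
   when the paired differences pass Shapiro–Wilk normality at α = 0.05,
   Wilcoxon signed-rank otherwise), plus a Mann–Whitney *U* comparison of
   AOI size between cats with and without natural open areas in range and
   Wilcoxon rank-sum / Spearman tests for sex, season and age.
5. **Synthetic data** — generators for fix streams (isotropic bivariate
   normal around an activity center with heavy-tailed annulus contamination),
   patchy multi-class landscapes (thresholded Gaussian random fields,
   polygonized), rendered RGB imagery, habitat preference
   (acceptance-rejection attraction to one class), and whole cohorts with
   metadata — so every stage is testable without field data.

A key quantity: a circle of area *A* has radius `r = sqrt(A / π)`, so an
AOI of 0.728 ha corresponds to an equal-area circle of radius ≈ 48.1 m —
typical owned-cat ranges are only a few dozen meters across.

## Worked example

```python
import catrange as cr

cfg = cr.TrackSimConfig(n_days=8, fixes_per_day=480, dispersion_sigma=20.0,
                        outlier_fraction=0.05, seed=7)
fs = cr.drop_acclimation_day(cr.simulate_track(cfg, cat_id="demo"))
cleaned = cr.filter_outliers(fs)
aoi = cr.delineate_aoi(cleaned)
circle = cr.equal_area_circle(cleaned, aoi.area_m2)
print(len(fs), cleaned.inlier_mask.sum(), round(aoi.area_ha, 3), round(circle.radius, 2))
```

prints

```
3360 3192 1.184 61.4
```

— 3360 fixes remain after the acclimation day, the SVM retains 3192 (95.0%),
the convex hull of the inliers covers 1.184 ha, and the isotropic null circle
with that area has a 61.4 m radius. `examples/` contains one narrative script
per capability (cleaning/delineation, imagery-to-map, full cohort analysis,
and the type-I/power simulation study); each prints the numbers it computes
and what they mean. A thin CLI mirrors the pipeline
(`catrange simulate | clean | segment | analyze | nullstudy`).

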