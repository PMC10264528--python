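# Methods

This note documents the measurement conventions, the synthetic-data model
and the numerical choices behind `nsnquant`, in the spirit of a methods
section a maintainer can audit.

## Segmentation

A nodule is segmented on one axial slice by intersecting a user-supplied
polygonal ROI with a fixed attenuation threshold.

* **Coordinates.** 0-based `(row, col)`, pixel centers at integer
  coordinates; pixel `(r, c)` occupies `[r−0.5, r+0.5] × [c−0.5, c+0.5]`.
  Stated once here, used everywhere.
* **Rasterization.** A pixel belongs to the ROI iff its center lies inside
  the polygon (even-odd rule); centers exactly on the boundary are
  included. Self-intersecting polygons are rejected.
* **Threshold.** Pixels with HU **≥ −800** (inclusive) are nodule
  candidates. The threshold value is standard for separating ground-glass
  tissue from aerated lung; the inclusive comparison is our fixed
  convention for bit-reproducibility, since either convention is defensible.
* **Post-processing.** 8-connected components; the largest is kept;
  interior holes (4-connected background) are filled — ground-glass cores
  can contain isolated low-density pixels that belong to the lesion.
  Connectivity is configurable.
* **Largest slice.** Across a slice stack, the slice with the maximal
  segmented area in mm² is analysed; ties go to the lowest index (logged).

Segmentation failures (nothing at threshold inside the ROI) raise an error
carrying the observed HU range so a pipeline can report them cleanly.

## The 12 features

* **Area** = pixel count × row spacing × col spacing (mm²).
* **Boundary and perimeter.** The outer contour is the marching-squares
  0.5-level polyline between mask and background. The raw polyline of a
  *binary* mask is a staircase whose length overestimates a smooth
  boundary by 5–7% at any scale (measured on digital disks from r = 20 to
  r = 200 px), which would cap the circularity of a perfect disk near
  0.90. We therefore regularize the contour with a circular moving average
  of its vertices (window 5), after which disk and ellipse perimeters are
  within 0.5% of their analytic values and disk circularity converges to
  ≈ 0.99. Contours with ≤ 12 segments are left raw so small-shape
  conventions stay exact (a single pixel is a diamond of perimeter 2√2; a
  2×2 block is the hand-computable octagon 4 + 2√2). The raw staircase is
  available via `smooth_window=1`, and a pixel-edge perimeter behind
  `pixel_edge_perimeter`.
* **Feret diameters** are computed on the convex hull of the *pixel
  corners* (not centers), so a one-pixel object has max √2 and min 1. The
  maximum is the largest hull-vertex pair distance; the minimum is the
  smallest hull width over hull-edge normals (the minimal width of a
  convex polygon is attained perpendicular to one of its edges). The
  reported Feret diameter is the mean of the two.
* **Intensity statistics.** Mean is arithmetic; median interpolates the
  midpoint for even counts; the mode is taken on integer-HU bins (values
  rounded to integers for the mode only) with ties resolved to the lowest
  HU; SD uses the sample (n−1) denominator. Skewness and excess kurtosis
  use population (1/N) moments — the mixed convention mirrors the lineage
  of common image-analysis tools and is asserted against direct-summation
  oracles to 1e−10. A Gaussian histogram gives kurtosis 0 (the excess
  convention is the only one consistent with near-zero cohort kurtosis
  medians that dip negative).
* **LMD** = area × (mean HU + 1000)/1000 in mg/mm — the 2D analogue of
  nodule mass (air ↦ 0, water ↦ 1 mg/mm³). Mean HU below −1000 is a domain
  error.
* **Shape.** Circularity = 4πA/P²; quantization can push a near-perfect
  digital disk slightly above 1, in which case the value is clamped to 1
  with a log note. Solidity = area / pixel-corner convex-hull area. Note
  the corner hull adds roughly P/2 pixels of area, so the solidity of a
  *convex* digital shape is ≈ 1/(1 + P/2A): it approaches 1 only for
  shapes tens of pixels across, which is why convexity checks use large
  rasters.
* **Repeat averaging.** Two measurement passes of the same nodule are
  combined by the element-wise mean of all stored fields. The averaged
  LMD is the mean of the two LMDs and therefore need not satisfy the
  single-measurement identity LMD = A(μ+1000)/1000 exactly.

## Growth model

Doubling time uses the exponential (Schwartz) model on LMD,
`DT = Δt ln2 / ln(LMD₂/LMD₁)`. A non-increasing LMD maps to `DT = +∞`
rather than a negative DT, so "median DT" style summaries are computed
over nodules with a positive LMD change only. The growing label is
`DT < cutoff` (strict); `DT = cutoff` is nongrowing. The default cutoff is
1,556 days, and the default risk cutoffs are skewness 0.90 and LMD
19.16 mg/mm; all are `RunConfig` fields.

## Synthetic CT model

The generator emulates 1-mm lung-window chest CT at 0.7 mm pixel spacing
(configurable):

* **Background** parenchyma is i.i.d. Gaussian, −900 ± 50 HU, clipped to
  the scanner range [−1024, 3071] HU. With these defaults ~2% of
  background pixels exceed −800 HU, which realistically stresses the
  threshold step with attached stray pixels.
* **Geometry.** Nodules are star-convex shapes given by a polar radius
  profile: ellipses, or Fourier blobs with harmonics k = 2…6 whose
  amplitudes scale with a `boundary_irregularity` knob in [0, 1]
  (amplitude 0.5·irr/√k); the profile is normalized so the enclosed area
  equals π(d/2)² for the requested equivalent diameter d. The baseline
  diameter is restricted to the 6–30 mm analysis window; follow-ups of
  grown nodules may exceed it.
* **Interior attenuation** is drawn i.i.d. from a shifted gamma law with
  shape k = 4/γ², scale σγ/2 and location μ − kθ, which hits a requested
  (mean μ, SD σ, skewness γ > 0) exactly in expectation. Requested
  skewness 0 falls back to a Gaussian; negative skewness is a
  parameterization error (the gamma family cannot produce it, and
  ground-glass histograms are right-tailed). SD 0 renders a constant
  interior and flags the moments as undefined.
* **Compositing.** Nodule values are blended over background with a
  one-pixel linear partial-volume band at the boundary (switchable off)
  and a per-pixel max against background, guaranteeing −800 HU
  separability of the interior.
* **Ground truth** couples the analytic boundary polygon (area, perimeter,
  Feret, circularity, solidity of the ideal shape) with the attenuation
  moments of the actually rendered pixels under the true mask, so both
  geometric and densitometric measurements can be checked against truth.
* **Growth pairs.** A follow-up realizes an exact LMD factor
  2^(Δt/DT), split geometrically between the area channel and the
  mass-equivalent attenuation channel (μ + 1000); the default split is
  50/50 because LMD couples size and density and either channel alone is a
  degenerate test. A factor whose density share would leave the nonsolid
  window (−800, −200) HU is refused with a diagnostic; the adaptive mode
  (used by the cohort simulator) shifts the excess into area, matching the
  observation that fast-growing lesions grow mostly in size. Cohort
  intervals are capped at 4 doubling times — fast growers are resected
  before many doublings accrue.

### Cohort simulation

Each nodule is assigned growing/nongrowing (default growing fraction
19/60 ≈ 0.32). The two **growth drivers** are drawn from group-conditional
laws calibrated to published growing-vs-nongrowing contrasts for
persistent NSNs: skewness is Gaussian per group (medians 1.12 vs 0.65,
IQRs ≈ 0.39) and LMD log-normal per group (medians 26.63 vs 12.81 mg/mm).
Every **other feature** is generated from the nodule's latent
growth-likeness score — the symmetric average of standardized skewness and
log-LMD — plus independent noise sized so the within-group IQRs match
their targets. Consequently (i) per-group feature medians converge to the
configured targets as n grows, and (ii) conditionally on skewness and LMD
no other feature carries outcome information, reproducing the structure
in which only those two survive multivariable selection. Area is derived
exactly as 1000·LMD/(mean + 1000), Feret and perimeter from area and
circularity, so every row satisfies the LMD identity.

Doubling times are log-normal (median 2,816 days, σ_log 1.50) truncated to
the assigned group's side of the 1,556-day cutoff; 25% of nongrowing
nodules are fully stable (DT = ∞). Scan intervals are log-normal (median
1,136 days, σ_log 0.66). Covariates (age 64.6 ± 11.4 y; male 0.417;
smoker 0.40; cancer history 0.483; emphysema 0.15; upper lobe 0.75) are
drawn independently of outcome. Rater noise for reliability studies adds
per-feature Gaussian noise with variance s²(1−ρ)/ρ to both measurement
sets, targeting a single-measurement absolute-agreement ICC of ρ
(default 0.88).

With `render_images=True` the cohort is materialized as actual scan
pairs and the feature table holds *measured* values from the full
segmentation + extraction pipeline. Measured attenuation features then
carry partial-volume bias (the blend band pulls the mean down and damps
skewness) — a property of real 2D measurements that the feature-level mode
does not model. Statistical studies (stepwise retention, AUC
calibration) use the feature-level mode, which is exact in distribution
for the drivers and orders of magnitude faster; image-level tests verify
the measurement chain itself.

### What the generator does not emulate

Scanner PSF and reconstruction-kernel texture (backgrounds are white
noise), vascular/bronchial structures crossing the nodule, part-solid
transformation, respiratory motion, inter-reader ROI variability (rater
noise is additive Gaussian on features, not on contours). Passing tests
therefore demonstrate correctness of the measurement and inference chain
under a controlled model, not clinical performance.

## Statistics

* **ICC** is the two-way, absolute-agreement, single-measurement form
  ICC(A,1), from the two-way ANOVA mean squares; zero between-nodule
  variance is reported as NaN (degenerate), not as agreement.
* **Mann–Whitney U** uses average ranks. For pooled n ≤ 12 the null
  distribution is enumerated over all group assignments of the observed
  values — exact in the presence of ties; otherwise a normal approximation
  with tie-corrected variance and continuity correction is used.
* **Spearman** correlations take average ranks with the t-approximation
  on n − 2 df. Infinite doubling times are valid ranks (stable nodules are
  the slowest growers).
* **Logistic regression** is IRLS/Newton maximum likelihood, convergence
  at max|score| < 1e−8 or 50 iterations, with step damping. Complete or
  quasi-complete separation is detected (diverging coefficients or
  perfectly pinned fitted probabilities) and flagged; a separated fit is
  never reported as a finite huge odds ratio. Wald z tests are reported,
  matching the OR/β/p presentation convention.
* **Backward stepwise**: univariate screening at p < 0.05 seeds the
  multivariable model; the worst predictor is dropped while its Wald p
  exceeds 0.10 (a common backward-elimination default; configurable), and
  the elimination order is logged. Under near-collinearity — and LMD is
  *definitionally* collinear with area × density — elimination can keep a
  proxy instead of the driver in a minority of replicates; this is an
  inherent property of the procedure, not an implementation artifact.
* **ROC**: empirical curve over distinct score thresholds (positive iff
  score ≥ threshold); AUC via the tie-corrected rank statistic, which
  equals the trapezoidal area exactly including ties; the optimal cutoff
  maximizes Youden's J = sensitivity + specificity − 1, ties resolving to
  the lower cutoff. A cost-ratio criterion can be substituted by scanning
  the returned (threshold, sensitivity, specificity) table.

## Problem sizes used in tests

Oracle-equivalence tests use random blobs ≤ 10⁴ pixels (Feret brute force
on blobs of a few hundred pixels, where the all-pairs oracle is
tractable). Moment recovery uses ≥ 10⁴ interior pixels. Parameter-recovery
studies use 18-mm nodules at 0.5 mm spacing with the scan interval set to
1.2 DT, a well-conditioned design (the DT estimate's relative error scales
as 1/ln(LMD ratio), so intervals ≪ DT are noise-dominated); cohort
statistics use 20 feature-level cohorts of n = 500. The end-to-end
image-rendered cohort test uses n = 60, the size of a typical
single-center NSN series.

## Known limitations

Purely 2D (largest-slice) analysis by design; no volumetric or
deep-learning segmentation. The Youden cutoff estimator on n ≈ 500 samples
has substantial variance (≈ 0.05–0.1 on the skewness scale). DT recovery
degrades for nodules measured over intervals much shorter than their
doubling time. DICOM support covers single-frame CT rescale/spacing only.
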