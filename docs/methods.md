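# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `nucmorph`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Per-nucleus features

A nucleus is the set of pixels carrying one positive label in an instance
map registered to an 8-bit sRGB patch, with a microns-per-pixel (MPP)
scalar converting pixel measurements to physical units. The default MPP of
the synthetic generator is 0.25 µm/px, the typical value of ×40 slide
scans.

**Area** is the pixel count times MPP². **Axis lengths** follow the
ellipse-of-inertia convention: 4·√λ for the two eigenvalues λ of the 2×2
covariance matrix of pixel-center coordinates, matching the dominant
regionprops convention; **eccentricity** is √(1 − (minor/major)²).

**Perimeter** uses the 4-direction Crofton line-integral estimator. The
choice was made by benchmarking candidate boundary estimators against the
Ramanujan closed-form perimeter of rasterized ellipses over the generator's
size range (semi-axes 10–35 px): the √2-weighted chain-code length
overestimates by up to ~5%, marching-squares contour length by ~6–9%, and
a convex-hull-plus-π estimator errs up to ~3.8%, while 4-direction Crofton
stays within ~2–3% with near-zero mean bias. Crofton is also a standard,
deterministic choice available in scikit-image. **Circularity** is the
form factor 4πA/P²; its error inherits area and perimeter errors
(≈ |ε_A − 2ε_P|), so it carries a wider tolerance than the axis lengths
(see "Numerical tolerances"). **Solidity** is the pixel count divided by
the number of pixels whose center lies in the convex hull of the
instance's pixel centers; for collinear instances (zero-area hull) it is
defined as 1.

**Color** statistics are computed over the instance's own pixels with
fixed, documented transforms: Rec.601 luma on the 0–255 scale for
grayscale; the HSV S channel (0–1) for saturation; CIELAB a\*/b\* under
sRGB with D65 white point and the 2° observer. All SDs use the sample
(n−1) convention and are defined as 0 for single-pixel instances.

Degenerate instances (empty, single pixel, collinear) raise by default; a
`permissive` flag floors the minor axis at 1 px instead. Multi-component
instances (one label, several islands) are treated as a single pixel set
with a warning, preserving upstream label semantics. Border-touching
nuclei are included; there is no minimum-size filter by default (both
configurable), since exhaustive whole-slide analysis implies inclusion.

## Slide-level aggregation

Each slide row holds, per cell class, the mean and sample SD of each of
the 15 features over that class's nuclei — 30 named columns per class,
`MEAN[<CLASS>_NUCLEUS_<FEATURE>]_H&E` / `STD[...]`. A class with no nuclei
yields missing values (absence is never zero-filled, which would bias
morphology means); one nucleus yields a defined MEAN and missing STD.
Feature values are sorted before summation so aggregation commutes exactly
(bitwise) with record reordering. Downstream analyses drop slides with
missing analysis columns and log the count.

## Segmentation metrics

Binary Dice compares binarized foregrounds only. AJI matches each
ground-truth instance, in ascending id order, to the not-yet-used
prediction of maximal IoU (ties to the lowest prediction id); matched
pairs contribute intersection/union, unmatched ground truth and unused
predictions contribute their full size to the denominator. The fully
deterministic tie policy is a refinement of the canonical greedy
definition; both metrics are defined as 1.0 when both maps are empty and
are computed in pixel space (overlap metrics are unit-free). An
object-level Dice (ground-truth-size-weighted) is emitted as a secondary
output; the binary form is canonical. All metrics are verified against an
independent brute-force re-implementation on exhaustive small
configurations.

## Synthetic ground truth

**Patches.** Nuclei are ellipses with semi-axes drawn i.i.d. from
N(14, 2.5²) px truncated below at 10 px (larger draw = semi-major), angle
uniform, placed by rejection sampling so rasterized footprints plus a 1-px
margin are disjoint and fully inside the canvas. Rasterization is hard
(pixel-center strictly inside, no anti-aliasing) so the area and solidity
oracles are exact. Rendering flat-fills each instance with its class's
CIELAB color converted to 8-bit sRGB (hematoxylin-like hues on a
near-white L=95 background), plus optional i.i.d. Gaussian noise. Analytic
truth per ellipse: area πab·MPP², axes 2a/2b·MPP, Ramanujan perimeter,
eccentricity √(1−(b/a)²), solidity 1, color means from the quantized fill
color, color SDs 0.

What this emulates and what it does not: the generator reproduces the
*measurement problem* (known geometry and color per instance at realistic
sizes and pixel scale) but none of the hard parts of real H&E — touching
and overlapping nuclei, chromatin texture, stain variation, out-of-focus
regions. Passing recovery tests therefore validates the estimators, not
segmentation robustness on real tissue.

**Cohorts.** Slide-level nuHIF columns are independent unit-variance
Gaussians with optional per-group and per-subtype mean shifts in SD units.
Aneuploidy and HRD scores are affine-plus-noise functions of the z-scored
designated atypia feature (SD of cancer nuclear area); whole-genome
doubling is Bernoulli with logistic probability in the same feature.
Survival is exponential — the simplest model satisfying proportional
hazards, so Cox recovery is well-posed — with hazard
h₀·exp(β·z(feature)), h₀ = 0.01/month, and independent uniform censoring
U(0, b) with b solved so the expected censoring fraction matches the
requested rate (default 0.2). Expression plants a gene block sharing a
Gaussian-copula rank correlation with the designated feature: the latent
Pearson r is set to 2·sin(π·ρ_s/6) so the *Spearman* correlation hits the
requested magnitude — Spearman is invariant to the (normal) marginals
chosen. The gene-set collection contains the planted set plus seeded decoy
sets. Every generator is a pure function of (parameters, seed).

Independent nuHIF columns are a deliberate simplification: real nuHIFs are
strongly correlated within feature families. Planted-signal recovery rates
here therefore bound the idealized, not the collinear, case.

## Cohort statistics

- **Standardization:** plain z-score per column (constant columns flagged,
  never divided by zero); robust z-score (x − median)/(IQR/1.349), the
  scale constant making one unit ≈ one SD under normality.
- **Clustering summary:** per-group medians of z-scored features,
  average-linkage agglomerative clustering with Euclidean distance,
  deterministic leaf order.
- **Classification:** stratified 5-fold CV, folds seeded; default learner
  a 100-tree random forest with balanced class weights (scikit-learn
  defaults otherwise), injectable behind a fit/predict_proba contract —
  the protocol (folds, weighting, AUROC), not the learner internals, is
  the contribution. AUROC is computed by the Mann–Whitney rank formula
  with tie midranks and cross-checked against brute-force pair counting
  and scikit-learn. Features are passed unstandardized to the (scale
  invariant) tree learner. WGD counts binarize as any-doubling vs none;
  top-5 mean impurity-decrease importances are reported across folds.
- **Correlation:** Spearman as Pearson on midranks; two-sided p by the t
  approximation for n ≥ 10 and exact permutation enumeration below that.
  Constant inputs are an explicit error, not NaN.
- **Multiple testing:** Benjamini–Hochberg step-up within each screen
  (per survival endpoint, across genes, across pathways), never pooled
  across screens, matching per-analysis reporting.
- **Survival:** per-feature Cox proportional-hazards fit of the robust
  z-scored feature with age and ordinal stage covariates (partial
  likelihood via lifelines); Wald 95% CI and p; rows with missing
  stage/survival excluded and counted; non-convergence flagged per row,
  never silently dropped. The Kaplan–Meier median-split analysis assigns
  ties (= median) to the high group ("≥ 50th percentile") and reports the
  log-rank p plus a covariate-free Cox HR on the binary indicator — the
  screening fit with covariates is a separate, also exposed, path.
  Because hazards are planted on the SD-scale z but screened on the
  sample-IQR robust z, the Wald CI carries no scale-estimation noise and
  its empirical coverage sits near 90–92% rather than the nominal 95%;
  the acceptance suite measures this directly.
- **Gene association/enrichment:** vectorized per-gene Spearman (t
  approximation, cohort-scale n) with BH across genes; positive/negative
  sets at q < 0.05 and ρ strictly beyond ±0.15; one-sided hypergeometric
  overlap enrichment against a user-supplied collection with BH across
  pathways, sorted by p, top 10 at q < 0.05. Thresholded overlap replaces
  ranked-list enrichment: the screen already reports pathway overlaps on
  selected sets, and ranked GSEA is out of scope.
- **Embedding prep:** z-scored matrix plus a recorded parameter block
  (100 neighbors, 2 dimensions, Euclidean); the embedding itself is
  delegated to an external implementation.
- **Stage encoding:** AJCC strings collapse to ordinal 1–4 via an
  editable JSON table shipped with the package; unknown strings map to
  missing, not errors.

## Numerical tolerances

Raster quantization bounds what any estimator can achieve, and the
recovery tests assert at the level the estimators support over the
generator's size range (min semi-axis 10 px): area ≤ 2%, perimeter and
axis lengths ≤ 3%, solidity ≤ 3%, color means within 1.0 per channel
(8-bit round-trip bound). Circularity compounds area and perimeter errors
and is asserted within [0.95, 1.05] of truth. Eccentricity is
ill-conditioned near circles — de/d(b/a) = (b/a)/e diverges as e → 0, so
its *relative* error is unbounded for near-circular nuclei regardless of
estimator — and is therefore asserted on the well-conditioned squared
scale, |e² − e_true²| ≤ 0.06, the propagation of the 3% axis tolerance
through e² = 1 − (b/a)².

## Problem sizes

The test and acceptance runs use 20 patches × 50 nuclei for feature
recovery, 200 random 8×8 configurations for metric oracles, two groups of
400 slides for classification calibration, 100 (tests) or 50 (script)
seeds at 800 slides for Cox recovery, and 5,000 genes with a 100-gene
planted block at n = 800 for the association screen — sizes at which the
planted effects are comfortably identified while a full run stays within
minutes on one CPU.

## Known limitations

- No texture features beyond per-nucleus intensity SDs (none are modeled
  by the generator either).
- The grayscale/saturation scales (0–255 and 0–1) are fixed conventions;
  other tools may normalize differently.
- Aggregation covers whatever records are provided; no tissue masking or
  spatial stratification.
- The AJI tie policy (lowest prediction id) is one deterministic
  refinement of the greedy definition; implementations that allow
  prediction reuse or process ground truth in a different order can differ
  on pathological configurations.
- Synthetic cohorts have independent features, exponential survival, and
  uniform censoring; calibration results transfer to real cohorts only to
  the extent those assumptions hold.
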