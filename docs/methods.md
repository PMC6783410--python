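# Methods

`gliorad` re-implements, as a tested pipeline, an MRI-radiomics analysis of
newly diagnosed glioblastoma: per-case texture/shape/location feature
extraction from three structural MR sequences and two lesion volumes of
interest, followed by two independent modeling arms — supervised principal
component (SPC) survival stratification, and L1-penalized logistic
prediction of the MGMT-promoter methylation label and of long-term
survival — and a combined radiomic + molecular risk grouping. Because the
original cohort's images are not public, a synthetic phantom cohort with
planted, analytically known structure stands in for the study data; every
stage is validated against that ground truth or against independent
brute-force oracles.

## Image preprocessing

Each case carries non-contrast T1, Gd-enhanced T1 (Gd-T1) and T2 volumes
plus two manually drawn lesion masks (enhancing core on Gd-T1; T2
high-intensity lesion on T2). Registration between sequences is *not*
estimated here; externally produced 4×4 world-to-world affine matrices are
accepted and applied by trilinear (images) or nearest-neighbour (masks)
resampling. The synthetic cohort is generated pre-aligned, so the default
transform is the identity.

Intensity normalization maps every series to 256 integer gray levels:

* **T1-like series** (T1, Gd-T1): the 99.9th percentile of in-brain
  intensities is the cutoff; voxels strictly above it are treated as
  high-signal noise and marked *invalid* (they stay in the rectangular
  grid but are excluded, via a validity mask, from every downstream
  statistic — histogram, co-occurrence pairs and runs never cross them).
  The remaining range [in-brain min, cutoff] is quantized into 256
  equal-width levels (`level = floor(frac·256)`, clipped to 255).
* **T2**: the full in-brain range is quantized the same way; nothing is
  deleted.

The percentile is computed over brain-mask voxels only (nonzero voxels
when no explicit mask is supplied); whether the original procedure used
brain-only or whole-image support is not documented, so this is a package
decision. Degenerate (constant) inputs map to level 0.

Two derived series are built from the normalized inputs:

* **T2Edge** — the 3-D Prewitt gradient magnitude of the normalized T2
  (per-axis separable 3×3×3 kernels: derivative [−1,0,1], smoothing
  [1,1,1]); the magnitude is re-mapped to 0–255 over the valid voxels, and
  validity is eroded by one voxel because a border voxel's kernel support
  leaves the valid set. The filter is genuinely volumetric, not
  slice-wise, for consistency with the 3-D texture operators.
* **Gdzscore** — a voxel-wise contrast-enhancement map. No closed formula
  for this series is published, so the package defines it as the
  z-scored level difference: `D = level(GdT1) − level(T1)` on jointly
  valid voxels, standardized to zero mean / unit population SD, then
  re-mapped to 0–255. A zero-spread difference (no enhancement) yields an
  all-zero series.

## VOIs and location analysis

`VOI_core` is the enhancing-lesion mask on the Gd-T1 grid. `VOI_edema` is
the T2 lesion mask (resampled to the Gd-T1 grid) minus the core, so the
two are disjoint by construction. All texture extraction runs on
native-grid VOIs; only location analysis maps VOIs — nearest-neighbour —
onto a 1 mm isotropic MNI152-space grid (182×218×182, origin
(−90, −126, −72) mm). Only the grid geometry is used; the atlas template
volume itself is never needed. Location features are centroid (atlas mm),
volume (mm³), and left/right fractions split at the midline x = 0 (x > 0
is the right side under this affine; midline voxels count half to each
side). The original study never enumerates its "location data", so this
minimal set is a package decision; location columns are appended to the
feature table but are *not* part of the 489-name texture catalog.
Voxelwise lesion frequency maps across cases support the symmetry
inspection.

## The 489-feature texture catalog

Per (series, VOI) combination — 5 series (T1, T2, T1Gd, T2Edge, Gdzscore)
× 2 VOIs (core, edema) — the extractor reports 48 features:

* **14 first-order** histogram statistics of the valid in-VOI levels:
  mean, median, min, max, range, population variance, skewness and excess
  kurtosis (biased moment estimators; 0 for constant input), energy
  (mean squared level), base-2 entropy over the 256-level histogram, P10,
  P90, IQR, RMS.
* **11 GLCM statistics × {Mean, SD}** over the 13 unique direction
  offsets of the 26-neighbourhood at distance 1 voxel: contrast,
  correlation, energy, entropy, homogeneity, dissimilarity,
  autocorrelation, cluster shade, cluster prominence, sum average,
  maximum probability. Each direction's matrix counts in-VOI valid voxel
  pairs in both orders (symmetric) and is normalized to sum 1.
* **6 GLRLM statistics × {Mean, SD}** over the same 13 directions:
  short-run emphasis, long-run emphasis ("Lrge"), gray-level
  non-uniformity, run-length non-uniformity, run percentage, low-gray-run
  emphasis. Runs are maximal same-bin segments along a direction, broken
  by out-of-VOI or invalid voxels; per direction the run-length mass
  equals the VOI voxel count (asserted at run time).

That is 48 × 10 = 480, plus **9 shape features** (core and edema volume,
mesh surface area, sphericity `π^(1/3)(6V)^(2/3)/A`, maximum 3-D
diameter, and the edema/core volume ratio): **489 names** total, with the
grammar `{Series}_{voi}_{Family}{Stat}[_{Mean|SD}]` (e.g.
`T1Gd_core_GLRLMLrge_SD`). The full per-family decomposition of the
original catalog is not published; this decomposition is the package's
construction of the printed total and is frozen in `gliorad.catalog`.

Numerical choices: gray-level matrices use 32 equal-width bins of the
in-VOI [min, max] (256-level matrices are nearly empty on small VOIs;
configurable). Note this re-binning is *relative*: it removes amplitude,
so a texture field's standard deviation does not move GLCM contrast under
it — contrast responds to amplitude only when binning is fixed on the
absolute 0–255 scale, which is how the generator-linkage test measures
it. Surface areas come from marching cubes on a lightly smoothed
(Gaussian σ 0.8 voxel) mask — a raw binary isosurface overestimates a
ball's area by ~9 % — with a binary fallback for structures too thin to
survive smoothing. The maximum 3-D diameter is the largest pairwise
distance between surface voxel centres (convex hull pre-reduction). VOIs
with fewer than 8 valid voxels, and empty edema VOIs, yield explicit
missing values; the feature vector always carries all 489 keys, and
downstream models impute missing values by the training-cohort median.

## Supervised principal component survival model

1. Each feature (standardized; cohort-median imputed) receives the
   univariate Cox partial-likelihood **score statistic** at β = 0,
   `U/√I`, with Breslow handling of ties — for a binary feature this is
   exactly the signed square root of the log-rank statistic (tested).
2. Features with |score| above a threshold θ are retained. θ is tuned by
   stratified (by event indicator) k-fold cross-validation: per fold and
   candidate θ, screening and the first principal component are computed
   on the training portion, held-out cases are scored on the trained
   loadings, and the fold records the Cox likelihood-ratio statistic of
   the held-out score. The tuned θ maximizes the mean held-out statistic
   (ties resolved toward the sparser θ). The default grid is 30 points
   spanning the 50th–99th percentile of |score|; a fixed θ (e.g. the
   original study's tuned 1.69) can be supplied directly.
3. The continuous risk score is the first PC of the standardized retained
   submatrix, oriented so a higher score means a higher hazard (the sign
   of a one-covariate Cox fit, Newton's method, Breslow ties). The
   discrete high/low classification splits at the *median training
   score* — the original description specifies two-group discrete
   prediction but not the cut rule.
4. Feature importance is the Pearson correlation between each retained
   standardized feature and the continuous score (the original importance
   formula is not given; this is a documented stand-in).

Standardization parameters, medians, loadings, the Cox coefficient and
the cut are frozen at training time and serialized to JSON.

## L1-logistic prediction (methylation label, long-term survival)

The penalized path uses scikit-learn's liblinear solver at
`C = 1/(n·λ)` with a large intercept scaling (the intercept is
effectively unpenalized; at λ_max the model reduces to the empirical
log-odds). The path is 100 log-spaced λ values from
`λ_max = max|X'(y − ȳ)|/n` down to 0.001·λ_max; λ_min minimizes the mean
k-fold binomial deviance, and the final model is refit on all data at
λ_min. Reported performance always comes from **nested** CV: 10 outer
folds, inner λ tuning on the training portion only (verified by an
id-tracing test), held-out classification at probability 0.5, metrics
(accuracy, sensitivity, specificity, PPV, NPV, prevalence) computed on
each repeat's pooled outer-fold predictions and averaged over 5 repeats.
The package's own nested runs use a 50-point inner λ grid to keep the
inner loop proportionate; the grid length is configurable.

Long-term-survivor labels at a cutoff: death before the cutoff → short;
observed time at or beyond it → long; censored strictly before it →
excluded (status unknown — the original handling of censored patients is
not stated, so exclusion is the documented choice). Cutoffs whose
labeling is single-class or leaves too few cases are reported as not
modelable rather than failing, mirroring the gaps in the original sweep.

## Survival analysis and combined risk

Kaplan-Meier estimation, the log-rank test and the multivariate Cox fit
are delegated to lifelines. Conventions fixed here: median survival is
the first time S(t) ≤ 0.5 and is left undefined (not interpolated) when
the curve never reaches it; age and KPS enter the Cox model untransformed
(HR per unit); the 3-level surgery factor is dummy-coded against total
removal and reported as all three pairwise contrasts (the
biopsy-vs-partial contrast from the coefficient difference and
covariance) *plus* a global 2-df Wald test, since the original table's
single shared p-value is ambiguous between the two. lifelines uses Efron
tie handling; the synthetic cohort's continuous times are tie-free, where
Efron and Breslow coincide, and the hand-written univariate score/Newton
fits use Breslow throughout. Combined risk is the fixed three-class rule:
high = radiomic high AND unmethylated, low = radiomic low AND methylated,
everything else intermediate.

## The synthetic phantom cohort

Each case is an axis-aligned ellipsoidal enhancing core (radii uniform in
8–14 mm) with a uniform-thickness edema shell (5–12 mm) inside a brain
ellipsoid, on a 48³–64³ grid at 2 mm spacing. Tissue classes get fixed
sequence-specific means (e.g. edema hyperintense on T2, core enhancing on
Gd-T1) plus white acquisition noise (SD 4). The core on Gd-T1 additionally
carries a Gaussian random texture field — white noise smoothed with a
Gaussian of width equal to the planted correlation length (2–6 mm) and
rescaled to the planted SD (`heterogeneity`, 5–25 intensity units).

Overall survival is exponential proportional hazards: rate
`h₀·exp(lp)` with `h₀ = ln2/15` per month (median ≈ 15 months for an
average lesion, as reported for GBM), and
`lp = 0.7·z(heterogeneity) + 0.4·z(log core volume) + 0.5·(1 − met)` —
hazard ratios of ≈2.0 per SD of heterogeneity, ≈1.5 per SD of log volume,
and ≈1.65 for unmethylated status, so the radiomic and molecular factors
are both prognostic and only partly overlapping, as in the study cohort.
Standardizations use the closed-form mean/SD of the sampling
distributions, so the linear predictor is exact ground truth (a Cox fit
of the true predictor recovers coefficient 1.0, tested). Censoring is an
independent exponential (0.02/month, ≈25–35 % censored). The
methylation-like label is Bernoulli with logit `0 − 0.8·z(heterogeneity)`
— a weak association in the direction reported (more heterogeneous
texture → unmethylated). Clinical covariates (age, sex, KPS, surgery) are
drawn independently of imaging so multivariate independence tests have a
known null. All randomness flows from one master seed; case *i* uses the
stream seeded by (seed, *i*), making cases independent and
order-insensitive, and the whole cohort bit-reproducible.

What the phantoms do *not* emulate: MR physics (bias fields, partial
volume, multi-site scanner effects), non-ellipsoidal lesion geometry,
infiltrative margins, or any real anatomical context. Passing tests
therefore demonstrate that the pipeline's operators and models are
correct and recover planted effects under their stated assumptions — not
that the extracted features are biologically meaningful on clinical
images.

## Problem sizes and reproduction

The acceptance script (`scripts/acceptance.py`) regenerates everything
from scratch at sizes the package treats as its standard experiment:
a 100-case phantom cohort for the end-to-end imaging pipeline; 50
replicates of the SPC screening recovery (n = 250, 50 features, planted
hazard ratio 2–3 per SD); n = 200 with 50 features for the nested-CV
LASSO null calibration and planted-effect power; nested CV with 10 outer
folds and a survivor sweep at 12 and 15 months. The full-width analyses
(8-cutoff sweep, 5 repeats everywhere) live in the `analysis/` drivers.

## Known limitations

* The 489-name catalog reproduces the printed feature *count* and naming
  style, not necessarily the original feature-by-feature composition.
* Gdzscore, the location feature set, the importance score, the discrete
  cut rule, the censored-survivor handling and the 0.5 probability
  threshold are all documented package choices where the original
  procedure is silent.
* Registration estimation, bias-field correction, skull stripping and
  nonlinear distortion correction are out of scope; masks and transforms
  are inputs.
* With θ tuned and evaluated through cross-validation on the same cohort,
  discrete-stratification p-values carry some selection optimism; the
  null-behaviour test documents the observed false-positive rate.
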