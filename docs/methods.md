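# Methods

## The fill-state marker

PET biomarkers of Alzheimer-type pathology are conventionally summarized
as SUV ratios: mean tracer uptake in a composite target region divided by
mean uptake in a reference region assumed pathology-free. The SUVR is a
marker of *intensity*. This package implements a complementary marker of
*spatial extent*, the **fill state**: the percentage of meta-ROI voxels
whose deviation from a normative cohort is individually significant.

For a subject volume $x$ spatially normalized to template space:

1. **Intensity normalization.** $\mathrm{SUVR}(v) = x(v)/\bar{x}_{\mathrm{ref}}$,
   where $\bar{x}_{\mathrm{ref}}$ is the mean over the reference-region
   mask. By construction the output averages 1 over the reference region.
2. **z-standardization.** Against a control model built from amyloid-negative
   cognitively normal subjects: voxelwise sample mean $\mu(v)$ and sample
   SD $s(v)$ (denominator $n-1$), giving
   $z(v) = (\mathrm{SUVR}(v) - \mu(v))/\max(s(v), s_{\min})$.
3. **Voxel classification.** A voxel is abnormal iff it lies inside the
   meta-ROI and $z(v) > 1.65$ (amyloid, tau) or $z(v) < -1.65$
   (neurodegeneration, a hypo-signal). 1.65 is the smallest two-decimal z
   with one-tailed exceedance below 5%; the inequality is strict, so a
   voxel exactly at the cutoff is negative.
4. **Markers.** Fill state = 100 × (abnormal voxels)/(usable ROI voxels);
   SUVR = mean intensity over the ROI; abnormal-voxel intensity = mean z
   over abnormal voxels only (undefined — not zero — when nothing is
   abnormal).

Under the null (a subject drawn from the control distribution), each ROI
voxel is abnormal with probability $1-\Phi(1.65) = 4.947\%$, which is the
expected fill state of a healthy subject and the false-positive floor of
the marker. With a lesion of fractional extent $f$ and effect size
$\delta$ local SDs, the expected fill state is approximately
$100f\,\Phi(\delta - 1.65) + 100(1-f)(1-\Phi(1.65))$; at $\delta = 5$ this
is $\approx 4.95 + 95.05f$, i.e. a regression of fill state on $100f$
should have slope ≈ 0.95 and intercept ≈ 5.

### Numerical choices and degenerate inputs

- **SD floor.** Control voxels with sample SD below $s_{\min} = 10^{-6}$
  SUVR units (possible with identical or constant inputs) are clamped to
  $s_{\min}$ and counted in a log message; this prevents infinite z while
  leaving ordinary voxels untouched.
- **Alignment.** Two grids are aligned iff shapes match and affines agree
  elementwise within $10^{-4}$. No resampling is performed: inputs are
  assumed to be in a common template space already, and misalignment is an
  error, not a warning.
- **Missing data.** Non-finite subject voxels inside the ROI are excluded
  from both the numerator and the denominator of the fill state (and from
  the ROI mean), and logged. A ROI with no usable voxel is an error.
- **Cutoffs are configuration.** Per-modality cutoff and direction are
  plain parameters, so robustness analyses with alternative cutoffs or
  whole-brain gray-matter masks are a one-argument change.
- **No small-sample t correction**: z uses the plain Gaussian
  standardization; the control sample size is recorded but does not enter
  the denominator.

## Statistics battery

- **Staging**: Kruskal-Wallis H across SCD/MCI/dementia (midranks, tie
  correction, $\chi^2_{k-1}$ p) with post hoc Mann-Whitney U. Mann-Whitney
  uses exact enumeration when the combined sample is ≤ 16 and tie-free,
  otherwise the normal approximation with tie-corrected variance and
  continuity correction. Both delegate to scipy.
- **ROC comparison**: AUC via the rank (Mann-Whitney) formulation, ties
  counted ½, so AUC ≡ U/(n₊n₋) identically. Correlated AUCs for the two
  markers measured on the same subjects are compared with the DeLong
  structural-components estimator: per-subject placement components
  V₁₀/V₀₁ estimate the covariance matrix of the two AUCs;
  z = ΔAUC/SE(Δ) with a two-sided normal p (configurable sidedness). A
  zero-variance difference (e.g. one marker a monotone transform of the
  other) is flagged degenerate rather than divided through.
- **Partial Spearman**: all variables are rank-transformed (midranks);
  x- and y-ranks are residualized on the ranked covariates by least
  squares and the Pearson correlation of residuals is returned, with a t
  p-value on n − k − 2 df. With no covariates this is exactly Spearman's
  rho. The construction is invariant under strictly monotone transforms of
  any variable and matches the rank-precision-matrix identity to 1e-10.
- **Reflect-and-square-root transform** for left-skewed cognitive scores:
  t(x) = √(max(x)+1 − x). Strictly decreasing, so association signs invert
  downstream; the reflection constant affects only the coefficient scale,
  never ranks or significance.
- **Regression models 1–4**: a multivariate linear model over the block of
  cognitive scores. Models 1–3 use one modality's fill state + SUVR + age
  + sex + education; model 4 uses all three fill states + covariates.
  Per-term multivariate significance is Wilks' lambda with Rao's F
  approximation (statsmodels MANOVA) — chosen as the default criterion of
  mainstream statistical software; with a single response it reduces
  exactly to the univariate partial F. Univariate OLS per score supplies
  coefficients with 95% CIs. Sex is a 0/1 indicator, education in years,
  predictors unstandardized. Rank-deficient designs raise an error naming
  the collinear terms.
- **Significance tiers**: α = .05, Bonferroni-corrected α (α/m, displayed
  to 3 decimals: .05/3 → .017), and α = .001 are reported side by side.

## Phantom cohorts

The synthetic generator exists so that every claim above is testable
without access-controlled imaging data. It emulates the *statistical*
structure of a PET cohort, not PET physics.

- **Geometry** (32³ default grid): meta-ROI = centered ellipsoid with
  semi-axes (14, 13, 12) voxels (≈ 28% of the grid, 9160 voxels);
  reference region = disjoint 3-slice slab; gray matter = enclosing
  ellipsoid. Configurations whose ROI touches the reference slab are
  rejected.
- **Normative fields**: μ(v) smooth in [1.0, 1.4] SUVR and σ(v) smooth in
  [0.05, 0.15], built by Gaussian-filtering seeded white noise
  (smoothness 4 voxels) and min–max rescaling — smooth, anatomically
  uneven baselines against which a fixed intensity threshold would fail.
- **Controls**: voxelwise independent Normal(μ(v), σ(v)). Noise is
  independent across voxels by default; a smoothing option exists because
  real PET is spatially correlated, but all quoted tolerances assume the
  default.
- **Patients**: a control-path background plus a contiguous lesion grown
  by breadth-first accretion from a random ROI voxel to ⌊f·N_ROI⌉ voxels,
  shifted by ±δ·σ(v) (default δ = 5, hyper-signal for amyloid/tau,
  hypo-signal for neurodegeneration). A "scattered" lesion mode (random
  voxels) supports extent-vs-intensity dissociation experiments. f = 0
  reproduces the control path bit for bit.
- **Cohorts**: group lesion fractions CN/SCD/MCI/dementia =
  0.02/0.10/0.30/0.55 with SD-0.05 jitter (clipped to [0, 1]); age ~
  N(70, 7) truncated [50, 90]; education ~ N(14, 3) truncated [8, 22];
  sex ~ Bernoulli(0.5); all three modality volumes of a subject share one
  true fraction. Cognitive scores (global/memory/executive, MMSE-like and
  z-like scales) are linear in (f, age, sex, education) with negative f
  loadings and Gaussian noise. Subjects with true amyloid fraction < 0.05
  are labeled amyloid-negative; amyloid-negative CN subjects form the
  control sample. All generation is a pure function of (config, seed);
  control sample size defaults to 40, a typical normative-cohort size.

What passing tests on phantoms do **not** show: robustness to spatial
autocorrelation, scanner effects, registration error, partial-volume
effects, or off-template anatomy. The phantom establishes internal
statistical validity of the marker pipeline, not clinical performance.

## Control-free CNN estimator

Computing a fill state requires a control cohort. The CNN estimator
removes that requirement at inference time: it is trained to regress the
control-based fill state directly from the SUVR volume, after which
`estimate()` takes only an image.

Architecture (sized for 32³ CPU training): four 3×3×3 stride-2
convolution blocks with ReLU (channels 8-16-32-32), global average
pooling, one dense unit, sigmoid output in [0, 1] (×100 for percentage
points). Implemented in NumPy with an im2col forward/backward pass and
Adam; training is exactly deterministic given the config seed (fixed
initialization, split, and batch order). Loss is mean absolute error, the
headline evaluation metric. Inputs are standardized by a fixed affine map
((x − 1.2)/0.3). Defaults: learning rate 3e-3, batch 16, 40 epochs, 70/30
train/validation split.

The bounded sigmoid head means estimates are clipped to [0, 100] and
clipping is logged; an unbounded linear head is available behind
`bounded_output=False` for fidelity experiments with out-of-range
estimates. One estimator is trained per modality.

On the default desk-scale benchmark (200 phantom subjects, 70/30 split)
the validation MAE is ~1.5–3 percentage points with r² ≈ 0.96–0.99, and
the CNN estimate carries the same covariate-adjusted correlation with the
synthetic memory score as the control-based truth to within ~0.01
Spearman — the clinical-validity check. An external phantom cohort with
different normative fields degrades r² but leaves it positive; absolute
performance on shifted distributions is not a claim this package makes.

## Problem sizes

Default analyses use 32³ grids, 40-control models, 120-subject cohorts for
the staging/correlation battery, 200 subjects for the CNN benchmark, 2000
replicates for type-I-error calibration, and 10,000 permutations for the
DeLong cross-check. These sizes put every Monte-Carlo estimate comfortably
inside its quoted tolerance while keeping a full run on one CPU in the
minutes range.

## Known limitations

- No spatial normalization, resampling, or partial-volume correction;
  inputs must share the template grid exactly.
- The phantom's independent voxel noise makes the null fill-state variance
  smaller than in smooth real data; tolerances calibrated here would widen
  under spatial correlation.
- The DeLong test's sidedness is configurable but defaults to two-sided.
- The amyloid-positivity SUVR threshold (default 1.11, the conventional
  florbetapir literature value) is a configuration parameter, not a
  validated claim.
- The CNN estimator is specific to the grid, field ranges, and modality it
  was trained on; checkpoints record their config for this reason.
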