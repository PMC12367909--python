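# Methods

`radsurv` implements a complete analysis chain for predicting biochemical
recurrence-free survival (BCRFS) after prostate radiotherapy from
T2-weighted MRI radiomics, hypoxia gene-signature scores and clinical
variables, together with a synthetic cohort generator so every stage is
exercisable — and testable — without access to patient data. This note
records the models, the defaults and why, the numerical conventions, and
the places where a design was genuinely open.

## Synthetic cohort model (`synthcohort`)

Each patient consists of a 3D image with an ellipsoidal prostate mask,
clinical covariates, two hypoxia scores, and a right-censored outcome.

**Clinical marginals.** Calibrated to a high-risk radiotherapy cohort:
age ~ truncated Normal(70, 5²) on [52, 80] years; PSA ~ LogNormal with
median 20 ng/mL and log-SD 0.85 (giving a 2–230 ng/mL range at n≈178);
ISUP grade categorical with probabilities (2.8, 37, 20, 9, 31.2)%;
T-stage (T1..T4) = (2.2, 19, 78, 0.8)%; treatment EBRT-alone with
probability 0.803 (else HDR boost + EBRT); tumour volume ~ LogNormal
(median 5 mL, log-SD 1.0). Hypoxia scores are bivariate Gaussian —
Ragnum-32 ~ N(0.30, 0.215²), West-28 ~ N(1.40, 1.03²) — with correlation
0.5; only medians and ranges of the real scores are public, so Gaussians
matched to those summaries are the simplest faithful choice, and the
correlation is configurable because the joint distribution is unknown.

**Planted image texture.** Each image is a stationary Gaussian random
field: white noise smoothed with an isotropic Gaussian kernel of width
ℓᵢ (mm), rescaled to unit variance, then mapped to T2w-like units
(300 + 100·field). ℓᵢ ~ LogNormal(median 2 mm, log-SD 0.35) is the
scalar "texture dial": grey-level co-occurrence and wavelet statistics
track correlation length monotonically, so a hazard that depends on
s = standardized log ℓ is recoverable by the downstream radiomics.
Scanner b applies an affine intensity map x → a_b·x + c_b with gains in
[0.8, 1.25] and offsets in [−20, 20], drawn once per scanner — exactly
the class of batch effect Nyúl standardization and ComBat are meant to
remove.

**Outcome model.** Exponential baseline (proportional hazards hold
exactly): hazard = h₀·exp(βᵀ(z−μ_z) + γ·s), with covariates centered at
their theoretical means so h₀ is the hazard of an average patient.
Default β are the log hazard ratios of the reference clinical model
(age −0.051/yr, PSA 0.00995/ng·mL⁻¹, ISUP 0.285/grade, T3 1.058,
volume 0, EBRT 0.438) and γ = 0.8 per SD of s, a deliberately
detectable planted effect. Censoring is Uniform(28, 140) months
(median 84 months, matching the study's median follow-up) with an
administrative cap at 140 months; the real censoring mechanism is
unreported, so independent uniform censoring is an explicit assumption.
h₀ = 0.0037 events/month was calibrated by simulation so the marginal
event fraction is 32.0% (Monte-Carlo SE 0.1% over 800 cohorts), the
recurrence rate of the reference cohort.

All randomness flows from one integer seed through three named
`SeedSequence` spawns (scanner effects, patient attributes, outcomes),
so cohorts are bitwise reproducible and adding outcome draws never
perturbs patient attributes.

**What the generator does not emulate:** prostate anatomy, PSA
kinetics, spatially heterogeneous tumour texture, non-affine scanner
effects, informative censoring, or gene-expression matrices. Passing
tests therefore demonstrate that the *pipeline machinery* is correct
and calibrated, not that the real-data effect sizes are reproduced.

## Intensity standardization (`imgprep`)

Nyúl-style piecewise-linear histogram standardization: each training
image's [1, 99] percentile window is mapped linearly onto [0, 100] and
the landmark percentiles {1, 10, 20, …, 90, 99} are averaged across
images to form the standard scale. At application time an image's own
landmarks are mapped onto the standard scale by piecewise-linear
interpolation with linear extension beyond the outer landmarks. The
landmark set and whether histograms are mask-restricted are exposed in
config because neither is canonical. Affine (gain/offset) scanner maps
are removed exactly: affinely related images standardize to voxelwise
identical outputs. Re-applying the transform is an identity up to
percentile-interpolation error, which scales with the inverse histogram
density — the practical tolerance at 20³-voxel test images is ~10⁻².

Resampling to isotropic voxels uses SimpleITK (linear for intensities,
nearest-neighbour for masks, nearest-neighbour extrapolation at the
boundary). Grey levels are discretized to a fixed **bin number** over
the ROI min–max (half-open bins, last bin closed, constant ROI → level
1); bin number is preferred over bin width because MR intensities have
no absolute unit even after standardization.

## Texture features (`texturefeat`)

Seven feature classes: shape, first-order, GLCM, GLRLM, GLSZM, GLDM,
NGTDM, each toggleable so the feature budget is auditable. Matrix
features follow the standard (IBSI-style) definitions; every formula is
checked against an explicit-loop oracle to 1e-10 in the tests.
Conventions that matter:

* **Wavelet filter bank**: single-level *undecimated* separable 3D
  transform (sub-bands stay aligned with the mask), Coiflet-1 filters,
  symmetric boundary; sub-band letters denote the filter applied along
  axes (0, 1, 2) in that order. Implemented as direct per-axis
  convolution, which imposes no even-dimension restriction.
* **Re-discretization per sub-band**: wavelet outputs are signed with
  their own ranges, so each filtered volume is discretized on its own
  ROI min–max before matrices are built.
* **GLCM**: 13 unique 3D directions, distance 1, symmetric, normalized
  per direction; features averaged over directions (a merged-matrix
  switch is not provided; averaging is the common default). Kurtosis is
  uncorrected (Normal → 3).
* **GLSZM** zones use 26-connectivity; **GLDM** dependence counts the
  centre plus 26-neighbours within grey-level tolerance α = 0; **GLRLM**
  runs are maximal per direction.
* Degenerate matrices (e.g. a single-voxel ROI) yield NaN — "undefined",
  never silently zero. Downstream stages drop all-NaN columns.

## Batch harmonization (`combat`)

Location/scale empirical-Bayes harmonization: features are standardized
by the batch-design fit, per-(batch, feature) location effects get a
Normal prior and scale effects an Inverse-Gamma prior with
moment-matched hyperparameters, estimated by iterative conditional
updates to relative tolerance 1e-6 (parametric mode) or by the
empirical-prior Monte-Carlo weighting over the other features'
estimates (nonparametric mode). Two documented choices:

* **Population-variance convention (`ddof=0`, default).** With it,
  harmonizing duplicated (effect-free) batches is an exact identity.
  `ddof=1` reproduces the Bioconductor reference implementation
  bit-for-bit (verified in a test against `sva::ComBat`, parametric and
  nonparametric) up to the re-centering below.
* **Grand-mean re-centering.** EB shrinkage moves a feature's overall
  mean by O((1−B)·σ); since batch harmonization should remove
  *between*-batch contrast and nothing else, each adjusted feature is
  re-centered to its original column mean exactly.

Biological covariates are *not* protected by default (a `covariates=`
argument enables protection). Zero-variance features pass through with
a warning. Known property, inherited from the canonical algorithm and
demonstrated in the tests: the nonparametric variant's per-feature
residual batch differences have wider tails than the parametric
variant's, because its prior support is the discrete set of other
features' effects; its aggregate (mean over features) shift removal
matches the parametric variant.

## Robustness screen (`robustsel`)

ICC(2,1) — two-way random effects, absolute agreement, single
measurement — computed per feature with **quantization settings as the
raters** and patients as subjects. This is this package's convention:
what the "raters" were in the original analysis (settings, scanners, or
repeat delineations) is not derivable from its description, and
settings-as-raters is the only choice exercisable without repeat scans.
ICC(3,1) is available by switch since settings could also be viewed as
fixed judges. A feature is robust when ICC > 0.8; each setting's robust
set is the robust features it extracts to finite values, and the
winning setting maximizes that set (ties → larger bin number, then
smaller voxel). Estimates below zero are reported as computed.

## Feature selection (`cvselect`)

Unsupervised: (1) remove features with |Spearman ρ| > 0.5 against
tumour volume — the volume-confounding screen is read as a correlation
threshold, since a p-value cutoff of 0.5 would not be a coherent
confounding filter and ρ is the named statistic; (2) iteratively
resolve pairs with |Pearson r| ≥ 0.5 by removing the member with the
larger mean |r| to all remaining features (pairs scanned by descending
|r|, all ties broken by feature name — fully deterministic).

Supervised, compared over 40 repeats of event-matched 5-fold CV (events
and censored patients dealt round-robin to folds, so per-fold event
counts differ by ≤ 1; 200 train/test samples):

* **univariable** — Wald p < 0.05 in a single-feature Cox model;
* **multivariable** — 1-df likelihood-ratio p < 0.05 for adding the
  feature to the clinical Cox model;
* **mrmr** — greedy ranking with relevance = |univariable Cox Wald z|
  (the survival stand-in for mutual-information relevance; a C-index
  based alternative is available), redundancy = mean |Pearson r| to the
  already-selected set, stopping when the best score ≤ 0 or `max_k`.
  Note that with this score pure-noise candidates often run to `max_k`
  (a noise |z| averages ≈ 0.8, exceeding typical redundancy); early
  termination is guaranteed only when redundancy is high.

Per run, features are z-scored with training-fold statistics, the
selected set joins the six clinical covariates in a Cox model fitted on
the training folds, and Harrell's C is computed on both folds from that
model's linear predictor. No test-fold information reaches any
selection or scaling decision; the test suite enforces this with a
canary feature equal to the test-fold outcome, whose selection
frequency must stay at noise level. Methods are ranked by the rank-sum
of median train and test C (ties → higher median test C, then name);
the final set is the winner's features by descending selection
frequency, truncated to its median per-run selected count. Runs whose
fit fails (e.g. a fold where a covariate is constant) are recorded,
excluded from medians, and counted in the summary.

## Survival modelling (`coxsuite`)

Cox proportional hazards fitted by Newton–Raphson with analytic
gradient and Hessian, Efron tie handling by default (Breslow by
switch), step-halving, convergence when the largest step component
< 1e-9. Wald CIs come from the observed information. Monotone
likelihood (risk separation) is detected (|β| > 50) and reported with
the offending covariate; zero-variance or collinear designs are
rejected up front. Fits agree with `lifelines` to its own convergence
tolerance, and exactly (gradient ≈ 1e-15) at the optimum.

Harrell's C uses the classical convention: pairs are comparable when
the earlier observed time carries an event; tied risk scores count ½;
no comparable pairs → undefined (error), not 0.5.

Model comparison: nested LR chi-square with Δk degrees of freedom. The
AIC identity LR = AIC_base − AIC_ext + 2Δk lets the same test be
reconstructed from two printed AIC values (`compare_from_aic`); the
quantity exp(−ΔAIC/2) is also reported for transparency but is a
calibrated p-value only at Δk = 2. A reconstructed LR < 0 returns p = 1
with a warning.

The four-model ladder (clinical / +hypoxia / +radiomics / +both) uses:
age, PSA (raw ng/mL — the reference hazard ratio of 1.01 per unit
indicates an untransformed scale; log-PSA by switch), ISUP as one
ordinal numeric covariate, T-stage grouped T1/2 vs T3+, tumour volume,
treatment indicator; hypoxia scores as-is; radiomic features z-scored
on the full data (the CV-internal scaling uses training folds only —
full-data scaling is applied exactly where the final models are fitted
on the complete cohort). Each extended model is compared to the
clinical baseline by the nested LR test. Internal validation refits the
model on bootstrap resamples (event-free resamples redrawn, failures
counted) and scores the *original* cohort with each bootstrap model's
coefficients; the 95% CI is the 2.5/97.5 percentile interval.

## Pipeline and CLI (`pipeline`, `cli`)

Stages run in a fixed order inside a run directory, persist every
intermediate (NIfTI cohort, Nyúl model JSON, raw and harmonized feature
CSVs, selection summary, model report), and log version, seed and a
config hash. Stages communicate only via files, so `radsurv simulate`,
`extract`, `select`, `model`, … can each be re-run alone; `radsurv run`
executes everything. Exit codes: 2 config errors, 3 data/convergence
errors.

## Problem sizes in the shipped tests

The test suite exercises the chain at sizes chosen for a laptop-class
single core: 16³–24³ voxel grids, cohorts of 60–500, 20–50 simulation
replicates, 200 CV samples for the null-calibration check. These sizes
give Monte-Carlo tolerances (3 SE bands, binomial pooled SEs) that the
assertions state explicitly.

## Known limitations

* The generator's texture dial is a global correlation length; it does
  not create focal lesions, so feature *selection* frequencies on
  synthetic data concentrate on a broader family of correlated texture
  features than a focal pathology would.
* Proportional hazards are exact in the generator; the Cox machinery
  includes no Schoenfeld-type diagnostics.
* The robustness screen's raters-are-settings convention is one of
  several defensible readings (see above).
* Nonparametric ComBat inherits the canonical algorithm's per-feature
  tail behaviour documented above.
* DICOM handling, bias-field correction, 2D texture, LoG filters,
  competing risks and time-varying covariates are out of scope.
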