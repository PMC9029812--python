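# Methods

`metclass` implements a classification pipeline for LC-MS metabolomic and
lipidomic feature tables from case/control cohorts, of the kind used to
separate Parkinson's disease, Alzheimer's disease, and healthy-control
cerebrospinal fluid. This note records the statistical model at each
stage, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## Pipeline order

For a training set the stages run in a fixed order:

1. **detrend** (optional) — per-feature gradient-boosted regression on
   run index, age, and sex; residuals carried forward.
2. **standardize** — per-feature observed-entry mean 0, sample variance 1
   (ddof = 1); constants retained for transforming held-out rows.
3. **MAD mask** — entries beyond k median absolute deviations of the
   feature median become missing.
4. **missingness filter** — features missing in more than 50% of
   subjects are dropped (exactly 50% is kept).
5. **multiple imputation** — m = 5 completed copies, fit on training
   rows only.
6. **weighted logistic elastic net** per copy, lambda by cross-validated
   deviance; held-out subjects predicted by reduced-feature modeling.

Masks only grow until imputation. In leave-one-out evaluation every one
of these stages, including the imputation and all scaling constants, is
refit per fold from the training rows alone; the held-out subject's
values can reach the fold only through its own prediction.

MAD masking is applied after detrending, on residuals, matching the
order in which correction and outlier removal are described for the
workflow this package reproduces; a flag supports the other order. The
MAD is unscaled (no 1.4826 consistency factor), reading "k median
absolute deviations" literally; the scale factor is configurable. When a
feature's MAD is zero but the data are not constant the threshold is
degenerate, so nothing is masked and a warning is raised.

The test row is screened against the training MAD bounds as well:
outlying test entries are treated as missing and handled by the
reduced-feature path, on the view that processing-noise outliers are
equally implausible wherever they occur. The preprocessing stages are
plain composable functions, so the alternative orderings (MAD before
detrending, or trusting test-row outliers) are available by composing
them differently; the pipeline default is the order listed above.

## Drift and covariate detrending

Each feature is regressed on (run index, age, sex) with gradient-boosted
trees (`xgboost`, squared error, exact splits), because run-order drift
in LC-MS batches is often nonlinear and discontinuous at batch
boundaries, which linear detrending misses. Hyperparameters are chosen
per feature by 5-fold CV over a small fixed grid: depth {2, 3}, rounds
{50, 200}, learning rate {0.1, 0.3}. The grid is deliberately tiny for
determinism and desk-scale runtime; it is configurable.

The lower bound of 50 rounds matters. A boosting run's total shrinkage
budget (rounds x learning rate) caps the fraction of a trend it can
represent; at 25 x 0.1 = 2.5 the fit retains ~7% of an amplitude-2
drift, and because that underfit bias costs less held-out MSE than the
extra variance of the larger configurations, CV selects exactly that
corner and leaves residual rank correlation ~0.1-0.15 with run order. At
50 x 0.1 = 5 the bias is negligible while CV still prefers the
low-variance corner; measured post-detrend |Spearman rho| is <= 0.06
across linear, step, and sine drifts. The cost is more noise-fitting on
truly covariate-free features (roughly 15-30% variance removed at
n = 400); since every feature is re-standardized afterwards, this
inflates no downstream statistic, but it is why the variance-preservation
test asserts a 30% band rather than a tighter one.

Detrending never sees phenotype labels, so it cannot leak them.
Features with fewer than 10 observed values fall back to a mean-only
detrend with a warning.

## Weighted logistic elastic net

The fitted criterion is

    min_{b0,b}  -(1/n) sum_i w_i [ y_i eta_i - log(1 + e^{eta_i}) ]
                + lambda sum_j pf_j [ (1-alpha) b_j^2/2 + alpha |b_j| ]

with eta_i = b0 + x_i'b. This is the standard weighted binomial negative
log-likelihood plus penalty (the same criterion glmnet minimizes); the
ridge term uses ||b||^2/2. Observation weights default to inverse class
proportions, w_i = n / (2 n_class(i)), so each class carries total weight
n/2; weights are normalized to sum to n, which makes the fit invariant
to duplicating rows while halving weights. alpha defaults to 0.5:
variable selection without a lasso-style hard cap of n on the number of
selected variables. Per-feature penalty factors pf_j allow age and sex
to enter unpenalized (pf = 0) in the missingness models; the intercept
is never penalized.

The solver is a penalized-IRLS cyclic coordinate descent written for
this package (numba kernels): quadratic approximation at the current
linear predictor, coordinate updates over an active set, exact-gradient
KKT scans to admit violators, warm starts down a log-spaced lambda path
from lambda_max (the smallest penalty with an all-zero penalized
solution) to lambda_max x 1e-3 over 100 points. Solutions satisfy the
KKT conditions of the criterion to ~1e-7 at the default tolerance; the
test suite checks the attained objective against an independent
high-precision L-BFGS-B solver on a split-variable formulation.

lambda is the arg-min of cross-validated held-out binomial deviance
(weighted by the observation weights), ties broken toward the larger,
sparser lambda; the 1-SE rule is deliberately not used. Inside the outer
leave-one-out loop, lambda is re-selected per fold and per imputation
copy by an inner 10-fold stratified CV by default; exact inner LOO is
available (`inner_cv="loo"`) at roughly 12x the cost. Whether the
original analysis re-selected lambda inside each outer fold or reused
one value is ambiguous; re-selecting is the conservative (leak-free)
reading and is the default here.

Consensus odds-ratio tables keep a feature only when its coefficient is
nonzero in all m imputation fits and exp(mean beta) lies outside
[0.9, 1.1]; the reported interval is exp(mean +- 2 SD) across the m
fits. Because features are standardized, an OR is per 1-SD increase.

## Multiple imputation

Missing abundances are modeled as multivariate normal and imputed with
an EM-with-bootstrap scheme: copy j bootstraps the training rows, fits
(mu, Sigma) by EM, and draws the missing entries of the original
training rows from their conditional normals; copy j is seeded seed + j.
A ridge prior shrinks Sigma toward the identity with weight 0.5% of n
pseudo-observations (abundances are standardized, so the identity is the
natural prior scale). EM converges on the observed-data log-likelihood
at relative tolerance 1e-4, max 200 sweeps; non-convergence falls back
to conditional-mean imputation with a warning.

When p > 200 the features are imputed in blocks of 50 against 20 leading
principal components appended as complete anchor columns. The anchors
come from the fully observed features when at least as many exist as the
requested PCs; under entrywise missingness at realistic rates no feature
is complete, and the anchors are then PCs of the mean-filled training
matrix. This keeps each covariance problem at ~70 dimensions against
~n rows instead of p >> n, at the price of ignoring residual
between-block covariance beyond what the anchors carry.

EM iterations are SQUAREM-accelerated: two EM sweeps define a squared
extrapolation of the parameter pair (mu, Sigma); the step is backtracked
toward the plain EM step until the extrapolated Sigma is positive
definite and a stabilizing sweep does not lose likelihood (a 1% dip
allowance, recovered by the stabilizing sweep, avoids rejecting nearly
all productive steps). The fixed point is untouched; the sweep count
drops from ~150 to ~30-50 on typical blocks, which is what makes
fold-internal imputation inside a 120-fold LOO loop affordable on one
CPU. Each row's E-step works through the precision matrix, so its cost
is O(d^2 + m^3) for m missing entries rather than a dense solve per row.

Held-out rows are never imputed. `apply_to_newrow` exists only to raise
a contract error; prediction with missing test features goes through
reduced-feature modeling: by default the fold's elastic net is refit on
the training data restricted to the test row's observed features at the
fold's selected lambda ("refit"); the cheaper "drop" strategy zeroes the
coefficients of unobserved features, which after standardization equals
mean substitution. Training-set MAD outliers are imputed like any other
missing entry; test-row outliers are dropped (reduced-feature) rather
than imputed.

## Missingness-indicator analysis

Presence/absence indicators (1 = observed) are taken from the mask after
MAD masking but before the 50% filter — profiles with extreme
missingness are exactly the ones whose presence patterns carry signal,
so filtering first would destroy the analysis. Constant columns are
dropped with a log entry. The indicator matrix is complete by
construction, so the same LOO elastic-net machinery runs without
imputation; age and sex enter unpenalized and indicators are
standardized like any feature (the reported ORs are therefore per SD of
a binary indicator — an odd but deliberate convention kept for
comparability with the abundance tables). Per-feature univariate
logistic regressions of the indicator on phenotype (+ age, sex) with BH
correction flag individually informative missingness patterns;
separation triggers a small-ridge refit that is marked in the output.

## Univariate scans and enrichment

Each feature is separately regressed against disease status (logistic,
feature as predictor), complete cases per feature; Wald z and two-sided
p; BH step-up within each (profile, ion mode) stratum, since ionization
modes are analyzed separately downstream. Untargeted results are
exported as the 4-column tab-separated input consumed by
pathway-activity tools (m/z, retention time, p-value, t-score), one file
per ion mode; the pathway permutation machinery itself is out of scope —
the file format is the interface boundary. For named (targeted) panels,
overrepresentation uses the hypergeometric tail P(X >= k) with the ORA
universe defined as all features surviving preprocessing in the relevant
profile, BH across sets; raw overlap fractions are reported alongside
because near-misses (2 of 3 members) are informative even when no set
reaches significance. The built-in drug-exclusion list carries the
monoisotopic masses of levodopa, entacapone, and seven metabolites
(populated from public compound references and cross-checked by
elemental-composition arithmetic); the filter removes features within a
closed +-1 m/z window by default, with no adduct expansion.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
at the scale of the motivating study: three groups of 85/57/56 by
default; phenotype-conditional ages 53.7 +- 20.3, 70.6 +- 9.8, 65 +- 10
(truncated normal on [20, 90]); female fractions 41/85, 29/57, 17/56;
assay batches of 28 filled round-robin within phenotype strata (a
stand-in for covariate-balancing batch assignment that reproduces the
balance downstream stages rely on); a global run order drawn as a random
permutation; LEDD and GBA flags for the PD group only. Default profile
widths are 6735 / 108 / 1070 features with per-phenotype missing rates
chosen to average to 16% / 3% / 81% overall while preserving the
observed ordering (controls most missing, PD least). Tests pass explicit
smaller sizes; the defaults are the study-scale conditions.

Features are baseline + phenotype effect + age/sex trends + drift +
unit Gaussian noise. Signal features default to a 1.5 SD group contrast
with random sign per disease group. Drift adds a unit-scale shape
(linear ramp, single step at a random position, or a 1.5-cycle sine with
random phase) times the configured amplitude, with a random sign per
feature. Missingness mechanisms: MCAR (uniform), MAR (rate modulated by
age), MNAR-phenotype (per-phenotype rates), and MNAR-abundance
(deterministic left-censoring of the lowest values per feature).

The "latent" signal mode exists for the exclusion-robustness analysis: a
subject-level disease factor u (unit noise plus a group offset) loads at
0.8 on the designated signal features and at 0.3 on a wider set of
secondary features, emulating pathway-level leakage of a disease
signature across many correlated metabolites. This structure is what
makes "remove the first model's support and refit" a meaningful
robustness probe: with only a small exchangeable informative block, an
alpha = 0.5 elastic net selects essentially the whole block and
exclusion would trivially destroy the signal, which contradicts the
multiplicity-of-good-models phenomenon the analysis is designed to
exhibit. The loadings (0.8 primary / 0.3 secondary) were fixed a priori:
0.8 gives a realistic near-duplicate-feature correlation of ~0.64 within
the primary block, and 0.3 leaves each secondary feature individually
weak while the ensemble still identifies u.

What the generator does **not** emulate: raw spectra, QC-pool runs,
peak-picking artifacts, heavy-tailed abundance distributions,
between-feature correlation beyond the latent factor, storage-time or
collection-site confounding, and LEDD pharmacokinetics. Passing tests
therefore certify the statistical machinery (no leakage, calibrated
nulls, recovery of planted structure), not performance on any real
cohort.

Ages can be overridden per group (`age_means`, `age_sds`). The null
calibration runs (the MCAR missingness control and the univariate
type-I check) use matched ages, because with the study's own age gaps a
zero-phenotype-effect cohort is not a null: the unpenalized age
covariate separates groups in the indicator model, and per-feature age
trends make abundances phenotype-associated through confounding — the
channel detrending removes in the full pipeline.

## Numerical choices and degenerate inputs

- Elastic-net coordinate descent: probabilities clipped to [1e-8,
  1 - 1e-8], linear predictors capped at +-30, convergence on the
  glmnet-style weighted squared coefficient change (1e-14 for single
  fits, 1e-8 inside CV), exact-gradient KKT scans between active-set
  passes.
- lambda_max with unpenalized covariates is computed at the null model
  containing the intercept and those covariates (Newton fit).
- Cross-validated deviance uses clipped probabilities (1e-10) and skips
  folds whose training labels collapse to one class, with a warning.
- Zero-variance features are dropped at standardization; constant
  features detrend to zero residuals; all-constant indicator columns are
  dropped before missingness modeling.
- Tie-breaks: lambda ties go to the larger lambda; BH uses a stable
  mergesort so equal p-values adjust identically.
- Per-fold randomness derives from CRC32 of the held-out subject id plus
  the run seed, and training rows are processed in canonical subject-id
  order, so results are invariant to shuffling the input rows.  The
  inner-CV partition is re-drawn per outer fold from that same per-fold
  seed: one partition shared across folds couples with which class lost
  its member and shifts the null.
- Out-of-fold scores are quantized at 1e-8 (the solver's convergence
  resolution) before ROC/AUC.  With class-balanced weights an empty fold
  model's prediction is the weighted prior, exactly 1/2 up to rounding
  dust whose sign tracks the held-out subject's class; ranking that dust
  manufactures AUC out of nothing (a pure-noise LOO run can reach AUC
  1.0 without quantization).  Quantized dust ties at 1/2 and contributes
  1/2 per pair, as the Mann-Whitney convention intends.

## Problem sizes used in tests

The acceptance-style tests run the full pipeline at n = 120 subjects
with 300-500 features (m = 5 imputations, inner 10-fold CV), the
missingness analysis at n = 140 with 300 indicators, and drift removal
at n = 402 — the latter because the null width of a Spearman correlation
is ~1/sqrt(n), and at cohort scale (n ~ 200) even a perfectly detrended
feature exceeds |rho| = 0.1 about 16% of the time. These sizes were
chosen as the smallest at which each property is cleanly identified.

## Known limitations

- The imputation model is Gaussian; heavy-tailed or left-censored
  abundance distributions are imputed only approximately (MNAR-abundance
  censoring is generated, but the imputer does not model the censoring
  mechanism — matching the analysis it reproduces).
- Reduced-feature "refit" reuses the fold's lambda rather than
  re-selecting it on the reduced feature set.
- Elastic-net coefficient inference (p-values, intervals beyond the
  across-imputation spread) is out of scope.
- The pathway permutation analysis of the export target is not
  reimplemented; only its input format and hypergeometric ORA are.
- Pooled leave-one-out AUC with data-driven feature selection is not an
  exactly unbiased null statistic: each subject's data influences the
  other folds' selected features, and ranking scores across folds mixes
  that information.  On null draws where a chance feature is strong
  enough to be selected stably, the pooled AUC can drift well above 1/2
  even though every fold is individually leak-free.  The evaluation
  reports what the pooled-score design measures; null-calibration runs
  quantify the drift rather than hide it.
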