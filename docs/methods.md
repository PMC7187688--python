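# Methods

`ethnoprs` implements an ethnicity-stratified polygenic risk workflow for a
dichotomous disease outcome (the motivating application is COPD) with a
continuous endophenotype (an FEV1-like lung-function trait) available for
SNP screening. This note documents the models, the synthetic cohorts the
test suite runs on, and the numerical choices.

## The screening model

SNP screening operates on the continuous trait, not the binary status. The
trait for sample vector `y` follows the genomic mixed model

    y ~ MVN(Z beta, sigma_g^2 K + sigma_e^2 I)

where `Z` holds the fixed clinical covariates (intercept, age, sex, height,
pack-years of smoking) and `K` is the genetic relationship matrix
`K = (1/m) sum_j x_j x_j'` over standardized dosage columns
`x_j = (g_j - 2 p_j) / sqrt(2 p_j (1 - p_j))`. Variance components are
estimated by REML; SNP heritability is `h^2 = sigma_g^2 / (sigma_g^2 +
sigma_e^2)`.

Each SNP's screening score is the best linear unbiased prediction

    u = G' K^-1 (y - Z beta_hat) / sigma_g_hat^2

with `G` the same standardized matrix that built `K`. The division by
`sigma_g^2` (rather than the multiplication the mixed-model equations
would give) fixes only the scale: screening keeps the `p` SNPs of largest
`|u|`, and any positive rescaling of `sigma_g^2` rescales all scores
equally, so the selected set is unaffected. Score magnitudes are therefore
not comparable across tools. The alternative criterion keeps the `p`
smallest p-values from per-SNP OLS of the trait on (covariates, genotype).

### REML numerics

* Single component: `K = U diag(lambda) U'` is computed once; the restricted
  likelihood is profiled over `h = sigma_g^2/(sigma_g^2+sigma_e^2)` on the
  rotated data (each evaluation is O(n q^2)), located by a 101-point grid
  plus bounded Brent refinement, then polished by average-information
  Newton steps on the analytic gradient in the eigenbasis. The `h = 0`
  boundary is admissible and reported with a converged flag.
* Multi-component (chromosome-partitioned): damped average-information
  updates with an EM fallback whenever an AI step leaves the feasible
  region or decreases the restricted likelihood, components projected onto
  the non-negative orthant, followed by the same undamped AI Newton tail
  when all components are interior. Convergence: restricted log-likelihood
  change below 1e-10 and step below 1e-10 times var(y). With a single
  component this path agrees with the eigen-profile path to machine
  precision, which the suite asserts.
* `K^-1`: a column-centered GRM is always singular (the ones vector is in
  its null space), so BLUP adds a ridge of `1e-6 * trace(K)/n` before the
  dense solve. The value keeps the condition number near 1e6 - small
  enough that independent dense routes agree to ~1e-9 relative - while
  perturbing scores by a negligible ~1e-6 relative.
* Standard errors of variance components come from the numerical observed
  information; they are NaN at the boundary, where the Hessian is singular.

## The risk model

Disease status is modeled by partially-penalized logistic regression: for
`x = (clinical covariates, screened SNP dosages)` the coefficients minimize

    (1/n) sum_i [ -y_i x_i' beta + log(1 + exp(x_i' beta)) ]
        + sum_{l in SNPs} lambda [ alpha |beta_l| + (1-alpha)/2 beta_l^2 ]

with the clinical block and intercept unpenalized. `alpha` = 1 is the
lasso, 0 the ridge, and 0.5 the elastic-net default (the mixing is
configurable; 0.5 is the conventional midpoint when no value is dictated).
Optimization is an outer quadratic (IRLS) approximation with cyclic
coordinate descent inside (soft-thresholding penalized coordinates), SNP
columns standardized internally and coefficients returned on the original
scale. Because the quadratic model can overshoot the true objective, each
outer step is step-halved until the exact penalized objective is
non-increasing; the suite asserts monotonicity per sweep. Convergence is a
maximum coefficient change below 1e-7. IRLS weights are floored at 1e-5 to
keep working responses finite under separation.

The lambda grid is 50 log-spaced values from a data-driven `lambda_max`
(the smallest lambda whose KKT conditions zero every SNP coefficient at the
covariate-only fit, nudged up by 0.1% to clear the exact boundary) down to
`1e-3 * lambda_max`. Ridge has no finite zeroing lambda; its grid reuses
the conventional `alpha = 1e-3` surrogate in the `lambda_max` formula.

### Model selection and validation

Five stratified outer CV folds; within each outer-training set the full
screening stack (GRM, REML, BLUP or p-values) is recomputed from scratch,
then a 10-fold stratified inner CV scores every (p, penalty family, lambda)
grid point by mean validation AUC (warm-started lambda paths per fold).
Ties break toward smaller `p`, then larger lambda - the sparser model. The
selected model is refit on the whole outer-training set and scored once on
the held-out fold. Inner-CV AUCs are averaged over folds (not pooled), and
fold assignment is stratified by case status with seeded shuffling - an
unstratified 10-fold split fails routinely when the case fraction is low
(cohort-style populations run near 9-10%). The screening ranking is
computed once per outer-training set and shared by the inner folds, which
tune only the triplet; held-out samples never enter screening or tuning,
and the suite includes a null-cohort detector plus a permutation check for
this contract. If REML lands on the `sigma_g^2 = 0` boundary under the
BLUP criterion, the fold falls back to p-value screening with a notice.

AUC is the Mann-Whitney statistic (ties credited 0.5), computed from rank
sums and verified against explicit pair counting.

External validation applies a serialized model to an independent cohort,
matching variants by id and allele pair, flipping dosages (`2 - g`) when
the pair is swapped, and dropping unresolvable or absent variants; dropped
terms contribute zero to the linear predictor under either missing-variant
policy, and counts are logged. Prediction-model covariates default to age,
sex and pack-years; family history is excluded by default because
self-reported family history behaves inconsistently across populations,
but the set is configurable.

## Deviance decomposition

For binary outcomes the deviance of predictions `mu` is the Bernoulli
cross-entropy `Delta = -sum[y log mu + (1-y) log(1-mu)]` (the saturated
terms vanish for 0/1 outcomes with 0 log 0 = 0; no factor of 2),
probabilities clipped to [1e-12, 1-1e-12]. Model fit is McFadden's
pseudo-R^2, `(1 - Delta_F/Delta_0) * 100`, and a variable group's
contribution is `(Delta_i - Delta_F)/Delta_0 * 100`, where `Delta_i` comes
from refitting without that group. Groups are each clinical covariate
singly plus the SNP block as one unit; removing the SNP block leaves the
covariate-only model. Default mode is out-of-fold: per CV training fold the
screening is recomputed, the full and reduced models are refit reusing the
tuned (p, penalty, lambda), and deviances are summed over held-out
predictions; `Delta_0` uses the training fold's prevalence. An in-sample
mode (single fit on all samples) is available behind a flag. Contributions
of correlated groups need not sum to the McFadden value, can come out
slightly negative (reported as computed, with a note), and an overfit model
can push `Delta_F` above `Delta_0`, yielding a negative McFadden - also
reported, not errored.

## Synthetic cohorts

Real multi-ethnic COPD panels are access-restricted, so all tests run on
simulated cohorts whose architecture is known exactly.

* Population structure: Balding-Nichols. Ancestral frequencies are uniform
  on [0.05, 0.5]; each population's frequency is a Beta draw with mean `p`
  and variance `Fst * p (1-p)`. `Fst = 0.15` in the cross-population
  experiments, the continental-scale magnitude. Genotypes are HWE binomial
  within population; no LD by default (an AR(1)-block option exists but is
  untested at acceptance level). The effect allele is the ancestral minor
  allele.
* Trait: standardized causal dosages times effect sizes, rescaled so the
  genetic variance is `h^2` against `1 - h^2` noise, plus covariate
  effects on standardized covariates (defaults: age -0.3, sex +0.15,
  height +0.3, pack-years -0.25, echoing lung-function epidemiology).
  REML on the trait with the covariates as fixed effects therefore targets
  `h^2` directly.
* Status: liability threshold - a sample is a case when its trait falls
  below the population's case-fraction quantile. The motivating study
  never printed its spirometric case definition; thresholding is a
  declared stand-in that reproduces the very different case ratios of
  case-control versus population-cohort designs (case fractions 0.35 vs
  0.10 in the acceptance run).
* Covariates: age ~ N(57, 9); sex ~ Bernoulli(0.5); height ~ N(175, 7) or
  N(162, 6) by sex; pack-years zero-inflated Gamma (40% never-smokers,
  Gamma(1.5, 20) otherwise - zero inflation matters for cohort-style
  populations with low smoking rates); family history ~ Bernoulli(0.15),
  inert by default.
* Causal sets: `round(overlap * n_causal)` SNPs shared across populations,
  the rest population-private and disjoint. Effect sizes are standard
  normal by default; the `equal` option gives every causal SNP the same
  magnitude (random sign), a planted-signal architecture used where
  screening detectability itself is under test.

What passing tests do and do not show: the simulations have no LD, no
admixture, no genotyping batch effects, and covariates independent of
genotype, so the pipeline's behavior under those real-data complications is
not certified - in particular, screening stability and cross-population
transfer will degrade differently when causal variants are tagged rather
than genotyped.

## Problem sizes in the validation suite

The exhaustive HWE sweep covers every genotype table up to 50 diploids.
REML recovery uses 20 replicate cohorts of n = 2,000 samples by m = 5,000
variants per heritability value in {0, 0.2, 0.4, 0.6}. The leakage
detector runs 10 null cohorts of 500 x 800. The cross-population
experiment uses two populations of 1,800 samples by 3,000 variants with 20
equal-magnitude private causal SNPs each (h^2 = 0.5, Fst = 0.15); these
sizes make the planted qualitative effects - matched-population advantage
of at least 0.05 AUC, within-population screening overlap at least five
times the random-lists expectation - detectable with comfortable margins
while the between-population overlap stays at the random level. The
reproduction script (`scripts/acceptance.py`) runs a softer, study-shaped
configuration: 2 x 1,200 samples, 3,000 variants, 50 normal-effect causal
SNPs at 20% cross-population overlap and h^2 = 0.4.

## Known limitations

* The BLUP screening score's absolute scale is convention-dependent (see
  above); only rankings are meaningful.
* Multi-component REML forms dense `n x n` inverses per iteration -
  comfortable to a few thousand samples, not biobank scale.
* Variant harmonization handles allele swaps only; strand-ambiguous A/T
  and C/G pairs are dropped, and multi-allelic sites, indels, and imputed
  (fractional) dosages are out of scope.
* The sex-consistency sample filter is skipped (and logged) unless
  X-chromosome genotypes are present; the simulator does not emit them.
* HWE filtering is applied to all samples jointly, not controls only.
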