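# Methods

## Model

`megafactor` fits a Bayesian sparse latent-factor whole-genome regression
for one focal trait observed together with many correlated secondary traits
(hyperspectral bands, gene-expression levels, ...).  The observation model
for an n x t trait matrix Y is

    Y = F Λ + X1 B1 (+ X2R B2R) + E_R
    F = X2F B2F + E_F

K latent factors F capture all correlation among traits; conditional on F
the trait residuals E_R are independent with per-trait variances σ²_Rj.
Factors are decomposed into marker-driven genetic values X2F B2F plus a
factor residual E_F.  Optionally X2R B2R adds trait-specific marker effects
(off by default, as in the large-t applications, for cost).

### Priors

* **Marker effects** (entries of B2F, and of B2R when present): BayesC
  spike-slab — a point mass at zero with exclusion probability π and a
  shared-variance normal slab otherwise.  Every π (one per factor, one per
  trait for B2R) gets a Beta(1, 1) prior and is sampled.  The slab variance
  gets a scaled-Inv-χ²(df = 4) prior whose scale is matched at
  initialization so the expected included markers carry half the target
  variance.
* **Loadings** λ_kj: spike-slab with slab variance σ²_Rj / τ_k, where
  τ_k = Π_{h≤k} δ_h, δ_1 = 1, δ_h ~ Gamma(a_δ=2, b_δ=1) is a multiplicative
  gamma shrinkage ladder: under the prior E[τ_k] = 2^(k-1), so later rows of
  Λ are shrunk progressively harder and the exact choice of K matters little
  as long as it exceeds the active rank (checked by `factor_tail_check`).
* **Residual variances** σ²_Rj: Inv-Gamma(1, 1).

### Identifiability

The factor scale is not identifiable against Λ, so the factor residual
variance is fixed at 1 for every factor whose loading row is free.  When a
loading row is fully pinned (see below) its scale *is* identifiable, and
that factor's residual variance is sampled with an Inv-Gamma(1, 1) prior
instead.  Factor label/sign switching is not resolved by rotation; all
reported quantities (α_f, genetic values, genetic variance, FΛ) are
rotation-invariant functionals.

### Fixed first factor

For prediction-style fits the first row of Λ is pinned to the unit vector
on the focal trait (`fixed_first_factor_spec`), so the first column of B2F
models marker effects acting directly and exclusively on the focal trait
while the remaining factors borrow strength from the secondary traits.

### Sampler

A systematic-scan Gibbs sampler with re-derived conjugate full
conditionals, in order: B1 (flat prior, normal conditional); Λ by
single-site spike-slab updates (fixed entries skipped); π_Λ from Beta
conditionals on row inclusion counts; δ (hence τ) from Gamma conditionals;
F rows jointly from their normal conditional; B2F marker-by-marker
spike-slab updates against the factor-score residuals; slab variances and
π_F; the optional B2R block; σ²_R from Inv-Gamma conditionals (loadings
contribute through their slab); and finally missing or masked Y entries
are drawn from their predictive normal — this last step is what lets the
observed secondary traits of held-out individuals inform their focal-trait
predictions in cross-validation.

The marker scans are compiled (numba), walk markers in the outer loop with
per-factor residuals held cache-resident, and maintain residuals
incrementally.  All randomness flows from one seed; identical inputs and
seed give bit-identical chains.  The per-iteration log joint is tracked and
must stay finite; a non-finite value aborts with the iteration index.

The single-coefficient spike-slab conditional: with sufficient statistics
x'x and x'r, posterior precision v = x'x/σ²_e + 1/σ²_b and mean
μ = x'r/(σ²_e v), the slab/spike marginal-likelihood ratio is
√(1/(σ²_b v))·exp(μ²v/2); the indicator is Bernoulli in these odds against
the prior π, and an included coefficient is drawn N(μ, 1/v).  A
zero-variance covariate makes the ratio exactly 1, so the indicator falls
back to prior odds and an excluded coefficient is exactly 0.

**MegaRRBLUP** is the same model with every marker exclusion probability
pinned to 0 (all markers included) — the ridge/RR-BLUP limit.  With the
focal factor pinned it is dual to GBLUP with a VanRaden kernel; the test
suite verifies prediction correlation > 0.99 against a matched-variance
ridge oracle on a 100 x 200 problem.

### Reported quantities

Per stored draw the sampler computes α_f = B2F λ_f (λ_f the focal column of
Λ), genetic values u = X2F α_f and the genetic variance of the focal trait
var(u) across individuals.  Posterior summaries are averages of per-draw
products, never products of posterior means.

## Initialization and defaults

F and Λ start from a truncated rank-K SVD of the column-standardized
observed Y (missing cells mean-filled for the decomposition only);
coefficients start at zero, variances at prior means, indicators drawn from
the prior π's.  Chain defaults are 10,000 iterations, 2,000 burn-in,
thinning 2.  The tests and the acceptance script use shorter chains
(typically 1,500–4,000 iterations) and reduced sample sizes chosen so each
check completes in minutes on one CPU while retaining the contrasts being
tested; the simulation *conditions* (heritabilities, effect sizes, trait
counts, split fractions) are never reduced.

## Single-trait baselines

`st_bayesc_fit` is the univariate BayesC regression (same spike-slab
kernel, sampled π, slab and residual variances).  `gwas_scan` is the
stage-1 single-marker scan: OLS with intercept and covariates, or an
MLM mode adding a VanRaden-GRM polygenic effect whose variance components
are estimated once on the null model by eigendecomposition REML, each
marker then tested by GLS.  A dedicated GWAS program is not shelled out to;
the scan's only role in the pipeline is a P-value ranking.  Missing
dosages are marker-mean imputed inside the scan to keep it vectorized.

## Two-stage pipeline

Stage 1 scans the focal trait on the partition of individuals *without*
secondary traits, drops markers with P > 0.01, and greedily clumps:
repeatedly take the most significant survivor and permanently mask all
markers within ±250 kb having r² > 0.5 with it (ties on P break by
position, then id, making the output order-invariant).  Stage 2 fits
ST-BayesC or the factor model (with the fixed first factor) on the other
partition restricted to the clumped candidates; unselected markers are
implicitly zero.  Post-processing computes each marker's explained
variance var(α_l x_l), flags significance (explained proportion strictly
> 0.1%, or P strictly < 1e-5 for scan results), and matches SNPs to gene
intervals within ±100 kb measured from the interval boundaries, inclusive
— the conservative reading of "within a distance of" a gene.

## Prediction and cross-validation

VanRaden GRM: K = ZZ'/(2Σ f_l(1−f_l)) with Z centered at 2f_l, monomorphic
markers excluded.  Secondary-trait kernel: H = SS'/c from centered,
standardized columns (c = number of columns).  GBLUP uses
eigendecomposition REML for one kernel and bounded quasi-Newton with three
restarts over the two variance ratios for two kernels.  Cross-validation
masks a random 50% of focal phenotypes, 20 repetitions; secondary traits of
masked individuals stay observed.  Because of that, raw predictive
correlation is biased, and accuracy is reported as
cor(û, y_test)/√ĥ² — the heritability-corrected genetic correlation.  The
literature source for this correction does not print a formula; the
√h²-denominator estimator is this package's stand-in and is exact when
prediction errors are independent of the phenotypic noise.  Method
comparisons across CV repeats use the adjusted t statistic
t = mean(d)/√((1/reps + n2/n1)·σ̂²), which inflates the denominator to
account for re-used validation data.

## Simulators

`sim_factor_scenario` reproduces the unstructured-population study:
genotypes i.i.d. uniform on {0,1,2} (n=3000, p=2000 by default), a 0/1
loading pattern in which trait 1 (focal) loads on every factor and each
factor additionally loads on its own block of dedicated secondary traits,
and per-factor QTL drawn without replacement within a factor but
independently across factors (a marker can hit several factors).  All QTL
within a factor share one effect magnitude — 0.1 by default, the value the
reference scatter comparisons use — with random signs; the factor residual
variance is set so QTL explain 95% of each genetic factor's variance, and
trait-specific noise contributes 10% of each trait's variance.  Scenario 1
makes every factor genetic; scenario 2 only the first, the others pure
noise of equal total variance.  Under this bookkeeping the focal trait's
genetic share is 0.95·0.9 ≈ 85.5% in scenario 1 and 85.5%/nfactor in
scenario 2, and the per-QTL explained shares average 85.5%/(nfactor·nqtl)
and 85.5%/(nfactor·nqtl) respectively — the quantities the acceptance
script recomputes empirically.  Per-QTL shares are accounted per
(factor, QTL) event with the through-factor effect; the truth object also
records each marker's combined focal effect α_l for scoring.

`sim_ld_genotypes` is an explicit stand-in for real structured genotypes:
2n haplotypes from a first-order Markov chain along one chromosome with
adjacent-allele correlation ρ (default 0.9, giving adjacent-dosage
r² ≈ ρ² ≈ 0.81) and allele frequencies drifting slowly inside `maf_range`
so the target correlation is achievable between neighbours.  It produces
block-wise LD with geometric decay but none of the long-range structure,
population stratification or variable recombination of real panels —
conclusions that depend on real LD (e.g. the full-scale ~10x RMSE gap
between 1-stage and 2-stage analyses on a whole genome) are out of
desk-scale reach and are only reproduced qualitatively.

`sim_arabidopsis_like` builds the structured-population study on such
genotypes: LD pruning (r² 0.8, 500-marker windows, 100-marker steps), 20
QTL drawn from the pruned markers, 10 factors with 2 QTL each, first
loading column 0.5, 20 dedicated secondary traits per factor (201 traits),
QTL magnitudes U(3, 5) with a random half negated, focal h² scaled to 0.6,
secondary h² 0.8, and a 649:354-proportioned partition into
secondary-trait and focal-only subsets.  QTL are restricted to markers
with MAF ≥ 0.2 so each QTL's explained share of focal variance stays in
the few-percent band the study design calls for.

`score_estimates` applies the truth-aware parsing rules: a QTL present in
the candidate set is compared directly; a missed QTL with a selected proxy
at r² > 0.4 is flagged and the proxy's estimate stands in (signed effects
can flip phase in negative LD, which is why the explained-standard-
deviation RMSE is also reported — it is phase-invariant); a QTL with
neither is scored as estimate 0; candidate non-QTL markers are scored
against 0.

## Diagnostics

`split_rhat` implements rank-normalized split R-hat (bulk and folded, the
larger reported); it matches the arviz reference implementation to 1e-6 on
fixed draw tables and returns 1.0 for constant chains by convention.  The
recommended functional is the per-draw genetic variance of the focal trait
across ≥ 3 chains.  `factor_tail_check` passes when the posterior-mean
absolute loadings of the last rows of Λ all fall below a tolerance
(default: 5% of the largest absolute loading — the reference procedure
only asks for "small" values, so the threshold is a package choice) and
otherwise recommends re-running with a larger K.  `top_loading_traces`
extracts plot-ready draw sequences for the largest loadings per factor.

## Numerical notes and edge cases

* Monomorphic markers: spike-slab indicator falls back to prior odds; the
  scan reports estimate 0, P = 1; the GRM drops them with a warning.
* Boundary conventions are exact: MAF ≤ 0.05 removed, missing rate ≥ 0.1
  removed (computed directly, not via 1 − call rate, to keep the boundary
  exact in floating point), call rate ≤ 0.5 removed, explained proportion
  strictly > 0.1% significant, gene windows inclusive.
* REML ratio optimizations are bounded in log-space ([-12, 12]) with an
  explicit zero-variance boundary check.
* Kernel matrices are symmetrized and validated to 1e-10.
* All generators and samplers take integer seeds; spawned seeds stay below
  2^31.

## Limitations

* The full conditionals and hyperparameter defaults were derived from the
  model statement above; no claim is made that they coincide with any
  other implementation's internal choices.
* The Markov-haplotype generator does not emulate real LD structure (see
  above).
* The corrected-accuracy estimator is the √h² correction, not a
  regression-based genetic correlation.
* Two-kernel REML optimizes a 2-parameter restricted likelihood directly
  and can be slow for n in the thousands.
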