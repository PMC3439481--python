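# Methods

This note documents the statistical models, the numerical choices, and the
synthetic-data generator behind `bivarped`, and states what the test suite
does and does not establish.

## 1. Familial correlations and co-heritability

For a quantitative trait with additive polygenic variance σ²_g and residual
variance σ²_e, full siblings share additive genetic covariance σ²_g · 2Φ
with kinship Φ = 1/4, so the sib intraclass correlation of a standardized
trait estimates h²/2 and narrow-sense heritability is estimated as
**h² = 2r** (clamped to [0, 1] with a flag when the raw value escapes the
parameter space).

The cross-trait analogue replaces the variance by the genetic covariance
σ_g,12: the **cross-trait sibling correlation** averages corr(A₁, B₂) and
corr(A₂, B₁) over sib pairs. We compute it as one Pearson correlation over
the pooled set of both ordered observations per unordered pair, which is
algebraically the same average and makes the estimator exactly symmetric
in the two traits. Its expectation for standardized traits is 0.5·σ_g,12,
the tabulated co-heritability readout ρ; the doubled value (the analogue of
h² = 2r) is reported alongside, labelled `genetic_covariance`.

Two pair weightings are provided: `pair_equal` (default; every sib pair
weight 1) and `sibship_equal` (each sibship's pairs share total weight 1,
damping large sibships). Dichotomous traits are treated as 0/1 numeric
columns.

**Standard errors** come from a pedigree-level bootstrap (families
resampled with replacement, B ≥ 200, seeded): pedigrees are the independent
sampling units, so this targets the correct sampling distribution without
distributional assumptions. Under independent sib pairs the pooled
estimator's null SE is (1 − r²)/√(2n) — the two ordered observations per
pair are uncorrelated under the null — and the bootstrap reproduces this
closed form in tests. A two-sided p-value uses the normal approximation
r/SE.

## 2. Phenotype preparation

* Cortical-opacity grade: `min(wedges, 4)` on a 0–8 wedge count (grades
  0–4; everything at or above 4 opaque one-eighth wedges is grade 4).
* Worse eye: elementwise max (or min when lower values are worse) over
  non-missing eyes.
* Annual change: (follow-up − baseline)/years, years > 0.
* Residualization: least-squares residuals on intercept + age + sex
  (female = 1); missing inputs yield missing residuals; ≥ 10 complete
  cases and a full-rank design are required.
* **Inverse normal transform (INT)**: value i ↦ Φ⁻¹((rank_i − 1/3)/(n + 1/3)),
  ties given average ranks, missing preserved. The 1/3 offsets make the
  transformed sample symmetric and approximately standard normal for any
  continuous input; for n = 3 the quantiles are exactly (0.2, 0.5, 0.8).
  Applying INT to heavily tied ordinal columns (such as the 0–4 grade)
  leaves plateaus of equal values; a log warning is emitted when more than
  half the values are tied. The pipeline residualizes first and transforms
  the residuals, so results are invariant to affine changes of trait units.

## 3. Genotype quality control

Filters run in a fixed order and are itemized in a `QcReport`: marker call
rate ≥ 0.98 → founder MAF ≥ 0.02 → (imputed markers) RSQ ≥ 0.8 → subject
call rate ≥ 0.98 computed among the remaining markers. MAF and the exact
Hardy–Weinberg test use founders only, avoiding pseudo-replication from
relatives. The HWE test is the exact conditional test (sum of conditional
probabilities of heterozygote counts no likelier than the observed one,
computed with log-gamma arithmetic; an asymptotic χ² variant is available).
Exact-test p-values are discrete and conservative by construction; their
randomized version is exactly uniform under the null, which is how
calibration is asserted in tests.

**LD pruning** slides windows of 1500 markers by steps of 150 within each
chromosome and greedily removes one member of the worst pair while any
within-window pair has r² > 0.8. r² is the squared Pearson correlation of
genotype/dosage values (composite LD) — phase is never used downstream, so
no EM haplotype estimation is attempted; this is a documented dialect
difference from haplotype-based pruners. The removed member of a pair is
the one with the lower MAF (tie: larger position), making the result
deterministic.

**Mendelian masking** checks every (child, available parents) trio at each
hard-call marker against the 27-configuration transmission table (duo rules
when one parent is genotyped) and sets the genotypes of the child *and*
the available parents to missing at offending markers — conservative,
since the erroneous member cannot be identified. The operation is
idempotent; dosage markers are skipped with a warning.

## 4. The bivariate two-level Haseman–Elston model

For traits t = 1..T (T ∈ {1, 2}) of individual i in pedigree k:

    y_t,ik = x_ik' β_t + g_t,ik + e_t,ik

with fixed effects x (SNP dosage, covariates, intercept), polygenic effects
g with Cov(g_s,i, g_t,j) = Σ_g[s,t] · (2Φ)_ij and residuals e with
Cov = Σ_e[s,t] · δ_ij. The stacked per-pedigree covariance is
**Ω_k = Σ_g ⊗ 2Φ_k + Σ_e ⊗ I** — the standard variance-components
realization of "polygenic plus random" effects.

Estimation alternates until convergence:

1. *Level 1:* GLS of the trait-major stacked outcome on block-diagonal
   fixed effects given current Ω_k; coefficient covariance (X'Ω⁻¹X)⁻¹
   (model-based; a sandwich estimator is available via `robust_se`).
2. *Level 2:* OLS of all elementwise residual products r_s,i·r_t,j within
   pedigrees on the two predictors (2Φ)_ij and δ_ij, per trait pair —
   the classic HE second level, unweighted (the simplest member of the
   tHE family). Both orderings of each cross-trait pair enter, so the
   update is symmetric.

Numerical choices (none forced by the model): initialization Σ_e = sample
trait covariance, Σ_g = 0.5·Σ_e; convergence when the largest
variance-parameter change is < 1e-6; max 50 iterations with an explicit
`converged` flag (never silent); Σ_g and Σ_e are eigen-floored at
`vc_floor` (default 0) each iteration; Ω gets a 1e-8 jitter retry before a
`NumericalError`. When the two level-2 predictors are collinear — an
unrelated-only sample, where 2Φ = I — the polygenic component is
unidentifiable and is attributed to the residual (Σ_g = 0); level 1 then
collapses to per-trait OLS exactly (identical regressors across traits),
which the tests verify to 1e-6. Degenerate design columns (e.g. an
interaction term with no joint carriers) receive the minimum-norm solution:
coefficient 0 with zero variance, Wald p = 1.

SNP inference uses **first-level Wald tests**: β̂' V⁻¹ β̂ with the estimated
coefficient covariance, χ² with 1 df per trait (2 df for the joint
bivariate test). Missing traits/covariates/dosages are handled complete
case per model.

* `interaction_model` fits snp1 + snp2 + snp1·snp2 per trait and jointly,
  warning (not failing) when the SNP pair has r² ≥ 0.5.
* `variance_explained` uses the standardized single-SNP formula
  2·maf·(1−maf)·β₁·β₂ / σ_g,12 — appropriate because the traits are
  standardized quantitative residuals; no liability-scale machinery.
* `genome_scan` offers `exact` mode (full refit per marker) and `fast`
  mode (variance components estimated once under the no-SNP model, Ω
  frozen, per-marker GLS fully vectorized; missing dosages mean-imputed).
  The two agree within 0.2 on −log₁₀ p for null markers in tests.
* `genomic_lambda` = median(implied χ²_df) / median(χ²_df distribution)
  (0.4549 at 1 df, 1.3863 at 2 df).

## 5. The synthetic-data generator

`simulate` produces the world the analysis assumes — and is therefore a
*positive control*, not evidence about real cohorts:

* **Pedigrees**: repeated units of one structure — `("nuclear", s)` (= a
  sibship of s with both parents), or `three_generation`: 16 members (2
  grandparents, 4 adult children with 4 founder spouses, 6 grandchildren),
  giving parent–offspring, sib, avuncular, grandparental and first-cousin
  pairs.
* **Genotypes** by gene dropping: founder haplotypes drawn at configured
  MAFs; `ld_rho` > 0 makes adjacent alleles a first-order Markov chain
  with correlation ρ (marginals preserved; clamped at the Fréchet bound
  for discordant MAFs) and children then inherit whole parental
  haplotypes (a fully linked block); with ld_rho = 0 each marker
  segregates independently. Missingness and then Mendelian errors
  (genotype replaced by a different value) are injected last; each error
  is labelled detectable/undetectable by the trio-enumeration rule, so
  masking sensitivity is testable exactly.
* **Traits**: covariate effects (age slope 0.02/yr, sex shift 0.3 —
  arbitrary but realistic magnitudes) + Σ causal β·dosage + per-pedigree
  polygenic draw L_A Z L_g' with L_A the Cholesky factor of 2Φ (+1e-8
  jitter) + iid residual with covariance Σ_e. Default variance structure:
  per-trait h² = 0.6, genetic covariance σ_g,12 = 0.478 (expected sib
  cross-trait correlation 0.239) and residual covariance −0.16 (expected
  within-person cross-trait correlation 0.318) — chosen once to mirror a
  published lens/brain trait pair and not revisited. An ordinal 0–4
  column mimicking a cortical wedge grade is cut from trait 1 at
  thresholds giving grade frequencies (0.60, 0.20, 0.10, 0.06, 0.04).
* Not emulated: realistic MRI volume distributions, assortative mating,
  genotyping batch effects, recombination maps, selection/ascertainment.
  A green simulation test therefore establishes internal consistency of
  the estimators with their assumed model, not robustness to these
  violations.

Named fixtures (`null_scan`, `power_scan`, `coherit_recovery`,
`qc_gauntlet`) write pedigree/PED/MAP/phenotype files plus a JSON manifest
of the generating truth, with fixed seeds (byte-identical regeneration).

## 6. Known limitations

* REML/ML mixed models are deliberately not the primary estimator; the HE
  two-level estimator is less efficient but matches the target design.
* The exact HWE filter and MAF are founder-based; cohorts without genotyped
  founders fall back to all subjects.
* Fast-mode scans share one Ω across markers; per-marker missingness is
  mean-imputed there (exact mode is complete-case).
* X-linked kinship, relationship inference from markers, and population
  structure correction are out of scope; precomputed principal components
  can be passed as covariates.
* Simulation-calibration tests (type-I error within the binomial 95%
  acceptance band at α ∈ {0.05, 0.001} over 2000 replicates; power and
  λ checks) are seeded and scaled to run on one CPU in minutes; they bound
  the behavior at those sample sizes, not asymptotically.
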