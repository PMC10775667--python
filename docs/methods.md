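# Methods

## The trial model

All analyses start from the linear mixed model of a provenance–progeny
common garden analyzed one site and one trait at a time:

    y = X b + Z_p u_p + Z_f u_f + Z_r u_r + Z_c u_c + e

with fixed block effects `b` and independent Gaussian random effects:
population `u_p ~ N(0, σ²_p I)`, mother-tree family nested in population
`u_f ~ N(0, σ²_f I)`, field row `u_r` (rows run across blocks), column
within block `u_c`, and residual `e ~ N(0, σ²_e I)`. Population is random
so that inferences refer to the species and the among-population variance
is estimated rather than absorbed. Families are open-pollinated and
treated as half-sib, so the additive genetic variance is `σ²_a = 4σ²_f`.
Missing responses are dropped per fit; there is no imputation.

Bivariate fits add unstructured 2×2 covariance blocks for the family and
residual terms (and the population term when included). Row and column
terms keep per-trait variances without cross-trait covariance: the field
gradients are nuisance structure and their cross-trait covariance is both
weakly identified and irrelevant to every downstream quantity, which only
uses family (and population) covariances.

## REML estimation

Univariate fits maximize the restricted likelihood with EM iterations
accelerated by average-information (AI) steps: at each iteration the AI
update is tried first and accepted only if it stays in the parameter space
and does not decrease the restricted log-likelihood; otherwise the
monotone EM update is used. Starting values split the phenotypic variance
equally across the declared components. Convergence is a relative
log-likelihood change below 1e-8 (at most 200 iterations). All likelihood
algebra uses the Woodbury identity on the random-effect incidence
matrices, so cost scales with the number of random-effect levels (a few
hundred) rather than trees.

Variance components are constrained non-negative. A component whose EM
path decays toward zero approaches the boundary only geometrically, so
when the likelihood plateaus, each small component is profiled at exactly
zero and fixed there if the restricted likelihood does not drop ("fix at
zero and re-estimate the rest"); such components are flagged as boundary
estimates. When the truth is on the boundary, the REML estimator lands
exactly at zero in roughly half to two-thirds of replicates (the
½χ²₀ + ½χ²₁ boundary mixture), with the remainder small and positive —
the test suite asserts that behaviour rather than a near-certain zero.

The asymptotic covariance of the estimates is the inverse AI matrix at
convergence (boundary components excluded). Single-level random factors
(e.g. a one-population table) are confounded with the intercept and are
dropped from the design; their predictions are zero.

Bivariate fits maximize the restricted likelihood directly (L-BFGS-B)
over Cholesky factors of the 2×2 blocks, which keeps every iterate
positive semi-definite without projections. Both responses are rescaled
to unit variance internally so all parameters are O(1) for the optimizer,
and components are scaled back afterwards. Starting values seed every
covariance block with the empirical correlation of the two responses
(a zero-covariance start stalls when traits are strongly correlated).
Exactly collinear responses make the joint model singular and are handled
analytically from the univariate fit. The component covariance matrix is
obtained by finite-differencing the observed information in the Cholesky
chart — feasible by construction even when a block sits at the PSD
boundary — and pushing it to the component scale through the Jacobian of
the quadratic Cholesky-to-covariance map.

## Genetic parameters

Per trait and site, from the univariate components:

* `h² = 4σ²_f / (σ²_f + σ²_e)`. The denominator deliberately excludes the
  population, row and column variances: it is the within-population
  phenotypic variance on the micro-environmental scale of a single tree.
  `h²` can therefore exceed 1 in principle (it is 4× an intraclass
  correlation).
* `CVa = 100·√(σ²_a)/|x̄|`, the additive genetic coefficient of variation
  in percent. (The raw ratio `σ²_a/x̄` is available behind
  `evolvability(..., literal=True)` for comparability, but it is not a
  coefficient of variation — it has the trait's units — and the standard
  mean-scaled evolvability is the default.)
* `QST = σ²_p / (σ²_p + 8σ²_f)` for half-sib designs.

Standard errors of `h²` and `QST` are first-order delta-method
propagations of the component covariance.

Global FST over the populations uses the Weir–Cockerham (1984)
variance-component estimator on biallelic dosages: per-locus
among-population (a), among-individual (b) and within-individual (c)
components, global estimate `Σa / Σ(a+b+c)` over polymorphic loci, and a
percentile 95% CI from 1000 bootstrap resamples of loci (the locus is the
unit of replication for neutral drift). The QST–FST contrast is
operationalized as interval overlap: QST ± 1.96 SE against the FST
bootstrap CI, giving a verdict of lower / higher / not-different.

## Breeding values and standardization

Mother-tree breeding values are the empirical BLUPs of the family term
(`within-population` level, selection acting inside populations) and of
the population + family terms (`total` level, selection acting across the
species). They are family-level predictions: the downstream integration
and selection analyses operate on mother trees, not individual offspring.
No ×2 parental rescaling is applied — every downstream statistic is
computed after standardization and is invariant to a scalar factor.

Standardization centers each trait's breeding values to mean 0 and scales
to sample SD 1 (n−1 denominator, fixed by a test) within site and level;
the fitness trait is excluded from standardization.

## Phenotypic integration

For `N` traits over `n` family records, the integration index is the
variance of the eigenvalues of the trait correlation matrix, computed
with divisor `N` (population variance) so that the single-axis limit
attains the maximum `N−1` exactly. Sampling noise alone yields an
expected eigenvalue variance of `(N−1)/n`, so the corrected index
subtracts it; the relative index is `100·uncorrected/(N−1)` percent. `n`
is the number of family records entering the correlation matrix — with
the two sites' 119 and 49 families this arithmetic reproduces the
published relative indices to two decimals, which fixes the convention.

Significance is assessed by randomization: each trait column is permuted
independently across families (destroying correlations, preserving
margins), with `p = (1 + #{null ≥ observed})/(n_perm + 1)`. The 99% CI is
a family-bootstrap percentile interval of the corrected index — the
published tables print 99% CIs without stating their construction, and a
bootstrap is the natural uncertainty companion to the permutation null.
The between-site contrast (also unspecified in the source analyses) is a
label-permutation test on the absolute difference of corrected indices
over the pooled family records; both choices are conventions of this
package and are flagged as such.

## Selection analysis

Relative fitness divides each family's predicted height by the site mean.
Two estimators of selection on each trait:

* **Genetic gradient** `β_G = cov_f(w, z)/σ²_f(z)` from the family
  components of the bivariate fit of fitness with the trait, with a
  delta-method SE. The raw component ratio is the defining formula; for
  reporting next to the phenotypic gradients the pipeline rescales it to
  relative fitness and a standardized trait (`cov_f/(σ_f·mean fitness)`),
  so both kinds of gradient share a scale. β_G is linear-only.
* **Phenotypic gradients** from the log-linear model
  `ln(λ_k) = Σᵢ(βᵢ z_ik + γᵢ z²_ik)`, fitted jointly over the five traits
  (partial regression) on standardized breeding values at each level. The
  error model is Gaussian on `ln(λ)` (maximum likelihood), which supplies
  a proper likelihood for the stated tests; a Gamma GLM with log link is
  available as an alternative error model. Quadratic coefficients are
  reported exactly as the `z²` coefficients (no ½ rescaling). Each
  coefficient's p-value is a likelihood-ratio test dropping that term,
  with χ²(1) reference. An intercept is included although the defining
  model omits it: the relative-fitness normalization drives it toward
  zero, while omitting it would force the quadratic terms to absorb the
  `E[z²] = 1` offset.

The unit of analysis is the family at both levels (predictors are
explicitly breeding values of mother trees); an individual-tree analysis
is a documented alternative, not implemented.

Note on attenuation: gradients estimated from *estimated* (shrunken,
noisy) breeding values are biased toward zero relative to the generating
coefficients — ordinary errors-in-variables — so the recovery tests
construct fitness from the generator's true standardized family effects,
where the log-linear estimator is exact in expectation.

## The synthetic generator

`synthetic_data` draws every effect from the same linear-Gaussian model
the analysis assumes: Gaussian population, family, row, column and
residual effects with configured variances; family effects jointly across
traits with covariance `D^{1/2}·R·D^{1/2}` (R the genetic correlation
matrix); trees laid out on a four-block row–column grid (blocks are
column strips; each family is split evenly over blocks, echoing the
plot-replicated design). The fitness trait's family effect is multiplied
by `exp(Σᵢ βᵢzᵢ + γᵢzᵢ²)` of the standardized true family effects, making
`ln(relative fitness)` exactly linear in `(z, z²)` so the generating
gradients are recoverable without transformation bias. SNP panels drift
population allele frequencies from a uniform(0.05, 0.95) ancestral
distribution through the Balding–Nichols beta model with
`E[FST] = fst_target`; genotypes are binomial(2, p). Missingness is
completely at random per trait at a configurable rate (default 0; the
realized missingness pattern of the real trial is unpublished).

Default configuration (the study conditions): 11 populations × 11
families × 8 trees (968 trees; the real high-productivity site had 119
families, 947 trees) and 11 × 4 × 8 = 352 for the low-productivity site
(real: 49 families, 375 trees) — the closest balanced nesting to the
study scale; trait means at field-realistic values (height 200 cm /
120 cm by site, δ¹³C −28‰, SLA 5 mm²·mg⁻¹, needle dry weight 40 mg, PGI
0.40); variances set for h² = 0.25, CVa ≈ 10% (δ¹³C plasticity 25%, mean
δ¹³C 2.5%), QST = 0.10; row/column variances 5% of the residual; genetic
correlations and selection coefficients mirroring the observed pattern
(height–needle mass +0.5, height–phenology −0.4; β_DW = 0.232,
γ_DW = −0.032, etc.). One consequence worth knowing: the fitness trait's
family variance is dominated by the injected selection signal (the
gradient magnitudes imply a family-level fitness SD near 28% of the site
mean), so the heritability of height in the default configuration is far
above the 0.25 its base components alone would give — coherent with the
generating model, not a bug. Two sites are independent draws — the generator
does not model across-site genetic covariance (the real trial shares 44
families between sites), nor spatial autocorrelation beyond row/column
effects, pedigree beyond half-sib, or climate covariates. Passing tests
therefore demonstrate correctness of the estimators under the assumed
model, not robustness to field realities such as spatially correlated
microsites or non-Gaussian residuals.

## Numerical conventions and problem sizes

* Convergence: relative |Δloglik| < 1e-8, ≤ 200 EM/AI iterations;
  bivariate optimizer ftol 1e-12, ≤ 500 iterations.
* Boundary detection: plateau profiling at zero with relative tolerance
  1e-8; collapse floor 1e-7 of the phenotypic variance.
* Hessian steps for the component covariance: 1e-3 relative (large
  enough that likelihood differences clear evaluation noise).
* Randomization defaults: 999 permutations, 999 bootstrap resamples
  (99% CI), 1000 FST locus bootstraps; all driven by explicit seeds.
* Recovery suites run 50 replicates at the study scale (11 × 11 × 8) for
  h²/QST, 50 bivariate replicates for the family correlation and β_G,
  200 replicates for the LRT type-I calibration, and 20 panels of 5000
  loci for FST — sizes chosen to hold mean-recovery bands with
  comfortable Monte Carlo margins.
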