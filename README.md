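# pinequant

Quantitative genetics of provenance–progeny common-garden trials, built
around the design of a two-site maritime pine (*Pinus pinaster*) experiment:
11 populations, 119 open-pollinated (half-sib) mother-tree families, ~8
trees per family, planted on a row–column design with four blocks at a
high- and a low-productivity site, with tree height as a fitness proxy and
five functional traits (mean and plasticity of carbon isotope
discrimination, specific leaf area, needle dry weight, phenology growth
index).

It is written for forest geneticists and evolutionary ecologists who want
the full chain from raw trial tables to evolutionary parameters as a
single, tested pipeline:

* **REML variance components** for the trial mixed model
  `y = Xb + Z₁p + Z₂f + Z₃r + Z₄c + ε` (fixed blocks; random population,
  family-within-population, row, column-within-block), univariate and
  bivariate (unstructured family/residual covariance), via EM iterations
  with average-information acceleration.
* **Genetic parameters** per trait and site: heritability
  `h² = 4σ²f / (σ²f + σ²e)`, evolvability `CVa = 100·√(4σ²f)/|x̄|` (%),
  and differentiation `QST = σ²p / (σ²p + 8σ²f)`, each with delta-method
  standard errors; global **FST** from SNPs (Weir–Cockerham estimator,
  bootstrap across loci) and a QST–FST interval-overlap verdict.
* **Breeding values** of the mother trees at two levels: within-population
  (family BLUP) and total (population + family BLUPs).
* **Phenotypic integration**: eigenvalue variance of the breeding-value
  correlation matrix, corrected by the random-covariation expectation
  `(N−1)/n` and expressed relative to the maximum `N−1`, with a
  permutation significance test and a family-bootstrap 99% CI.
* **Selection gradients**: genetic gradients `β_G = cov_f(w, z)/σ²f(z)`
  from bivariate fits, and linear/quadratic phenotypic gradients from the
  log-linear fitness model `ln(λ) = Σ(βᵢzᵢ + γᵢzᵢ²)` with per-coefficient
  likelihood-ratio tests.
* **Synthetic-data generator** reproducing the full design (including SNPs
  drifted to a target FST with the Balding–Nichols model and a fitness
  trait carrying known selection gradients), so every stage is testable
  without any data download.

## Worked example

Simulate one site at the study's scale and estimate the genetic parameters
of needle dry weight (generated with h² = 0.25, CVa = 10%, QST = 0.10):

```python
from pinequant import (default_config, simulate_trial, ModelSpec, fit_reml,
                       heritability, evolvability, qst)

cfg = default_config("HiProd", seed=42)   # 11 populations x 11 families x 8 trees
obs = simulate_trial(cfg)

fit = fit_reml(obs, ModelSpec(response="DW"))
h2, h2_se = heritability(fit)
q, q_se = qst(fit)
print(f"sigma2_p={fit.sigma2_p:.2f}  sigma2_f={fit.sigma2_f:.2f}  "
      f"sigma2_e={fit.sigma2_e:.2f}  (loglik {fit.loglik:.1f})")
print(f"h2  = {h2:.3f} +/- {h2_se:.3f}")
print(f"CVa = {evolvability(fit, obs['DW'].mean()):.1f}%")
print(f"QST = {q:.3f} +/- {q_se:.3f}")
```

prints

```
sigma2_p=3.20  sigma2_f=3.18  sigma2_e=58.08  (loglik -3389.8)
h2  = 0.208 +/- 0.095
CVa = 8.6%
QST = 0.112 +/- 0.077
```

The REML components split the phenotypic variance among populations,
families and residual; with 121 families the heritability estimate (0.21 ±
0.10) and the differentiation estimate (0.11 ± 0.08) recover the generating
values (0.25 and 0.10) within one standard error — the sampling noise shown
is what a trial of this size genuinely delivers.

The full pipeline — both sites, all six traits, FST, integration and
selection — runs from a single config:

```bash
pinequant run --config examples/config.yaml --out results/ --seed 1
```

writing per-site CSV tables (`genetic_parameters_*.csv`,
`breeding_values_*.csv`, `selection_gradients_*.csv`), integration and FST
JSON reports, and a run manifest; re-running with the same config and seed
is bit-identical.

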