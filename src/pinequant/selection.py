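"""Selection gradients on mother-tree breeding values.

Two complementary estimators of the strength of selection on each trait,
with height (a fitness proxy) supplying relative fitness lambda = height /
mean(height) within each site:

* the *genetic* selection gradient, beta_G = cov_f(fitness, trait) /
  var_f(trait), from the family covariance components of a bivariate REML
  fit of fitness with the trait;
* *phenotypic* selection gradients from the log-linear fitness model

      ln(lambda_k) = sum_i ( beta_i z_ik + gamma_i z_ik^2 )

  fitted jointly over the five traits (partial regression), where z are
  standardized breeding values at the within-population or total level.
  The default error model is Gaussian on ln(lambda) (maximum likelihood),
  which gives proper likelihood-ratio tests: each coefficient's p-value
  comes from refitting without that term, 2*(ll_full - ll_reduced) ~
  chi-square(1).  A Gamma GLM with log link is available as an alternative
  error model.

An intercept is included in the fitted model: relative-fitness
normalization drives it toward zero, but omitting it would force the
quadratic terms to absorb the E[z^2] = 1 offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_model import VarianceComponents

__all__ = [
    "relative_fitness",
    "genetic_gradient",
    "phenotypic_gradients",
    "GradientFit",
]


def relative_fitness(values: pd.Series | np.ndarray) -> pd.Series:
    """Relative fitness: each value divided by the within-site mean."""
    v = pd.Series(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two records")
    if (v <= 0).any():
        raise ValueError("fitness values must be positive")
    return v / v.mean()


def genetic_gradient(biv_fit: VarianceComponents,
                     fitness_trait: str, trait: str,
                     fitness_mean: float | None = None) -> tuple[float, float]:
    """Genetic selection gradient beta_G = cov_f(w, z) / var_f(z) with SE.

    ``biv_fit`` is a bivariate fit of (fitness_trait, trait).  By default
    the gradient is the raw component ratio.  Passing ``fitness_mean``
    instead returns the gradient of *relative* fitness on the
    *standardized* trait, cov_f / (sd_f(trait) * fitness_mean) — the scale
    on which phenotypic gradients are reported, so the two are comparable.
    The SE comes from the delta method on the asymptotic covariance of the
    family covariance and the trait's family variance.
    """
    cov_name = "family.cov"
    var_name = f"family.{trait}"
    c = biv_fit[cov_name]
    v = biv_fit[var_name]
    if v <= 0:
        raise ValueError(f"family variance of {trait} is not positive")
    if fitness_mean is not None:
        m = abs(fitness_mean)
        beta = c / (np.sqrt(v) * m)
        g = np.array([1.0 / (np.sqrt(v) * m), -0.5 * c / (v ** 1.5 * m)])
    else:
        beta = c / v
        g = np.array([1.0 / v, -c / v ** 2])
    S = np.array([
        [biv_fit.cov_of(cov_name, cov_name), biv_fit.cov_of(cov_name, var_name)],
        [biv_fit.cov_of(cov_name, var_name), biv_fit.cov_of(var_name, var_name)],
    ])
    var_beta = float(g @ S @ g)
    se = float(np.sqrt(var_beta)) if var_beta >= 0 else float("nan")
    return float(beta), se


@dataclass
class GradientFit:
    """Joint log-linear fit: one row per coefficient in ``table``.

    ``table`` columns: trait, term (linear/quadratic), estimate, se, lrt_p.
    """

    table: pd.DataFrame
    loglik: float
    n_obs: int
    intercept: float
    condition_number: float

    def coef(self, trait: str, term: str) -> float:
        m = self.table[(self.table.trait == trait) & (self.table.term == term)]
        return float(m["estimate"].iloc[0])

    def p(self, trait: str, term: str) -> float:
        m = self.table[(self.table.trait == trait) & (self.table.term == term)]
        return float(m["lrt_p"].iloc[0])


def _gaussian_ll(resid: np.ndarray) -> float:
    n = resid.size
    rss = float(resid @ resid)
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def phenotypic_gradients(z: pd.DataFrame, fitness: pd.Series,
                         traits: list[str] | None = None,
                         error_model: str = "lognormal") -> GradientFit:
    """Linear and quadratic selection gradients, all traits fitted jointly.

    ``z`` holds standardized breeding values (one column per trait, one row
    per family); ``fitness`` is aligned relative fitness (positive, mean 1).
    ``error_model``: "lognormal" (Gaussian ML on ln lambda, default) or
    "gamma" (Gamma GLM, log link, via statsmodels).
    """
    traits = traits or list(z.columns)
    zz = z[traits].to_numpy(dtype=float)
    lam = np.asarray(fitness, dtype=float)
    keep = np.isfinite(lam) & np.all(np.isfinite(zz), axis=1)
    zz, lam = zz[keep], lam[keep]
    if (lam <= 0).any():
        raise ValueError("relative fitness must be positive")
    n, k = zz.shape
    cols = (["_intercept"] + [f"{t}:linear" for t in traits]
            + [f"{t}:quadratic" for t in traits])
    D = np.column_stack([np.ones(n), zz, zz ** 2])
    cond = float(np.linalg.cond(D))
    if cond > 1e8:
        raise ValueError(f"ill-conditioned design (condition number {cond:.3g})")

    if error_model == "gamma":
        return _gamma_gradients(D, cols, lam, traits, cond)
    if error_model != "lognormal":
        raise ValueError("error_model must be 'lognormal' or 'gamma'")

    y = np.log(lam)
    coef, rss_full = _ols(D, y)
    ll_full = _gaussian_ll(y - D @ coef)
    # classical OLS standard errors (unbiased residual variance)
    dof = n - D.shape[1]
    sigma2 = rss_full / dof
    XtX_inv = np.linalg.inv(D.T @ D)
    ses = np.sqrt(sigma2 * np.diag(XtX_inv))

    rows = []
    for j, name in enumerate(cols):
        if name == "_intercept":
            continue
        keep_cols = [i for i in range(D.shape[1]) if i != j]
        _, rss_red = _ols(D[:, keep_cols], y)
        ll_red = -0.5 * n * (np.log(2.0 * np.pi * rss_red / n) + 1.0)
        lrt = 2.0 * (ll_full - ll_red)
        pval = float(stats.chi2.sf(max(lrt, 0.0), df=1))
        trait, term = name.split(":")
        rows.append({"trait": trait, "term": term,
                     "estimate": float(coef[j]), "se": float(ses[j]),
                     "lrt_p": pval})
    return GradientFit(pd.DataFrame(rows), float(ll_full), n,
                       float(coef[0]), cond)


def _ols(D, y):
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    return coef, float(resid @ resid)


def _gamma_gradients(D, cols, lam, traits, cond) -> GradientFit:
    import statsmodels.api as sm

    fam = sm.families.Gamma(link=sm.families.links.Log())
    full = sm.GLM(lam, D, family=fam).fit()
    rows = []
    for j, name in enumerate(cols):
        if name == "_intercept":
            continue
        keep_cols = [i for i in range(D.shape[1]) if i != j]
        red = sm.GLM(lam, D[:, keep_cols], family=fam).fit()
        # LRT with the full model's dispersion, as in analysis of deviance
        lrt = (red.deviance - full.deviance) / full.scale
        pval = float(stats.chi2.sf(max(lrt, 0.0), df=1))
        trait, term = name.split(":")
        rows.append({"trait": trait, "term": term,
                     "estimate": float(full.params[j]),
                     "se": float(full.bse[j]), "lrt_p": pval})
    return GradientFit(pd.DataFrame(rows), float(full.llf), len(lam),
                       float(full.params[0]), cond)
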