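"""Genetic parameters from variance components, and FST from SNPs.

For a half-sib design the additive genetic variance is four times the
among-family variance, sigma2_a = 4 sigma2_f.  From a univariate fit:

* heritability       h2  = 4 sigma2_f / (sigma2_f + sigma2_e)
* evolvability       CVa = 100 * sqrt(sigma2_a) / |mean|     (percent)
* differentiation    QST = sigma2_p / (sigma2_p + 8 sigma2_f)

Standard errors of h2 and QST come from the first-order delta method using
the fit's asymptotic component covariance.  Population, row and column
variances are excluded from the heritability denominator (the heritability
refers to within-population phenotypic variance on the micro-environmental
scale of a single tree).

Global FST over populations uses the Weir-Cockerham (1984) variance
-component estimator: per-locus among-population (a), among-individual (b)
and within-individual (c) components, with the global estimate the ratio
of sums over loci and a percentile confidence interval from resampling
loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_model import VarianceComponents
from .synthetic_data import SnpMatrix

__all__ = [
    "GeneticParams",
    "FstResult",
    "heritability",
    "evolvability",
    "qst",
    "fst_global",
    "weir_cockerham_components",
    "qst_fst_compare",
    "genetic_parameters_table",
]


@dataclass
class GeneticParams:
    trait: str
    site: str
    h2: float
    h2_se: float
    cva_pct: float
    qst: float
    qst_se: float
    sigma2_a: float
    boundary: bool = False


@dataclass
class FstResult:
    fst: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_loci: int

    def to_dict(self) -> dict:
        return {"fst": self.fst, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n_boot": self.n_boot,
                "n_loci": self.n_loci}


def heritability(vc: VarianceComponents) -> tuple[float, float]:
    """Narrow-sense heritability and its delta-method standard error."""
    f, e = vc.sigma2_f, vc.sigma2_e
    if f + e <= 0:
        raise ValueError("sigma2_f + sigma2_e must be positive")
    h2 = 4.0 * f / (f + e)
    # gradient of 4f/(f+e) wrt (f, e)
    g = np.array([4.0 * e / (f + e) ** 2, -4.0 * f / (f + e) ** 2])
    cov = np.array([
        [vc.cov_of("family", "family"), vc.cov_of("family", "residual")],
        [vc.cov_of("family", "residual"), vc.cov_of("residual", "residual")],
    ])
    var = float(g @ cov @ g)
    se = float(np.sqrt(var)) if var >= 0 else float("nan")
    return h2, se


def evolvability(vc: VarianceComponents, trait_mean: float,
                 literal: bool = False) -> float:
    """Evolvability CVa as a percentage of the trait mean.

    The standard coefficient of additive genetic variation,
    ``100 * sqrt(sigma2_a) / |mean|``.  ``literal=True`` instead returns
    the raw ratio ``sigma2_a / mean`` (variance over mean, not a
    coefficient of variation; kept for comparability).
    """
    if trait_mean == 0:
        raise ValueError("trait mean must be non-zero")
    sigma2_a = 4.0 * vc.sigma2_f
    if literal:
        return sigma2_a / trait_mean
    return 100.0 * np.sqrt(sigma2_a) / abs(trait_mean)


def qst(vc: VarianceComponents) -> tuple[float, float]:
    """Quantitative genetic differentiation QST and delta-method SE."""
    p, f = vc.sigma2_p, vc.sigma2_f
    if p + 8.0 * f <= 0:
        raise ValueError("sigma2_p + 8*sigma2_f must be positive")
    q = p / (p + 8.0 * f)
    g = np.array([8.0 * f / (p + 8.0 * f) ** 2,
                  -8.0 * p / (p + 8.0 * f) ** 2])
    cov = np.array([
        [vc.cov_of("population", "population"), vc.cov_of("population", "family")],
        [vc.cov_of("population", "family"), vc.cov_of("family", "family")],
    ])
    var = float(g @ cov @ g)
    se = float(np.sqrt(var)) if var >= 0 else float("nan")
    return q, se


# ---------------------------------------------------------------------------
# Weir-Cockerham FST


def weir_cockerham_components(snps: SnpMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (a, a+b+c) variance components of the WC 1984 estimator.

    Works on biallelic dosage data; individuals with a missing genotype are
    excluded locus-wise.  Returns arrays over loci; loci where fewer than
    two populations have data, or that are monomorphic overall, get NaN.
    """
    G = snps.genotypes.to_numpy(dtype=float)
    pops, pop_idx = np.unique(snps.populations.to_numpy(), return_inverse=True)
    r_all = len(pops)
    n_loci = G.shape[1]
    # per population per locus: sample size, allele freq, het frequency
    counts = np.zeros((r_all, n_loci))
    freqs = np.zeros((r_all, n_loci))
    hets = np.zeros((r_all, n_loci))
    for i in range(r_all):
        sub = G[pop_idx == i]
        ok = ~np.isnan(sub)
        counts[i] = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freqs[i] = np.nansum(sub, axis=0) / (2.0 * counts[i])
            hets[i] = np.nansum(sub == 1.0, axis=0) / counts[i]

    a = np.full(n_loci, np.nan)
    abc = np.full(n_loci, np.nan)
    have = counts > 0
    r = have.sum(axis=0).astype(float)
    usable = r >= 2
    n_i = counts
    nbar = np.where(usable, counts.sum(axis=0) / np.maximum(r, 1), np.nan)
    sum_n2 = (counts ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (counts.sum(axis=0) - sum_n2 / counts.sum(axis=0)) / (r - 1.0)
        pbar = np.nansum(np.where(have, n_i * freqs, 0.0), axis=0) / counts.sum(axis=0)
        s2 = np.nansum(np.where(have, n_i * (freqs - pbar) ** 2, 0.0), axis=0) / (
            (r - 1.0) * nbar)
        hbar = np.nansum(np.where(have, n_i * hets, 0.0), axis=0) / counts.sum(axis=0)

        poly = usable & (pbar > 0) & (pbar < 1) & (nbar > 1) & (nc > 0)
        pq = pbar * (1.0 - pbar)
        a_ = (nbar / nc) * (s2 - (pq - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0))
        b_ = (nbar / (nbar - 1.0)) * (
            pq - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c_ = hbar / 2.0
    a[poly] = a_[poly]
    abc[poly] = (a_ + b_ + c_)[poly]
    return a, abc


def fst_global(snps: SnpMatrix, n_boot: int = 1000,
               seed: int | None = 0) -> FstResult:
    """Global multi-population FST with a bootstrap-across-loci 95% CI.

    The point estimate is the ratio of sums of per-locus Weir-Cockerham
    components; the CI is the 2.5-97.5 percentile interval over ``n_boot``
    resamples of loci.
    """
    a, abc = weir_cockerham_components(snps)
    ok = np.isfinite(a) & np.isfinite(abc)
    if not ok.any():
        raise ValueError("no polymorphic loci: FST undefined")
    a, abc = a[ok], abc[ok]
    n_loci = a.size
    fst = float(a.sum() / abc.sum())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_loci, size=(n_boot, n_loci))
    boots = a[idx].sum(axis=1) / abc[idx].sum(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, fst), max(hi, fst)
    return FstResult(fst, float(lo), float(hi), n_boot, n_loci)


def qst_fst_compare(q: GeneticParams | tuple[float, float],
                    f: FstResult) -> str:
    """Verdict on QST vs neutral FST by interval overlap.

    The QST interval is the point estimate +/- 1.96 SE; the FST interval is
    the bootstrap CI.  Returns ``"lower"``, ``"higher"`` or
    ``"not-different"``.  A missing QST SE degrades to a point-vs-interval
    comparison.
    """
    if isinstance(q, GeneticParams):
        q_val, q_se = q.qst, q.qst_se
    else:
        q_val, q_se = q
    if not np.isfinite(q_se):
        q_se = 0.0
    lo, hi = q_val - 1.96 * q_se, q_val + 1.96 * q_se
    if hi < f.ci_low:
        return "lower"
    if lo > f.ci_high:
        return "higher"
    return "not-different"


def genetic_parameters_table(fits: dict[str, VarianceComponents],
                             means: dict[str, float],
                             site: str) -> pd.DataFrame:
    """Assemble the per-trait parameter table for one site."""
    rows = []
    for trait, vc in fits.items():
        h2, h2_se = heritability(vc)
        q, q_se = qst(vc)
        rows.append({
            "trait": trait, "site": site,
            "h2": h2, "h2_se": h2_se,
            "cva_pct": evolvability(vc, means[trait]),
            "qst": q, "qst_se": q_se,
            "sigma2_a": 4.0 * vc.sigma2_f,
            "boundary": bool(vc.boundary),
        })
    return pd.DataFrame(rows)
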