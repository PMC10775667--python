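"""Phenotypic integration: eigenvalue variance of trait correlation matrices.

The integration index (PINT) of N traits over n family records is the
variance of the eigenvalues of their correlation matrix (population
variance, divisor N).  It is 0 for independent traits and N-1 when all
variation lies on a single perfectly correlated axis.  Sampling noise alone
produces an expected eigenvalue variance of (N-1)/n, so the *corrected*
index subtracts that; the *relative* index expresses the uncorrected value
as a percentage of the maximum N-1.

Uncertainty: significance by randomization (independently permuting each
trait column, which destroys correlations while preserving margins) and a
99% confidence interval by bootstrap over family records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntegrationResult",
    "correlation_matrix",
    "pint",
    "relative_from_corrected",
    "pint_randomization",
    "pint_site_contrast",
]


@dataclass
class IntegrationResult:
    site: str
    level: str
    pint_uncorrected: float
    pint_corrected: float
    pint_relative_pct: float
    n_traits: int
    n_records: int
    corr: pd.DataFrame
    ci99: tuple[float, float] | None = None
    p_value: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "site": self.site, "level": self.level,
            "pint_uncorrected": self.pint_uncorrected,
            "pint_corrected": self.pint_corrected,
            "pint_relative_pct": self.pint_relative_pct,
            "n_traits": self.n_traits, "n_records": self.n_records,
            "ci99": list(self.ci99) if self.ci99 else None,
            "p_value": self.p_value,
            "corr": self.corr.to_dict(),
        }


def correlation_matrix(bvs: pd.DataFrame, trait_cols: list[str]) -> pd.DataFrame:
    """Pearson correlations among breeding-value columns across families.

    Pairwise-complete observations are used, so each correlation uses every
    family with both traits present.  Raises on zero-variance traits.
    """
    sub = bvs[trait_cols]
    if len(sub.dropna(how="any")) < 3:
        raise ValueError("need at least 3 complete family records")
    sds = sub.std(ddof=1)
    zero = sds[~(sds > 0)].index.tolist()
    if zero:
        raise ValueError(f"zero-variance traits: {zero}")
    return sub.corr(method="pearson")


def _eigenvalue_variance(corr: np.ndarray) -> float:
    eig = np.linalg.eigvalsh(corr)
    return float(np.var(eig))  # divisor N: population variance of eigenvalues


def pint(corr: pd.DataFrame | np.ndarray, n: int,
         site: str = "", level: str = "") -> IntegrationResult:
    """Integration indices from a correlation matrix and its record count.

    ``n`` is the number of family records that produced the matrix (it sets
    the random-covariation correction (N-1)/n).
    """
    C = np.asarray(corr, dtype=float)
    N = C.shape[0]
    if C.shape != (N, N) or not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if np.linalg.eigvalsh(C).min() < -1e-6:
        raise ValueError("correlation matrix is not positive semi-definite")
    if n <= N - 1:
        raise ValueError("need more records than traits minus one")
    unc = _eigenvalue_variance(C)
    corrected = unc - (N - 1) / n
    relative = 100.0 * unc / (N - 1)
    cdf = corr if isinstance(corr, pd.DataFrame) else pd.DataFrame(C)
    return IntegrationResult(site, level, unc, corrected, relative, N, n, cdf)


def relative_from_corrected(corrected: float, n_traits: int,
                            n_records: int) -> float:
    """Relative integration (%) implied by a corrected index.

    Adds back the random-covariation expectation (N-1)/n to recover the
    uncorrected eigenvalue variance, then scales by the maximum N-1.
    """
    unc = corrected + (n_traits - 1) / n_records
    return 100.0 * unc / (n_traits - 1)


def _corrected_of(values: np.ndarray) -> float:
    n, N = values.shape
    C = np.corrcoef(values, rowvar=False)
    return _eigenvalue_variance(C) - (N - 1) / n


def pint_randomization(bvs: pd.DataFrame, trait_cols: list[str],
                       n_perm: int = 999, seed: int | None = 0,
                       site: str = "", level: str = "",
                       n_boot: int = 999) -> IntegrationResult:
    """Integration indices with randomization p-value and bootstrap 99% CI.

    The null distribution permutes each trait column independently across
    families; p = (1 + #{null >= observed}) / (n_perm + 1) on the corrected
    index.  The 99% CI is the 0.5-99.5 percentile interval of the corrected
    index over ``n_boot`` resamples of families.
    """
    vals = bvs[trait_cols].dropna(how="any").to_numpy(dtype=float)
    n, N = vals.shape
    res = pint(pd.DataFrame(np.corrcoef(vals, rowvar=False),
                            index=trait_cols, columns=trait_cols),
               n, site=site, level=level)
    if n_perm < 99:
        res.warnings.append("n_perm < 99: p-value resolution is coarse")
    rng = np.random.default_rng(seed)
    obs = res.pint_corrected
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = np.column_stack([rng.permutation(vals[:, j]) for j in range(N)])
        null[b] = _corrected_of(perm)
    res.p_value = float((1 + np.sum(null >= obs)) / (n_perm + 1))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = _corrected_of(vals[idx])
    lo, hi = np.percentile(boots, [0.5, 99.5])
    res.ci99 = (float(lo), float(hi))
    return res


def pint_site_contrast(bvs_a: pd.DataFrame, bvs_b: pd.DataFrame,
                       trait_cols: list[str], n_perm: int = 999,
                       seed: int | None = 0) -> float:
    """Permutation p-value for a between-site difference in corrected PINT.

    Pools the family records of both sites, shuffles site labels keeping
    group sizes, and compares |corrected PINT difference| against the
    permutation distribution.
    """
    a = bvs_a[trait_cols].dropna(how="any").to_numpy(dtype=float)
    b = bvs_b[trait_cols].dropna(how="any").to_numpy(dtype=float)
    obs = abs(_corrected_of(a) - _corrected_of(b))
    pooled = np.vstack([a, b])
    na = a.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        order = rng.permutation(pooled.shape[0])
        null[i] = abs(_corrected_of(pooled[order[:na]])
                      - _corrected_of(pooled[order[na:]]))
    return float((1 + np.sum(null >= obs)) / (n_perm + 1))
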