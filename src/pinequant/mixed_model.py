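"""REML variance-component estimation for the trial mixed model.

The analysis model for one trait at one site is

    y = X b + Z_p u_p + Z_f u_f + Z_r u_r + Z_c u_c + e

with fixed block effects ``b`` and independent Gaussian random effects for
population (``p``), mother-tree family nested in population (``f``), field
row (``r``, shared across blocks) and column within block (``c``), plus a
residual.  Univariate fits use EM-REML iterations accelerated by
average-information (AI) steps: an AI step is taken whenever it stays in
the parameter space and increases the restricted likelihood, otherwise the
monotone EM update is used.  Components that collapse toward zero are fixed
at the boundary and the remaining components re-estimated.

Bivariate fits add unstructured 2x2 covariance blocks for the family and
residual terms (and the population term when included) and maximize the
restricted likelihood directly over Cholesky factors of those blocks.

All likelihood computations use the Woodbury identity so the cost scales
with the number of random-effect levels, not the number of trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "fit_reml",
    "fit_bivariate",
    "predict_random_effects",
    "fixed_effect_mean",
]

_ZERO_TOL = 1e-7  # relative collapse threshold for boundary detection


@dataclass(frozen=True)
class ModelSpec:
    """Which trait(s) to fit and which random terms to include.

    ``response`` is a trait name, or a pair of names for a bivariate fit.
    ``include_population`` drops the population term (used for oracle tests
    on purely within-population designs); ``include_rowcol`` drops the field
    row/column terms for data without positional structure.
    """

    response: str | tuple[str, str]
    fixed: str = "block"
    include_population: bool = True
    include_rowcol: bool = True

    @property
    def is_bivariate(self) -> bool:
        return not isinstance(self.response, str)


@dataclass
class VarianceComponents:
    """REML estimates for one fit.

    ``components`` maps component names to estimates: for univariate fits
    the names are ``population``, ``family``, ``row``, ``col``,
    ``residual``; bivariate fits use ``family.<trait>`` for variances and
    ``family.cov`` for covariances (same for ``population`` / ``residual``).
    ``asym_cov`` is the asymptotic covariance matrix of the (non-boundary)
    estimates from the information matrix; boundary components carry zero
    rows and are listed in ``boundary``.
    """

    components: pd.Series
    loglik: float
    n_obs: int
    converged: bool
    boundary: tuple[str, ...]
    asym_cov: pd.DataFrame
    spec: ModelSpec
    n_iter: int = 0
    loglik_path: list[float] = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return float(self.components[name])

    def get(self, name: str, default: float = 0.0) -> float:
        return float(self.components.get(name, default))

    @property
    def sigma2_p(self) -> float:
        return self.get("population")

    @property
    def sigma2_f(self) -> float:
        return self.get("family")

    @property
    def sigma2_r(self) -> float:
        return self.get("row")

    @property
    def sigma2_c(self) -> float:
        return self.get("col")

    @property
    def sigma2_e(self) -> float:
        return self.get("residual")

    def se(self, name: str) -> float:
        if name not in self.asym_cov.index:
            return float("nan")
        return float(np.sqrt(max(self.asym_cov.loc[name, name], 0.0)))

    def cov_of(self, a: str, b: str) -> float:
        if a not in self.asym_cov.index or b not in self.asym_cov.index:
            return float("nan")
        return float(self.asym_cov.loc[a, b])

    def family_correlation(self) -> float:
        """Genetic (family-effect) correlation from a bivariate fit."""
        t1, t2 = self.spec.response
        v1, v2 = self[f"family.{t1}"], self[f"family.{t2}"]
        if v1 <= 0 or v2 <= 0:
            return float("nan")
        return self[f"family.cov"] / np.sqrt(v1 * v2)

    def to_dict(self) -> dict:
        return {
            "components": self.components.to_dict(),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "boundary": list(self.boundary),
            "se": {k: self.se(k) for k in self.components.index},
        }


# ---------------------------------------------------------------------------
# design construction


def _one_hot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _factor(df: pd.DataFrame, col: str) -> tuple[np.ndarray, pd.Index]:
    codes, levels = pd.factorize(df[col], sort=True)
    return _one_hot(codes, len(levels)), pd.Index(levels)


def _design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, dict, dict]:
    """Fixed-effect matrix and random-term incidence matrices."""
    if "site" in df.columns and df["site"].nunique() > 1:
        raise ValueError("fit one site at a time (multiple sites in table)")
    if spec.fixed in df.columns:
        X, _ = _factor(df, spec.fixed)
    else:
        X = np.ones((len(df), 1))
    terms: dict[str, np.ndarray] = {}
    levels: dict[str, pd.Index] = {}
    if spec.include_population:
        if "population" not in df.columns:
            raise ValueError("table has no 'population' column")
        terms["population"], levels["population"] = _factor(df, "population")
    terms["family"], levels["family"] = _factor(df, "family")
    if spec.include_rowcol:
        for col in ("row", "col"):
            if col not in df.columns:
                raise ValueError(f"table has no '{col}' column; "
                                 "set include_rowcol=False")
        terms["row"], levels["row"] = _factor(df, "row")
        colkey = df["block"].astype(str) + ":" + df["col"].astype(str) \
            if "block" in df.columns else df["col"].astype(str)
        codes, lv = pd.factorize(colkey, sort=True)
        terms["col"] = _one_hot(codes, len(lv))
        levels["col"] = pd.Index(lv)
    if terms["family"].shape[1] < 2:
        raise ValueError("random factor 'family' has fewer than 2 levels")
    # a single-level factor is confounded with the intercept and carries no
    # variance information; drop it (its predictions are zero)
    for name in [n for n, Z in terms.items() if Z.shape[1] < 2]:
        del terms[name]
        levels.pop(name, None)
    return X, terms, levels


# ---------------------------------------------------------------------------
# univariate EM/AI REML


class _RemlWork:
    """Per-theta REML quantities for one univariate model."""

    def __init__(self, y, X, terms):
        self.y, self.X = y, X
        self.names = list(terms)
        self.Zs = [terms[k] for k in self.names]
        self.n, self.p = len(y), X.shape[1]
        self.qs = np.array([Z.shape[1] for Z in self.Zs])

    def evaluate(self, theta: np.ndarray, sigma_e: float):
        """Restricted loglik plus the pieces EM/AI steps need.

        theta: variances of the random terms (0 = excluded); sigma_e > 0.
        """
        n, p = self.n, self.p
        active = [i for i, t in enumerate(theta) if t > 0]
        y, X = self.y, self.X
        if active:
            Z = np.hstack([self.Zs[i] for i in active])
            lam = np.concatenate(
                [np.full(self.qs[i], sigma_e / theta[i]) for i in active])
            A = Z.T @ Z + np.diag(lam)
            cA = linalg.cho_factor(A, lower=True)

            def vinv(M):
                return (M - Z @ linalg.cho_solve(cA, Z.T @ M)) / sigma_e

            logdet_V = (
                n * np.log(sigma_e)
                + sum(self.qs[i] * np.log(theta[i]) for i in active)
                + 2.0 * np.log(np.diag(cA[0])).sum()
                - sum(self.qs[i] for i in active) * np.log(sigma_e)
            )
        else:
            Z, cA = None, None

            def vinv(M):
                return M / sigma_e

            logdet_V = n * np.log(sigma_e)

        ViX = vinv(X)
        Viy = vinv(y)
        XtViX = X.T @ ViX
        cX = linalg.cho_factor(XtViX, lower=True)
        beta = linalg.cho_solve(cX, X.T @ Viy)
        Py = Viy - ViX @ beta
        yPy = float(y @ Py)
        ll = -0.5 * (logdet_V + 2.0 * np.log(np.diag(cX[0])).sum() + yPy) \
            - 0.5 * (n - p) * np.log(2.0 * np.pi)

        def proj(M):
            """P @ M given V^{-1} M."""
            ViM = vinv(M)
            return ViM - ViX @ linalg.cho_solve(cX, X.T @ ViM)

        return {
            "ll": ll, "Py": Py, "yPy": yPy, "vinv": vinv, "proj": proj,
            "ViX": ViX, "cX": cX, "beta": beta, "active": active,
        }

    def scores_and_ai(self, theta, sigma_e, ev):
        """Score vector and average-information matrix over all terms + e."""
        Py, proj = ev["Py"], ev["proj"]
        ws = [Z.T @ Py for Z in self.Zs]
        traces = []
        for Z in self.Zs:
            PZ = proj(Z)
            traces.append(float(np.sum(Z * PZ)))
        # tr(P) for the residual score
        I_proj = proj(np.eye(self.n)) if self.n <= 400 else None
        if I_proj is not None:
            trP = float(np.trace(I_proj))
        else:
            trP = self._trace_P(theta, sigma_e, ev)
        U = np.column_stack([Z @ w for Z, w in zip(self.Zs, ws)] + [Py])
        PU = proj(U)
        AI = 0.5 * (U.T @ PU)
        score = np.array(
            [-0.5 * (t - float(w @ w)) for t, w in zip(traces, ws)]
            + [-0.5 * (trP - float(Py @ Py))]
        )
        return score, AI, ws, traces, trP

    def _trace_P(self, theta, sigma_e, ev):
        n = self.n
        active = ev["active"]
        if active:
            Z = np.hstack([self.Zs[i] for i in active])
            lam = np.concatenate(
                [np.full(self.qs[i], sigma_e / theta[i]) for i in active])
            A = Z.T @ Z + np.diag(lam)
            cA = linalg.cho_factor(A, lower=True)
            tr_vinv = (n - float(np.trace(linalg.cho_solve(cA, Z.T @ Z)))) / sigma_e
        else:
            tr_vinv = n / sigma_e
        ViX = ev["ViX"]
        tr_fix = float(np.trace(linalg.cho_solve(ev["cX"], ViX.T @ ViX)))
        return tr_vinv - tr_fix


def _em_ai_reml(y, X, terms, tol=1e-8, max_iter=200):
    work = _RemlWork(y, X, terms)
    names = work.names
    m = len(names)
    vary = float(np.var(y))
    if vary < 1e-24:
        comps = pd.Series(0.0, index=names + ["residual"])
        cov = pd.DataFrame(0.0, index=comps.index, columns=comps.index)
        return comps, 0.0, True, tuple(comps.index), cov, 0, [0.0]

    theta = np.full(m, vary / (m + 1))
    sigma_e = vary / (m + 1)
    frozen = np.zeros(m, dtype=bool)
    floor = _ZERO_TOL * vary

    ev = work.evaluate(theta, sigma_e)
    ll = ev["ll"]
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, AI, ws, traces, trP = work.scores_and_ai(theta, sigma_e, ev)
        # indices: 0..m-1 random terms, m residual; restrict to live params
        live = [i for i in range(m) if not frozen[i]] + [m]
        stepped = False
        try:
            delta = np.linalg.solve(AI[np.ix_(live, live)], score[live])
            cand = np.concatenate([theta, [sigma_e]])
            cand[live] = cand[live] + delta
            # overshoots below zero are damped, not zeroed: only the EM
            # collapse rule may fix a component at the boundary
            prev = np.concatenate([theta, [sigma_e]])
            low = prev[:m] * 0.1
            cand[:m] = np.where(frozen, 0.0, np.maximum(cand[:m], low))
            if cand[m] > 1e-12 * vary and np.all(np.isfinite(cand)):
                ev_new = work.evaluate(cand[:m], cand[m])
                if np.isfinite(ev_new["ll"]) and ev_new["ll"] >= ll - 1e-10:
                    theta, sigma_e, ev = cand[:m], cand[m], ev_new
                    stepped = True
        except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
            pass
        if not stepped:
            # monotone EM-REML update
            new_theta = theta.copy()
            for i in range(m):
                if frozen[i]:
                    continue
                new_theta[i] = theta[i] + theta[i] ** 2 * (
                    float(ws[i] @ ws[i]) - traces[i]) / work.qs[i]
            new_sigma_e = sigma_e + sigma_e ** 2 * (
                float(ev["Py"] @ ev["Py"]) - trP) / work.n
            theta, sigma_e = np.maximum(new_theta, 0.0), new_sigma_e
            ev = work.evaluate(theta, sigma_e)
        # boundary collapse: fix tiny components at zero
        collapse = (~frozen) & (theta < floor)
        if collapse.any():
            frozen |= collapse
            theta[collapse] = 0.0
            ev = work.evaluate(theta, sigma_e)
        ll_new = ev["ll"]
        # near a plateau, profile small components at exactly zero: EM decays
        # toward a zero boundary geometrically and would otherwise creep for
        # hundreds of iterations without converging
        if abs(ll_new - ll) < 100.0 * tol * (1.0 + abs(ll)):
            for i in range(m):
                if frozen[i] or not theta[i] < 1e-2 * vary:
                    continue
                trial = theta.copy()
                trial[i] = 0.0
                ev_trial = work.evaluate(trial, sigma_e)
                if ev_trial["ll"] >= ll_new - 1e-8 * (1.0 + abs(ll_new)):
                    theta, ev = trial, ev_trial
                    frozen[i] = True
                    ll_new = ev["ll"]
        path.append(ll_new)
        if abs(ll_new - ll) < tol * (1.0 + abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    if not converged:
        warnings.warn("REML did not converge within max_iter", RuntimeWarning)

    # asymptotic covariance from the AI matrix at the solution
    score, AI, *_ = work.scores_and_ai(theta, sigma_e, ev)
    live = [i for i in range(m) if not frozen[i]] + [m]
    idx = names + ["residual"]
    cov = pd.DataFrame(0.0, index=idx, columns=idx)
    try:
        inv = np.linalg.inv(AI[np.ix_(live, live)])
        for a, ia in enumerate(live):
            for b, ib in enumerate(live):
                cov.iloc[ia, ib] = inv[a, b]
    except np.linalg.LinAlgError:
        cov[:] = np.nan

    comps = pd.Series(np.concatenate([theta, [sigma_e]]), index=idx)
    boundary = tuple(np.array(names)[frozen])
    return comps, float(ll), converged, boundary, cov, it, path


def fit_reml(table: pd.DataFrame, spec: ModelSpec,
             tol: float = 1e-8, max_iter: int = 200) -> VarianceComponents:
    """Univariate REML fit of the trial mixed model for one trait.

    Rows with a missing response are dropped.  Returns the variance
    components with their asymptotic covariance, the restricted
    log-likelihood and convergence information.
    """
    if spec.is_bivariate:
        return fit_bivariate(table, spec, tol=tol, max_iter=max_iter)
    df = table.dropna(subset=[spec.response]).reset_index(drop=True)
    y = df[spec.response].to_numpy(dtype=float)
    X, terms, _ = _design(df, spec)
    n_req = X.shape[1] + len(terms) + 1
    if len(y) < n_req:
        raise ValueError(f"need at least {n_req} non-missing records")
    comps, ll, conv, boundary, cov, it, path = _em_ai_reml(
        y, X, terms, tol=tol, max_iter=max_iter)
    return VarianceComponents(comps, ll, len(y), conv, boundary, cov, spec,
                              n_iter=it, loglik_path=path)


# ---------------------------------------------------------------------------
# bivariate REML


class _BivWork:
    """Cross-product-space restricted likelihood for a two-trait model.

    Records are conceptually stacked trait-major over the complete-case
    trees; every matrix product with the residual precision Sigma_e^{-1}
    (x) I is assembled from single-trait cross-products, so each likelihood
    evaluation costs O(q^3) in the number of random-effect levels q.
    """

    def __init__(self, y1, y2, X, terms):
        self.names = list(terms)  # structured 2x2 terms come first
        self.Zbase = [terms[k] for k in self.names]
        self.qs = [Z.shape[1] for Z in self.Zbase]
        self.n = len(y1)
        self.p = X.shape[1]
        M = np.column_stack(self.Zbase + [X, y1, y2])
        self.G0 = M.T @ M
        self.off = np.concatenate([[0], np.cumsum(self.qs)])
        self.xsl = slice(self.off[-1], self.off[-1] + self.p)
        self.y1i, self.y2i = self.off[-1] + self.p, self.off[-1] + self.p + 1
        self.yty = np.array([[self.G0[self.y1i, self.y1i],
                              self.G0[self.y1i, self.y2i]],
                             [self.G0[self.y2i, self.y1i],
                              self.G0[self.y2i, self.y2i]]])

    def loglik(self, blocks: dict[str, np.ndarray], scalars: dict[str, float],
               sigma_e: np.ndarray) -> float:
        """blocks: 2x2 PD covariance per structured term; scalars: per-trait
        variances of unstructured terms keyed "<term>.<1|2>"; sigma_e 2x2 PD.
        """
        n, p = self.n, self.p
        try:
            Einv = np.linalg.inv(sigma_e)
        except np.linalg.LinAlgError:
            return -np.inf
        sE, ldE = np.linalg.slogdet(sigma_e)
        if sE <= 0:
            return -np.inf

        # assemble column layout of the stacked Z
        cols = []  # (term_index, trait, global slice in A)
        ginv_diag = []
        ld_G = 0.0
        pos = 0
        for i, name in enumerate(self.names):
            q = self.qs[i]
            if name in blocks:
                S = blocks[name]
                sS, ldS = np.linalg.slogdet(S)
                if sS <= 0:
                    return -np.inf
                Sinv = np.linalg.inv(S)
                cols.append((i, 0, slice(pos, pos + q)))
                cols.append((i, 1, slice(pos + q, pos + 2 * q)))
                ginv_diag.append(("block", i, Sinv, q))
                ld_G += q * ldS
                pos += 2 * q
            else:
                for t in (0, 1):
                    v = scalars.get(f"{name}.{t + 1}", 0.0)
                    if v > 0:
                        cols.append((i, t, slice(pos, pos + q)))
                        ginv_diag.append(("scalar", i, v, q))
                        ld_G += q * np.log(v)
                        pos += q
        qa = pos

        def cross(i, j):  # base cross-product Z_i^T Z_j (X = index -1)
            si = self.xsl if i == -1 else slice(self.off[i], self.off[i] + self.qs[i])
            sj = self.xsl if j == -1 else slice(self.off[j], self.off[j] + self.qs[j])
            return self.G0[si, sj]

        def zy(i, t):  # Z_i^T y_t
            si = self.xsl if i == -1 else slice(self.off[i], self.off[i] + self.qs[i])
            return self.G0[si, self.y1i + t]

        if qa:
            A = np.zeros((qa, qa))
            ZtRy = np.zeros(qa)
            ZtRX = np.zeros((qa, 2 * p))
            for a, (ia, ta, sa) in enumerate(cols):
                for ib, tb, sb in cols:
                    A[sa, sb] += Einv[ta, tb] * cross(ia, ib)
                ZtRy[sa] = Einv[ta, 0] * zy(ia, 0) + Einv[ta, 1] * zy(ia, 1)
                for t in (0, 1):
                    ZtRX[sa, t * p:(t + 1) * p] = Einv[ta, t] * cross(ia, -1)
            # add G^{-1}
            pos = 0
            for kind, i, val, q in ginv_diag:
                if kind == "block":
                    Sinv = val
                    s0, s1 = slice(pos, pos + q), slice(pos + q, pos + 2 * q)
                    A[s0, s0] += Sinv[0, 0] * np.eye(q)
                    A[s1, s1] += Sinv[1, 1] * np.eye(q)
                    A[s0, s1] += Sinv[0, 1] * np.eye(q)
                    A[s1, s0] += Sinv[1, 0] * np.eye(q)
                    pos += 2 * q
                else:
                    sl = slice(pos, pos + q)
                    A[sl, sl] += np.eye(q) / val
                    pos += q
            try:
                cA = linalg.cho_factor(A, lower=True)
            except linalg.LinAlgError:
                return -np.inf
            ld_A = 2.0 * np.log(np.diag(cA[0])).sum()
            AinvZy = linalg.cho_solve(cA, ZtRy)
            AinvZX = linalg.cho_solve(cA, ZtRX)
        else:
            ld_A = 0.0

        # X^T V^{-1} X etc. (stacked X = blockdiag(X, X))
        XtRX = np.zeros((2 * p, 2 * p))
        XtRy = np.zeros(2 * p)
        XX = cross(-1, -1)
        for t in (0, 1):
            for s in (0, 1):
                XtRX[t * p:(t + 1) * p, s * p:(s + 1) * p] = Einv[t, s] * XX
            XtRy[t * p:(t + 1) * p] = Einv[t, 0] * zy(-1, 0) + Einv[t, 1] * zy(-1, 1)
        ytRy = float(np.sum(Einv * self.yty))
        if qa:
            XtVX = XtRX - ZtRX.T @ AinvZX
            XtVy = XtRy - ZtRX.T @ AinvZy
            ytVy = ytRy - float(ZtRy @ AinvZy)
        else:
            XtVX, XtVy, ytVy = XtRX, XtRy, ytRy
        try:
            cXX = linalg.cho_factor(XtVX, lower=True)
        except linalg.LinAlgError:
            return -np.inf
        yPy = ytVy - float(XtVy @ linalg.cho_solve(cXX, XtVy))
        ld_V = n * ldE + ld_G + ld_A
        ld_X = 2.0 * np.log(np.diag(cXX[0])).sum()
        nn = 2 * n - 2 * p
        return -0.5 * (ld_V + ld_X + yPy) - 0.5 * nn * np.log(2.0 * np.pi)


def _chol_to_cov(l11, l21, l22):
    return np.array([[l11 ** 2, l11 * l21],
                     [l11 * l21, l21 ** 2 + l22 ** 2]])


def fit_bivariate(table: pd.DataFrame, spec: ModelSpec,
                  tol: float = 1e-8, max_iter: int = 200,
                  se: bool = True) -> VarianceComponents:
    """Bivariate REML fit with unstructured family/residual covariance.

    Fits the two traits jointly on trees with both traits observed.  The
    family and residual terms (and population, when included) carry
    unstructured 2x2 covariance blocks parameterized by their Cholesky
    factors, which keeps every iterate positive semi-definite; row and
    column terms, when included, have per-trait variances without
    cross-trait covariance.  Set ``se=False`` to skip the numerical
    information matrix (faster for simulation loops).
    """
    t1, t2 = spec.response
    df = table.dropna(subset=[t1, t2]).reset_index(drop=True)
    y1 = df[t1].to_numpy(dtype=float)
    y2 = df[t2].to_numpy(dtype=float)
    # fit on unit-variance responses so every parameter is O(1); component
    # estimates are scaled back afterwards
    sc1, sc2 = np.std(y1), np.std(y2)
    if sc1 <= 0 or sc2 <= 0:
        raise ValueError("constant response in bivariate fit")
    y1, y2 = y1 / sc1, y2 / sc2
    r_emp = float(np.corrcoef(y1, y2)[0, 1])
    if abs(r_emp) > 1.0 - 1e-10:
        return _degenerate_bivariate(df, spec, t1, t2, sc1, sc2,
                                     np.sign(r_emp))
    X, terms, _ = _design(df, spec)
    work = _BivWork(y1, y2, X, terms)
    structured = [n for n in work.names if n in ("population", "family")] + []
    structured += ["residual"]
    scalar_terms = [n for n in work.names if n not in structured]

    s1, s2 = np.std(y1), np.std(y2)
    # start: equal split of each trait's variance over terms, with the
    # empirical response correlation seeding every covariance block (a
    # zero-covariance start stalls for strongly correlated traits)
    k = len(work.names) + 1
    v1, v2 = s1 ** 2 / k, s2 ** 2 / k
    r0 = float(np.clip(np.corrcoef(y1, y2)[0, 1], -0.95, 0.95))

    p0, names_par = [], []
    for name in structured:
        p0 += [np.sqrt(v1), r0 * np.sqrt(v2), np.sqrt(v2 * (1 - r0 ** 2))]
        names_par += [f"{name}.l11", f"{name}.l21", f"{name}.l22"]
    for name in scalar_terms:
        p0 += [v1, v2]
        names_par += [f"{name}.1", f"{name}.2"]
    p0 = np.array(p0)

    lb, ub = [], []
    for name in structured:
        lb += [1e-6 * s1, -np.inf, 1e-6 * s2]
        ub += [np.inf] * 3
    for name in scalar_terms:
        lb += [1e-10 * s1 ** 2, 1e-10 * s2 ** 2]
        ub += [np.inf, np.inf]

    def unpack(par):
        blocks, scalars = {}, {}
        i = 0
        for name in structured:
            cov = _chol_to_cov(par[i], par[i + 1], par[i + 2])
            if name == "residual":
                sig_e = cov
            else:
                blocks[name] = cov
            i += 3
        for name in scalar_terms:
            scalars[f"{name}.1"], scalars[f"{name}.2"] = par[i], par[i + 1]
            i += 2
        return blocks, scalars, sig_e

    def nll(par):
        blocks, scalars, sig_e = unpack(par)
        ll = work.loglik(blocks, scalars, sig_e)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(
        nll, p0, method="L-BFGS-B", bounds=list(zip(lb, ub)),
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
    )
    blocks, scalars, sig_e = unpack(res.x)
    # restricted loglik of the unscaled data (contrast-space Jacobian)
    ll = -res.fun - (work.n - work.p) * (np.log(sc1) + np.log(sc2))

    comp, scale = {}, {}
    for name in structured:
        S = sig_e if name == "residual" else blocks[name]
        comp[f"{name}.{t1}"] = S[0, 0]
        comp[f"{name}.{t2}"] = S[1, 1]
        comp[f"{name}.cov"] = S[0, 1]
        scale[f"{name}.{t1}"], scale[f"{name}.{t2}"] = sc1 ** 2, sc2 ** 2
        scale[f"{name}.cov"] = sc1 * sc2
    for name in scalar_terms:
        comp[f"{name}.{t1}"] = scalars[f"{name}.1"]
        comp[f"{name}.{t2}"] = scalars[f"{name}.2"]
        scale[f"{name}.{t1}"], scale[f"{name}.{t2}"] = sc1 ** 2, sc2 ** 2
    comps = pd.Series(comp)

    cov_df = pd.DataFrame(np.nan, index=comps.index, columns=comps.index)
    if se:
        cov_df = _component_covariance(nll, res.x, structured, scalar_terms,
                                       comps.index, t1, t2)
    sc_vec = pd.Series(scale)[comps.index]
    comps = comps * sc_vec
    cov_df = cov_df * np.outer(sc_vec, sc_vec)

    return VarianceComponents(
        comps, float(ll), len(df), bool(res.success), (), cov_df, spec,
        n_iter=int(res.nit),
    )


def _degenerate_bivariate(df, spec, t1, t2, sc1, sc2, sign):
    """Exactly collinear responses: the joint model is singular, so the
    components follow from the univariate fit of trait 1 by scaling."""
    uni = fit_reml(df.assign(**{t1: df[t1]}),
                   ModelSpec(response=t1, fixed=spec.fixed,
                             include_population=spec.include_population,
                             include_rowcol=spec.include_rowcol))
    names = list(uni.components.index)
    comp = {}
    for name in names:
        v = uni[name]
        comp[f"{name}.{t1}"] = v
        comp[f"{name}.{t2}"] = v * (sc2 / sc1) ** 2
        if name in ("population", "family", "residual"):
            comp[f"{name}.cov"] = sign * v * (sc2 / sc1)
    comps = pd.Series(comp)
    cov_df = pd.DataFrame(np.nan, index=comps.index, columns=comps.index)
    return VarianceComponents(comps, uni.loglik, uni.n_obs, uni.converged,
                              uni.boundary, cov_df, spec, n_iter=uni.n_iter)


def _component_covariance(nll, x_opt, structured, scalar_terms, comp_index,
                          t1, t2):
    """Asymptotic covariance of the components via the Cholesky chart.

    The observed information is differenced in the optimizer's Cholesky
    parameter space (feasible by construction even when a covariance block
    sits at the positive-semi-definite boundary) and pushed forward to the
    component scale with the Jacobian of the quadratic Cholesky-to-
    covariance map.
    """
    m = len(x_opt)
    # steps large enough that loglik differences clear evaluation noise
    h = np.maximum(np.abs(x_opt) * 1e-3, 1e-4)
    H = np.zeros((m, m))
    f0 = -nll(x_opt)

    def f(vec):
        return -nll(vec)

    def pert(deltas):
        v = x_opt.copy()
        for i, d in deltas.items():
            v[i] += d
        return v

    with np.errstate(all="ignore"):
        for i in range(m):
            H[i, i] = (f(pert({i: h[i]})) - 2 * f0 + f(pert({i: -h[i]}))) \
                / h[i] ** 2
            for j in range(i + 1, m):
                H[i, j] = H[j, i] = (
                    f(pert({i: h[i], j: h[j]})) - f(pert({i: h[i], j: -h[j]}))
                    - f(pert({i: -h[i], j: h[j]}))
                    + f(pert({i: -h[i], j: -h[j]}))
                ) / (4 * h[i] * h[j])
    H[~np.isfinite(H)] = 0.0
    cov_par = np.linalg.pinv(-H, hermitian=True)

    # Jacobian d(components)/d(cholesky params), rows follow comp_index
    names = list(comp_index)
    J = np.zeros((len(names), m))
    pos = 0
    for name in structured:
        l11, l21, l22 = x_opt[pos], x_opt[pos + 1], x_opt[pos + 2]
        J[names.index(f"{name}.{t1}"), pos] = 2 * l11
        J[names.index(f"{name}.{t2}"), pos + 1] = 2 * l21
        J[names.index(f"{name}.{t2}"), pos + 2] = 2 * l22
        J[names.index(f"{name}.cov"), pos] = l21
        J[names.index(f"{name}.cov"), pos + 1] = l11
        pos += 3
    for name in scalar_terms:
        J[names.index(f"{name}.{t1}"), pos] = 1.0
        J[names.index(f"{name}.{t2}"), pos + 1] = 1.0
        pos += 2
    cov = J @ cov_par @ J.T
    return pd.DataFrame(cov, index=names, columns=names)


# ---------------------------------------------------------------------------
# random-effect prediction


def predict_random_effects(fit: VarianceComponents, table: pd.DataFrame,
                           spec: ModelSpec | None = None) -> dict[str, pd.Series]:
    """Empirical BLUPs of every random-effect level at the REML estimates.

    Returns ``{factor: Series indexed by level}`` with ``u_hat = G Z' P y``
    evaluated at the fitted components.  Factors estimated at the zero
    boundary get all-zero predictions.
    """
    if not fit.converged:
        raise ValueError("cannot predict from an unconverged fit")
    spec = spec or fit.spec
    if spec.is_bivariate:
        raise NotImplementedError("predictions are univariate per trait")
    df = table.dropna(subset=[spec.response]).reset_index(drop=True)
    y = df[spec.response].to_numpy(dtype=float)
    X, terms, levels = _design(df, spec)
    work = _RemlWork(y, X, terms)
    theta = np.array([fit.get(name) for name in work.names])
    sigma_e = fit.sigma2_e
    if sigma_e <= 0:
        return {name: pd.Series(0.0, index=levels[name])
                for name in work.names}
    ev = work.evaluate(theta, sigma_e)
    out = {}
    for name, Z, t in zip(work.names, work.Zs, theta):
        u = t * (Z.T @ ev["Py"])
        out[name] = pd.Series(u, index=levels[name], name=name)
    return out


def fixed_effect_mean(fit: VarianceComponents, table: pd.DataFrame,
                      spec: ModelSpec | None = None) -> float:
    """Mean of the estimated fixed (block) effects: the site-level mean."""
    spec = spec or fit.spec
    df = table.dropna(subset=[spec.response]).reset_index(drop=True)
    y = df[spec.response].to_numpy(dtype=float)
    X, terms, _ = _design(df, spec)
    work = _RemlWork(y, X, terms)
    theta = np.array([fit.get(name) for name in work.names])
    ev = work.evaluate(theta, fit.sigma2_e)
    return float(np.mean(ev["beta"]))
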