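"""REML engine: oracles, boundary handling, invariances, bivariate fits."""

import numpy as np
import pandas as pd
import pytest

from pinequant.mixed_model import (ModelSpec, fit_reml, fit_bivariate,
                                   predict_random_effects)
from pinequant.synthetic_data import simulate_trial

ONEWAY = ModelSpec(response="Y", include_population=False,
                   include_rowcol=False)


def _anova_sigma2f(obs, k):
    g = obs.groupby("family")["Y"]
    msb = g.mean().var(ddof=1) * k
    msw = g.var(ddof=1).mean()
    return (msb - msw) / k


class TestUnivariate:
    def test_matches_balanced_anova_oracle(self, halfsib_config):
        # REML on a balanced one-way layout equals the closed-form
        # method-of-moments estimator when that estimate is interior
        for seed in (0, 1, 2):
            obs = simulate_trial(halfsib_config(n_fam=100, seed=seed))
            # single fixed-effect level so blocks do not perturb balance
            obs["block"] = 1
            oracle = _anova_sigma2f(obs, 8)
            assert oracle > 0
            fit = fit_reml(obs, ONEWAY)
            assert fit.converged
            assert fit.sigma2_f == pytest.approx(oracle, abs=1e-6)

    def test_constant_response_all_zero(self, halfsib_config):
        obs = simulate_trial(halfsib_config(var_fam=0.0, var_res=0.0))
        fit = fit_reml(obs, ONEWAY)
        assert fit.sigma2_f == 0.0 and fit.sigma2_e == 0.0
        assert fit.converged and len(fit.boundary) > 0

    def test_parameter_recovery_nested(self, nested_config):
        # sigma2_p=2, sigma2_f=1, sigma2_e=4; mean estimates within 10%
        spec = ModelSpec(response="Y", include_rowcol=False)
        est = np.zeros(3)
        n_rep = 50
        for s in range(n_rep):
            obs = simulate_trial(nested_config(var_pop=2.0, var_fam=1.0,
                                               var_res=4.0, seed=100 + s))
            fit = fit_reml(obs, spec)
            est += [fit.sigma2_p, fit.sigma2_f, fit.sigma2_e]
        est /= n_rep
        assert np.all(np.abs(est / np.array([2.0, 1.0, 4.0]) - 1.0) < 0.10)

    def test_loglik_monotone_over_iterations(self, nested_config):
        obs = simulate_trial(nested_config(seed=8))
        fit = fit_reml(obs, ModelSpec(response="Y", include_rowcol=False))
        # small slack: fixing a vanishing component at the zero boundary may
        # trade a sub-tolerance amount of loglik for an exact boundary value
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) > -1e-4)

    def test_invariant_to_relabeling_and_row_order(self, nested_config):
        obs = simulate_trial(nested_config(seed=3))
        spec = ModelSpec(response="Y", include_rowcol=False)
        ref = fit_reml(obs, spec)
        shuffled = obs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.assign(
            family=shuffled["family"].map(lambda f: f"fam_{hash(f) % 10**6}"),
            population=shuffled["population"].map(lambda p: f"zz{p}"))
        alt = fit_reml(relabeled, spec)
        assert np.allclose(ref.components, alt.components, rtol=1e-6,
                           atol=1e-8)

    def test_zero_population_variance_hits_boundary(self, nested_config):
        # truth on the boundary: the REML estimate is exactly zero in about
        # half of replicates (the 1/2 chi2_0 + 1/2 chi2_1 mixture), and the
        # remainder are small; with finite-sample shrinkage the exact-zero
        # rate sits somewhat above one half
        spec = ModelSpec(response="Y", include_rowcol=False)
        at_zero = 0
        for s in range(50):
            obs = simulate_trial(nested_config(var_pop=0.0, seed=500 + s))
            fit = fit_reml(obs, spec)
            at_zero += fit.sigma2_p == 0.0
            assert fit.sigma2_p < 0.5  # never a materially positive estimate
        assert at_zero >= 25

    def test_too_few_records_rejected(self, halfsib_config):
        obs = simulate_trial(halfsib_config(n_fam=4, k=2)).head(3)
        with pytest.raises(ValueError, match="non-missing records"):
            fit_reml(obs, ONEWAY)


class TestBivariate:
    BSPEC = ModelSpec(response=("A", "B"), include_population=False,
                      include_rowcol=False)

    def test_zero_correlation_cov_near_zero(self, two_trait_config):
        obs = simulate_trial(two_trait_config(r=0.0, seed=4))
        fit = fit_bivariate(obs, self.BSPEC)
        cov = fit["family.cov"]
        assert abs(cov) < 2.0 * fit.se("family.cov")

    def test_duplicate_trait_correlation_one(self, two_trait_config):
        obs = simulate_trial(two_trait_config(seed=9))
        obs["B"] = obs["A"]
        fit = fit_bivariate(obs, self.BSPEC, se=False)
        assert fit.family_correlation() == pytest.approx(1.0, abs=1e-6)

    def test_correlation_recovery(self, two_trait_config):
        ests = []
        for s in range(50):
            obs = simulate_trial(two_trait_config(r=0.6, seed=200 + s))
            fit = fit_bivariate(obs, self.BSPEC, se=False)
            ests.append(fit.family_correlation())
        assert 0.5 < np.mean(ests) < 0.7

    def test_marginals_match_univariate(self, two_trait_config):
        obs = simulate_trial(two_trait_config(r=0.4, seed=11))
        biv = fit_bivariate(obs, self.BSPEC, se=False)
        for t in ("A", "B"):
            uni = fit_reml(obs, ModelSpec(response=t,
                                          include_population=False,
                                          include_rowcol=False))
            assert biv[f"family.{t}"] == pytest.approx(uni.sigma2_f, rel=0.05,
                                                       abs=0.02)
            assert biv[f"residual.{t}"] == pytest.approx(uni.sigma2_e,
                                                         rel=0.05)


class TestPredictions:
    def test_zero_family_variance_full_shrinkage(self, halfsib_config):
        obs = simulate_trial(halfsib_config(var_fam=0.0, var_res=2.0, seed=2))
        fit = fit_reml(obs, ONEWAY)
        preds = predict_random_effects(fit, obs)
        assert np.allclose(preds["family"], 0.0)

    def test_no_shrinkage_limit_recovers_family_means(self, halfsib_config):
        obs = simulate_trial(halfsib_config(var_fam=50.0, var_res=0.01,
                                            seed=2))
        obs["block"] = 1
        fit = fit_reml(obs, ONEWAY)
        preds = predict_random_effects(fit, obs)
        dev = obs.groupby("family")["Y"].mean() - obs["Y"].mean()
        u = preds["family"].reindex(dev.index)
        assert np.allclose(u, dev, rtol=0.01, atol=0.01 * dev.std())

    def test_family_predictions_sum_to_zero_balanced(self, halfsib_config):
        obs = simulate_trial(halfsib_config(n_fam=60, seed=6))
        obs["block"] = 1
        fit = fit_reml(obs, ONEWAY)
        u = predict_random_effects(fit, obs)["family"]
        assert abs(u.sum()) < 1e-6 * u.std()

    def test_nested_sums_follow_shrinkage_identity(self, nested_config):
        # with random population effects the within-population family sums
        # equal (lambda_p / lambda_f) * u_pop, not zero
        obs = simulate_trial(nested_config(seed=13))
        obs["block"] = 1
        fit = fit_reml(obs, ModelSpec(response="Y", include_rowcol=False))
        preds = predict_random_effects(fit, obs)
        fam_pop = obs[["family", "population"]].drop_duplicates()
        sums = (preds["family"].rename("u").reset_index()
                .merge(fam_pop, left_on="index", right_on="family")
                .groupby("population")["u"].sum())
        expected = preds["population"] * (fit.sigma2_f / fit.sigma2_p)
        assert np.allclose(sums, expected.reindex(sums.index), atol=1e-6)

    def test_unconverged_fit_rejected(self, nested_config):
        obs = simulate_trial(nested_config(seed=1))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = fit_reml(obs, ModelSpec(response="Y", include_rowcol=False),
                           max_iter=1, tol=1e-14)
        with pytest.raises(ValueError, match="unconverged"):
            predict_random_effects(fit, obs)
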