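"""Selection gradients: relative fitness, beta_G, log-linear model, LRTs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pinequant.mixed_model import ModelSpec, fit_bivariate
from pinequant.selection import (relative_fitness, genetic_gradient,
                                 phenotypic_gradients)
from pinequant.synthetic_data import SimulationConfig, simulate_trial, \
    simulate_trial_detailed


class TestRelativeFitness:
    def test_scaling(self):
        out = relative_fitness(pd.Series([10.0, 20.0, 30.0]))
        assert np.allclose(out, [0.5, 1.0, 1.5])

    def test_constant_heights(self):
        assert (relative_fitness(pd.Series([7.0, 7.0, 7.0])) == 1.0).all()

    def test_mean_exactly_one(self):
        rng = np.random.default_rng(0)
        out = relative_fitness(pd.Series(rng.uniform(50, 150, 100)))
        assert out.mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            relative_fitness(pd.Series([1.0, -2.0]))


def _fitness_trait_config(beta=0.2, seed=0, n_fam=119):
    """Fitness trait W carrying a linear selection signal on trait A
    (family variance of A is 1, so the generating gradient equals beta)."""
    return SimulationConfig(
        n_populations=1, families_per_population=n_fam, trees_per_family=8,
        trait_names=("W", "A"), trait_means={"W": 1.0, "A": 10.0},
        var_fam={"W": 0.04, "A": 1.0}, var_res={"W": 1.0, "A": 3.0},
        beta_true={"A": beta} if beta else {}, fitness_trait="W",
        n_blocks=4, grid_rows=16, grid_cols=64, seed=seed)


BSPEC = ModelSpec(response=("W", "A"), include_population=False,
                  include_rowcol=False)


class TestGeneticGradient:
    def test_null_within_two_se(self):
        obs = simulate_trial(_fitness_trait_config(beta=0.0, seed=11))
        fit = fit_bivariate(obs, BSPEC)
        bg, se = genetic_gradient(fit, "W", "A")
        assert abs(bg) < 2.0 * se

    def test_self_regression_is_one(self):
        obs = simulate_trial(_fitness_trait_config(seed=9))
        obs["W"] = obs["A"]
        fit = fit_bivariate(obs, ModelSpec(response=("A", "W"),
                                           include_population=False,
                                           include_rowcol=False), se=False)
        assert genetic_gradient(fit, "A", "W")[0] == pytest.approx(1.0,
                                                                   abs=1e-6)

    def test_recovery_of_generating_gradient(self):
        ests = []
        for s in range(50):
            obs = simulate_trial(_fitness_trait_config(beta=0.2,
                                                       seed=300 + s))
            fit = fit_bivariate(obs, BSPEC, se=False)
            ests.append(genetic_gradient(fit, "W", "A")[0])
        assert 0.15 < np.mean(ests) < 0.25


def _null_fit(seed, n_fam=119):
    rng = np.random.default_rng(seed)
    z = pd.DataFrame(rng.standard_normal((n_fam, 5)), columns=list("abcde"))
    lam = np.exp(rng.normal(0.0, 0.1, n_fam))
    lam /= lam.mean()
    return phenotypic_gradients(z, pd.Series(lam))


class TestPhenotypicGradients:
    def test_null_coefficients_small_and_p_spread(self):
        g = _null_fit(0)
        for _, r in g.table.iterrows():
            assert abs(r.estimate) < 2.5 * r.se
        assert (g.table["lrt_p"] > 0.05).sum() >= 8

    def test_recovery_at_table_magnitudes(self):
        rng = np.random.default_rng(1)
        n = 500
        z = pd.DataFrame(rng.standard_normal((n, 5)), columns=list("abcde"))
        lnl = 0.232 * z["d"] - 0.032 * z["d"] ** 2 + rng.normal(0, 0.05, n)
        lam = np.exp(lnl)
        lam /= lam.mean()
        g = phenotypic_gradients(z, pd.Series(lam))
        assert g.coef("d", "linear") == pytest.approx(0.232, abs=0.02)
        assert g.coef("d", "quadratic") == pytest.approx(-0.032, abs=0.02)

    def test_single_population_levels_coincide(self, halfsib_config):
        # with one population the within and total breeding values are the
        # same numbers, so the fitted gradients must agree exactly
        from pinequant.breeding_values import breeding_value_table, \
            standardize
        from pinequant.mixed_model import fit_reml
        cfg = SimulationConfig(
            n_populations=1, families_per_population=80, trees_per_family=8,
            trait_names=("HT", "A", "B"),
            trait_means={"HT": 100.0, "A": 10.0, "B": 5.0},
            var_fam={"HT": 25.0, "A": 1.0, "B": 0.5},
            var_res={"HT": 75.0, "A": 3.0, "B": 1.5},
            beta_true={"A": 0.1}, fitness_trait="HT",
            n_blocks=4, grid_rows=16, grid_cols=64, seed=6)
        obs = simulate_trial(cfg)
        fits = {t: fit_reml(obs, ModelSpec(response=t, include_rowcol=False))
                for t in ("HT", "A", "B")}
        bvt = breeding_value_table(fits, obs, "S")
        results = {}
        for level in ("within", "total"):
            frame = bvt.rename(columns={f"{t}__{level}": t
                                        for t in ("HT", "A", "B")})
            lam = relative_fitness(100.0 + frame["HT"])
            z = standardize(frame, trait_cols=["A", "B"])
            results[level] = phenotypic_gradients(z[["A", "B"]], lam)
        a = results["within"].table["estimate"].to_numpy()
        b = results["total"].table["estimate"].to_numpy()
        assert np.allclose(a, b, atol=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(st.integers(0, 10_000))
    def test_sign_flip_equivariance(self, seed):
        # flipping a trait's sign negates beta and preserves gamma
        rng = np.random.default_rng(seed)
        z = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        lam = np.exp(0.15 * z["b"] - 0.02 * z["b"] ** 2
                     + rng.normal(0, 0.05, 80))
        lam /= lam.mean()
        g1 = phenotypic_gradients(z, pd.Series(lam))
        z2 = z.copy()
        z2["b"] = -z2["b"]
        g2 = phenotypic_gradients(z2, pd.Series(lam))
        assert g2.coef("b", "linear") == pytest.approx(
            -g1.coef("b", "linear"), abs=1e-10)
        assert g2.coef("b", "quadratic") == pytest.approx(
            g1.coef("b", "quadratic"), abs=1e-10)

    def test_gamma_glm_alternative_agrees_in_sign(self):
        rng = np.random.default_rng(2)
        n = 300
        z = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        lam = np.exp(0.2 * z["a"] + rng.normal(0, 0.1, n))
        lam /= lam.mean()
        g_ln = phenotypic_gradients(z, pd.Series(lam))
        g_gm = phenotypic_gradients(z, pd.Series(lam), error_model="gamma")
        assert g_gm.coef("a", "linear") == pytest.approx(
            g_ln.coef("a", "linear"), abs=0.03)
        assert g_gm.p("a", "linear") < 0.01

    def test_lrt_type_one_error_moderate_sample(self):
        # null coefficient rejected at ~nominal rate (50 quick replicates;
        # the full 200-replicate calibration runs in the acceptance suite)
        rej = sum(_null_fit(s).p("a", "linear") < 0.05 for s in range(50))
        assert rej / 50 <= 0.12


class TestSignConsistency:
    def test_genetic_and_phenotypic_gradients_share_sign(self):
        # common generating gradient: beta_G and the within/total phenotypic
        # betas should agree in sign in nearly all replicates
        from pinequant.breeding_values import breeding_value_table, \
            standardize
        from pinequant.mixed_model import fit_reml
        agree = 0
        n_rep = 10
        for s in range(n_rep):
            cfg = SimulationConfig(
                n_populations=4, families_per_population=30,
                trees_per_family=8, trait_names=("W", "A"),
                trait_means={"W": 1.0, "A": 10.0},
                var_pop={"W": 0.005, "A": 0.3},
                var_fam={"W": 0.01, "A": 1.0},
                var_res={"W": 0.5, "A": 3.0},
                beta_true={"A": 0.3}, fitness_trait="W",
                n_blocks=4, grid_rows=16, grid_cols=64, seed=800 + s)
            obs = simulate_trial(cfg)
            bfit = fit_bivariate(obs, ModelSpec(response=("W", "A"),
                                                include_rowcol=False),
                                 se=False)
            bg = genetic_gradient(bfit, "W", "A")[0]
            fits = {t: fit_reml(obs, ModelSpec(response=t,
                                               include_rowcol=False))
                    for t in ("W", "A")}
            bvt = breeding_value_table(fits, obs, "S")
            signs = [np.sign(bg)]
            for level in ("within", "total"):
                frame = bvt.rename(columns={f"{t}__{level}": t
                                            for t in ("W", "A")})
                lam = relative_fitness(1.0 + frame["W"])
                z = standardize(frame, trait_cols=["A"])
                g = phenotypic_gradients(z[["A"]], lam)
                signs.append(np.sign(g.coef("A", "linear")))
            agree += len(set(signs)) == 1
        assert agree >= 9
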