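import numpy as np
import pytest

from pinequant.synthetic_data import SimulationConfig


@pytest.fixture
def halfsib_config():
    """Balanced one-way half-sib layout: one population, no field gradients."""
    def make(n_fam=119, k=8, var_fam=1.0, var_res=3.0, seed=0, **kw):
        return SimulationConfig(
            n_populations=1, families_per_population=n_fam,
            trees_per_family=k, trait_names=("Y",), trait_means={"Y": 10.0},
            var_fam={"Y": var_fam}, var_res={"Y": var_res},
            n_blocks=4, grid_rows=32, grid_cols=64, fitness_trait="Y",
            seed=seed, **kw)
    return make


@pytest.fixture
def nested_config():
    """Study-scale nested layout: 11 populations x 11 families x 8 trees."""
    def make(var_pop=1.0, var_fam=1.0, var_res=3.0, seed=0, **kw):
        return SimulationConfig(
            n_populations=11, families_per_population=11, trees_per_family=8,
            trait_names=("Y",), trait_means={"Y": 10.0},
            var_pop={"Y": var_pop}, var_fam={"Y": var_fam},
            var_res={"Y": var_res}, n_blocks=4, grid_rows=16, grid_cols=64,
            fitness_trait="Y", seed=seed, **kw)
    return make


@pytest.fixture
def two_trait_config():
    """Two correlated traits on the half-sib layout (for bivariate fits)."""
    def make(r=0.6, n_fam=119, seed=0, **kw):
        return SimulationConfig(
            n_populations=1, families_per_population=n_fam, trees_per_family=8,
            trait_names=("A", "B"), trait_means={"A": 10.0, "B": 10.0},
            var_fam={"A": 1.0, "B": 1.0}, var_res={"A": 3.0, "B": 3.0},
            genetic_corr=np.array([[1.0, r], [r, 1.0]]),
            n_blocks=4, grid_rows=16, grid_cols=64, fitness_trait="A",
            seed=seed, **kw)
    return make
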