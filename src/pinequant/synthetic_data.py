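"""Synthetic provenance-progeny trial and SNP panel generator.

Emulates a maritime pine common-garden experiment: populations sampled
across the species range, half-sib families (open-pollinated mother trees)
nested within populations, trees planted on a row-column design with four
blocks, and six traits (height as a fitness proxy plus five functional
traits).  The generator draws every effect from the linear-Gaussian model
the downstream REML analysis assumes, so that variance components, breeding
values, integration indices and selection gradients are all recoverable
from known truth.

Trait model for tree k of family f in population p at grid cell (r, c) of
block b::

    y = mean + u_pop(p) + u_fam(f) + u_row(r) + u_col(b, c) + e

with independent zero-mean Gaussian effects of the configured variances.
Family effects are drawn jointly across traits with covariance
``diag(sd_fam) @ genetic_corr @ diag(sd_fam)`` so genetic correlations are
controlled.  The fitness trait additionally carries a selection signal on
the standardized family effects of the other traits (see
:func:`simulate_trial`), making the true selection gradients known.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TrialData",
    "SnpMatrix",
    "simulate_trial",
    "simulate_plasticity_trait",
    "simulate_snps",
    "default_config",
]

#: Trait set of the emulated experiment.  HT (height, cm) is the fitness
#: proxy; M_D13C / PI_D13C are the mean and year-to-year plasticity of
#: carbon isotope discrimination (per mil); SLA specific leaf area
#: (mm^2/mg); DW needle dry weight (mg); PGI phenology growth index
#: (dimensionless early-growth ratio).
DEFAULT_TRAITS = ("HT", "M_D13C", "PI_D13C", "SLA", "DW", "PGI")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a single-site provenance-progeny simulation.

    Variances are in squared trait units; ``genetic_corr`` is the matrix of
    family-effect correlations between traits; ``beta_true`` / ``gamma_true``
    are linear and quadratic selection coefficients acting on standardized
    family effects (the scale on which gradients are later estimated).
    """

    n_populations: int = 11
    families_per_population: int = 11
    trees_per_family: int = 8
    n_blocks: int = 4
    grid_rows: int = 16
    grid_cols: int = 64
    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    trait_means: dict[str, float] = field(default_factory=dict)
    var_pop: dict[str, float] = field(default_factory=dict)
    var_fam: dict[str, float] = field(default_factory=dict)
    var_row: dict[str, float] = field(default_factory=dict)
    var_col: dict[str, float] = field(default_factory=dict)
    var_res: dict[str, float] = field(default_factory=dict)
    genetic_corr: np.ndarray | None = None
    beta_true: dict[str, float] = field(default_factory=dict)
    gamma_true: dict[str, float] = field(default_factory=dict)
    fitness_trait: str = "HT"
    n_loci: int = 2000
    individuals_per_population: int = 20
    fst_target: float = 0.13
    missing_rate: float = 0.0
    site: str = "HiProd"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fst_target < 1:
            raise ValueError("fst_target must lie strictly inside (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for name in ("var_pop", "var_fam", "var_row", "var_col", "var_res"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} entries must be non-negative")
        if self.genetic_corr is not None:
            g = np.asarray(self.genetic_corr, dtype=float)
            k = len(self.trait_names)
            if g.shape != (k, k):
                raise ValueError("genetic_corr shape must match trait_names")
            if not np.allclose(g, g.T, atol=1e-10):
                raise ValueError("genetic_corr must be symmetric")
            if not np.allclose(np.diag(g), 1.0, atol=1e-10):
                raise ValueError("genetic_corr must have unit diagonal")
            if np.linalg.eigvalsh(g).min() < -1e-8:
                raise ValueError("genetic_corr must be positive semi-definite")

    @property
    def n_families(self) -> int:
        return self.n_populations * self.families_per_population

    @property
    def n_trees(self) -> int:
        return self.n_families * self.trees_per_family

    def corr_matrix(self) -> np.ndarray:
        if self.genetic_corr is None:
            return np.eye(len(self.trait_names))
        return np.asarray(self.genetic_corr, dtype=float)

    def vec(self, d: dict[str, float], default: float = 0.0) -> np.ndarray:
        return np.array([d.get(t, default) for t in self.trait_names])


@dataclass
class TrialData:
    """Simulated observations plus the generating truth.

    ``observations`` is the long-format trial table (one row per tree);
    ``family_effects`` and ``population_effects`` hold the realized random
    effects per trait, indexed by family / population identifier, so that
    recovery of variance components, BLUPs and selection gradients can be
    checked against truth.  ``z_family`` are the standardized family effects
    (family effect divided by the true family SD) the fitness signal was
    built from.
    """

    observations: pd.DataFrame
    family_effects: pd.DataFrame
    population_effects: pd.DataFrame
    z_family: pd.DataFrame
    config: SimulationConfig


@dataclass
class SnpMatrix:
    """Biallelic genotype panel: individuals x loci, minor-allele dosages.

    ``genotypes`` holds values in {0, 1, 2} with NaN for missing;
    ``populations`` gives the population label of each individual (aligned
    with the genotype rows).
    """

    genotypes: pd.DataFrame
    populations: pd.Series

    def __post_init__(self) -> None:
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype values must be 0/1/2 or missing")
        if self.populations.nunique() < 2:
            raise ValueError("at least two populations required")


def default_config(site: str = "HiProd", seed: int = 0) -> SimulationConfig:
    """Study-scale default configuration for one common-garden site.

    Variance levels are set so that heritabilities fall near 0.25, CVa near
    10% of the trait mean (delta13C plasticity higher), and QST near 0.10;
    genetic correlations and selection coefficients mirror the qualitative
    pattern of the experiment (height positively associated with needle
    biomass, negatively with late phenology).
    """
    traits = DEFAULT_TRAITS
    means = {"HT": 200.0, "M_D13C": -28.0, "PI_D13C": 1.5, "SLA": 5.0,
             "DW": 40.0, "PGI": 0.40}
    if site == "LoProd":
        means["HT"] = 120.0
    # sigma_a = cva/100 * |mean|, var_fam = sigma_a^2 / 4 (half-sib)
    cva = {"HT": 10.0, "M_D13C": 2.5, "PI_D13C": 25.0, "SLA": 3.0,
           "DW": 10.0, "PGI": 10.0}
    var_fam = {t: (cva[t] / 100.0 * abs(means[t])) ** 2 / 4.0 for t in traits}
    h2 = 0.25
    var_res = {t: var_fam[t] * (4.0 / h2 - 1.0) for t in traits}
    qst = 0.10
    var_pop = {t: 8.0 * var_fam[t] * qst / (1.0 - qst) for t in traits}
    var_row = {t: 0.05 * var_res[t] for t in traits}
    var_col = {t: 0.05 * var_res[t] for t in traits}
    corr = np.eye(len(traits))
    pairs = {("HT", "DW"): 0.5, ("HT", "PGI"): -0.4, ("SLA", "DW"): -0.3,
             ("M_D13C", "PI_D13C"): 0.2}
    idx = {t: i for i, t in enumerate(traits)}
    for (a, b), r in pairs.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    beta = {"M_D13C": -0.030, "PI_D13C": 0.027, "SLA": 0.132,
            "DW": 0.232, "PGI": -0.046}
    gamma = {"DW": -0.032, "PGI": -0.026}
    fams = 11 if site != "LoProd" else 4
    return SimulationConfig(
        families_per_population=fams,
        trait_means=means, var_pop=var_pop, var_fam=var_fam,
        var_row=var_row, var_col=var_col, var_res=var_res,
        genetic_corr=corr, beta_true=beta, gamma_true=gamma,
        site=site, seed=seed,
    )


def _layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign trees to blocks and grid cells.

    Blocks are vertical strips of columns; rows run across blocks while
    columns are identified within their block, matching the analysis model
    (row effects shared across blocks, column effects nested in blocks).
    Each family contributes one plot of up to ``trees_per_family / n_blocks``
    trees per block, placed at random cells of the block.
    """
    n = config.n_trees
    if config.grid_cols % config.n_blocks:
        raise ValueError("grid_cols must be divisible by n_blocks")
    cols_per_block = config.grid_cols // config.n_blocks
    cells_per_block = config.grid_rows * cols_per_block
    per_block = -(-n // config.n_blocks)  # ceil
    if per_block > cells_per_block:
        raise ValueError(
            f"grid overflow: {per_block} trees/block but only "
            f"{cells_per_block} cells/block"
        )
    rows = np.empty(n, dtype=int)
    cols = np.empty(n, dtype=int)
    blocks = np.empty(n, dtype=int)
    # tree order: population-major, family, tree; deal trees of each family
    # round-robin over blocks so families are replicated in every block
    order = np.arange(n)
    block_of = order % config.n_blocks
    for b in range(config.n_blocks):
        members = order[block_of == b]
        cells = rng.choice(cells_per_block, size=members.size, replace=False)
        rows[members] = cells // cols_per_block
        cols[members] = b * cols_per_block + cells % cols_per_block
        blocks[members] = b
    return pd.DataFrame({"block": blocks + 1, "row": rows + 1, "col": cols + 1})


def simulate_trial(config: SimulationConfig) -> pd.DataFrame:
    """Simulate one site of the provenance-progeny trial.

    Returns the long-format observation table (one row per tree) with
    design factors and one column per trait.  All randomness is a pure
    function of ``config.seed``.  See :func:`simulate_trial_detailed` for
    the generating truth.
    """
    return simulate_trial_detailed(config).observations


def simulate_trial_detailed(config: SimulationConfig) -> TrialData:
    """Simulate a site and return observations together with true effects."""
    rng = np.random.default_rng(config.seed)
    traits = list(config.trait_names)
    k = len(traits)
    n_pop, n_fam = config.n_populations, config.n_families
    n = config.n_trees

    means = config.vec(config.trait_means)
    sd_pop = np.sqrt(config.vec(config.var_pop))
    sd_fam = np.sqrt(config.vec(config.var_fam))
    sd_row = np.sqrt(config.vec(config.var_row))
    sd_col = np.sqrt(config.vec(config.var_col))
    sd_res = np.sqrt(config.vec(config.var_res))

    pop_eff = rng.standard_normal((n_pop, k)) * sd_pop

    # family effects jointly across traits: cov = D^(1/2) corr D^(1/2)
    corr = config.corr_matrix()
    cov = np.outer(sd_fam, sd_fam) * corr
    # PSD square root (eigendecomposition tolerates zero-variance traits)
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    fam_eff = rng.standard_normal((n_fam, k)) @ root.T

    # standardized family effects on the true-SD scale
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_fam > 0, fam_eff / np.where(sd_fam > 0, sd_fam, 1.0), 0.0)

    # fitness: multiplicative selection signal on standardized family
    # effects, so ln(relative fitness) is exactly sum(beta*z + gamma*z^2)
    fit_j = traits.index(config.fitness_trait)
    beta = config.vec(config.beta_true)
    gamma = config.vec(config.gamma_true)
    if np.any(beta) or np.any(gamma):
        s = z @ beta + (z**2) @ gamma
        fam_eff[:, fit_j] += means[fit_j] * (np.exp(s) - 1.0)

    layout = _layout(config, rng)
    row_eff = rng.standard_normal((config.grid_rows, k)) * sd_row
    col_eff = rng.standard_normal((config.grid_cols, k)) * sd_col
    res = rng.standard_normal((n, k)) * sd_res

    pop_ids = np.repeat(np.arange(n_pop), config.families_per_population * config.trees_per_family)
    fam_ids = np.repeat(np.arange(n_fam), config.trees_per_family)

    values = (
        means
        + pop_eff[pop_ids]
        + fam_eff[fam_ids]
        + row_eff[layout["row"].to_numpy() - 1]
        + col_eff[layout["col"].to_numpy() - 1]
        + res
    )
    if config.missing_rate > 0:
        miss = rng.random((n, k)) < config.missing_rate
        values = np.where(miss, np.nan, values)

    pop_names = np.array([f"P{i+1:02d}" for i in range(n_pop)])
    fam_names = np.array(
        [f"P{p+1:02d}F{f % config.families_per_population + 1:02d}"
         for f, p in zip(range(n_fam), np.repeat(np.arange(n_pop), config.families_per_population))]
    )
    obs = pd.DataFrame({
        "site": config.site,
        "block": layout["block"].to_numpy(),
        "row": layout["row"].to_numpy(),
        "col": layout["col"].to_numpy(),
        "population": pop_names[pop_ids],
        "family": fam_names[fam_ids],
        "tree": [f"{fam_names[f]}T{i % config.trees_per_family + 1}"
                 for i, f in enumerate(fam_ids)],
    })
    for j, t in enumerate(traits):
        obs[t] = values[:, j]

    fam_df = pd.DataFrame(fam_eff, index=fam_names, columns=traits)
    fam_df.index.name = "family"
    pop_df = pd.DataFrame(pop_eff, index=pop_names, columns=traits)
    pop_df.index.name = "population"
    z_df = pd.DataFrame(z, index=fam_names, columns=traits)
    z_df.index.name = "family"
    return TrialData(obs, fam_df, pop_df, z_df, config)


def simulate_two_sites(config_hi: SimulationConfig,
                       config_lo: SimulationConfig | None = None) -> pd.DataFrame:
    """Simulate both common-garden sites as independent draws."""
    if config_lo is None:
        config_lo = replace(
            default_config("LoProd", seed=config_hi.seed + 1),
        )
    return pd.concat(
        [simulate_trial(config_hi), simulate_trial(config_lo)],
        ignore_index=True,
    )


def simulate_plasticity_trait(year_hi: pd.Series, year_lo: pd.Series) -> pd.Series:
    """Plastic response of a trait between two growing seasons.

    Defined as the value in the wetter year minus the value in the drier
    year (for delta13C, the 5th minus the 6th growing season).  Missing if
    either year is missing.
    """
    if not year_hi.index.equals(year_lo.index):
        raise ValueError("year_hi and year_lo must be aligned on the same trees")
    return year_hi - year_lo


def simulate_snps(config: SimulationConfig) -> SnpMatrix:
    """Draw a neutral SNP panel with population structure at a target FST.

    Ancestral allele frequencies are uniform on (0.05, 0.95); population
    frequencies follow the Balding-Nichols beta model
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` whose among-population frequency
    variance gives E[FST] = ``fst_target``; genotypes are binomial(2, p).
    """
    f = config.fst_target
    rng = np.random.default_rng(config.seed)
    n_pop = config.n_populations
    n_ind = config.individuals_per_population
    p_anc = rng.uniform(0.05, 0.95, size=config.n_loci)
    shape = (1.0 - f) / f
    a, b = p_anc * shape, (1.0 - p_anc) * shape
    p_pop = rng.beta(a, b, size=(n_pop, config.n_loci))
    geno = rng.binomial(2, p_pop[:, None, :].repeat(n_ind, axis=1)).astype(float)
    geno = geno.reshape(n_pop * n_ind, config.n_loci)
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = np.nan
    pops = np.repeat([f"P{i+1:02d}" for i in range(n_pop)], n_ind)
    ind = [f"{p}I{i % n_ind + 1:03d}" for i, p in enumerate(pops)]
    gdf = pd.DataFrame(geno, index=ind,
                       columns=[f"L{j+1:05d}" for j in range(config.n_loci)])
    return SnpMatrix(gdf, pd.Series(pops, index=ind, name="population"))
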