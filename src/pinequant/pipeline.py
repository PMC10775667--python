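"""End-to-end analysis: simulate/load -> REML -> parameters -> BLUPs ->
integration -> selection, with per-stage logging and a reproducible report.

Each site is analyzed independently (every fit is per site); the only
cross-site step is the integration contrast.  All outputs are pure
functions of (inputs, config, seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic_data import (SimulationConfig, default_config, simulate_trial,
                             simulate_snps)
from .mixed_model import ModelSpec, fit_reml, fit_bivariate, fixed_effect_mean
from .genetic_parameters import (genetic_parameters_table, fst_global,
                                 qst_fst_compare, GeneticParams)
from .breeding_values import breeding_value_table, standardize
from .integration import pint_randomization, pint_site_contrast
from .selection import relative_fitness, genetic_gradient, phenotypic_gradients
from . import io as pqio

log = logging.getLogger("pinequant")

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """One pipeline run: where the data come from and what to compute."""

    observations: str | None = None      # CSV path; None -> simulate
    snps: str | None = None              # genotype CSV; None -> simulate
    popmap: str | None = None
    sim: dict = field(default_factory=dict)       # per-site SimulationConfig overrides
    sites: list[str] = field(default_factory=lambda: ["HiProd", "LoProd"])
    traits: list[str] = field(default_factory=lambda: [
        "HT", "M_D13C", "PI_D13C", "SLA", "DW", "PGI"])
    fitness_trait: str = "HT"
    n_boot: int = 1000
    n_perm: int = 999
    seed: int = 0
    include_rowcol: bool = True
    out_dir: str = "pinequant_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _site_config(cfg: RunConfig, site: str, seed: int) -> SimulationConfig:
    base = default_config(site, seed=seed)
    overrides = dict(cfg.sim.get(site, cfg.sim.get("all", {})))
    if overrides:
        from dataclasses import replace
        base = replace(base, **overrides)
    return base


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.error("stage %s failed", name)
                raise RuntimeError(f"pipeline stage '{name}' failed") from None
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle to out_dir.

    Returns the in-memory report: genetic parameters and selection
    gradients per site, integration indices per site and level, global
    FST, and the QST-FST verdicts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(cfg.seed)

    # --- data ---------------------------------------------------------
    if cfg.observations:
        obs = pqio.read_observations(cfg.observations)
    else:
        parts = []
        for i, site in enumerate(cfg.sites):
            parts.append(simulate_trial(_site_config(cfg, site, rng_seed + i)))
        obs = pd.concat(parts, ignore_index=True)
        pqio.write_observations(obs, out / "observations.csv")
    if cfg.snps:
        snps = pqio.read_snps(cfg.snps, cfg.popmap)
    else:
        snps = simulate_snps(_site_config(cfg, cfg.sites[0], rng_seed + 101))

    report: dict = {"sites": {}, "manifest": {
        "config_digest": cfg.digest(), "seed": cfg.seed,
        "version": __version__,
        "n_obs": int(len(obs)),
    }}

    # --- FST (shared across sites) ------------------------------------
    fst = fst_global(snps, n_boot=cfg.n_boot, seed=rng_seed + 7)
    report["fst"] = fst.to_dict()
    log.info("stage fst done: %.4f (%.4f, %.4f)", fst.fst, fst.ci_low, fst.ci_high)

    bv_std_by_site: dict[str, dict[str, pd.DataFrame]] = {}

    for site in cfg.sites:
        site_obs = obs[obs["site"] == site].reset_index(drop=True)
        if site_obs.empty:
            raise RuntimeError(f"pipeline stage 'data' failed: no rows for {site}")
        sres: dict = {}
        t0 = time.perf_counter()

        # univariate fits
        fits = {}
        for trait in cfg.traits:
            spec = ModelSpec(response=trait,
                             include_rowcol=cfg.include_rowcol)
            fits[trait] = fit_reml(site_obs, spec)
        log.info("stage fits[%s] done in %.1fs (converged: %s)", site,
                 time.perf_counter() - t0,
                 all(f.converged for f in fits.values()))

        # genetic parameters + QST-FST verdicts
        means = {t: float(site_obs[t].mean()) for t in cfg.traits}
        params = genetic_parameters_table(fits, means, site)
        params.to_csv(out / f"genetic_parameters_{site}.csv", index=False)
        verdicts = {}
        for _, row in params.iterrows():
            gp = GeneticParams(row.trait, site, row.h2, row.h2_se,
                               row.cva_pct, row.qst, row.qst_se, row.sigma2_a)
            verdicts[row.trait] = qst_fst_compare(gp, fst)
        sres["genetic_parameters"] = params.to_dict(orient="records")
        sres["qst_fst_verdicts"] = verdicts

        # breeding values at both levels
        bvt = breeding_value_table(fits, site_obs, site)
        bvt.to_csv(out / f"breeding_values_{site}.csv", index=False)
        level_frames = {}
        for level in ("within", "total"):
            cols = {f"{t}__{level}": t for t in cfg.traits}
            frame = bvt[["family", "population"] + list(cols)].rename(columns=cols)
            level_frames[level] = frame
        bv_std_by_site[site] = level_frames

        # phenotypic integration
        sres["integration"] = {}
        for level, frame in level_frames.items():
            res = pint_randomization(
                frame, cfg.traits, n_perm=cfg.n_perm, seed=rng_seed + 11,
                site=site, level=level)
            sres["integration"][level] = res.to_dict()
            res.corr.to_csv(out / f"correlations_{site}_{level}.csv")

        # selection gradients
        fit_trait = cfg.fitness_trait
        others = [t for t in cfg.traits if t != fit_trait]
        grad_rows = []
        fitness_mean = float(site_obs[fit_trait].mean())
        for trait in others:
            bspec = ModelSpec(response=(fit_trait, trait),
                              include_rowcol=cfg.include_rowcol)
            bfit = fit_bivariate(site_obs, bspec)
            bg, bg_se = genetic_gradient(bfit, fit_trait, trait,
                                         fitness_mean=fitness_mean)
            grad_rows.append({"trait": trait, "site": site,
                              "coefficient": "beta_G", "level": "genetic",
                              "estimate": bg, "se": bg_se, "lrt_p": np.nan})
        site_mean = fixed_effect_mean(fits[fit_trait], site_obs)
        for level, frame in level_frames.items():
            heights = site_mean + frame[fit_trait].to_numpy(dtype=float)
            lam = relative_fitness(pd.Series(heights, index=frame.index))
            z = standardize(frame, trait_cols=others)
            gfit = phenotypic_gradients(z[others], lam, traits=others)
            for _, r in gfit.table.iterrows():
                name = "beta" if r.term == "linear" else "gamma"
                grad_rows.append({"trait": r.trait, "site": site,
                                  "coefficient": name, "level": level,
                                  "estimate": r.estimate, "se": r.se,
                                  "lrt_p": r.lrt_p})
        grads = pd.DataFrame(grad_rows)
        grads.to_csv(out / f"selection_gradients_{site}.csv", index=False)
        sres["gradients"] = grads.to_dict(orient="records")
        report["sites"][site] = sres

    # cross-site integration contrast (within-population level)
    if len(cfg.sites) == 2:
        a, b = cfg.sites
        report["integration_site_contrast_p"] = {
            level: pint_site_contrast(
                bv_std_by_site[a][level], bv_std_by_site[b][level],
                cfg.traits, n_perm=cfg.n_perm, seed=rng_seed + 13)
            for level in ("within", "total")
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    _write_summary(report, out / "summary.txt")
    return report


def _write_summary(report: dict, path: Path) -> None:
    lines = [f"pinequant run {report['manifest']['config_digest']}",
             f"FST = {report['fst']['fst']:.4f} "
             f"({report['fst']['ci_low']:.4f}, {report['fst']['ci_high']:.4f})"]
    for site, sres in report["sites"].items():
        lines.append(f"\n== {site} ==")
        for rec in sres["genetic_parameters"]:
            lines.append(
                f"  {rec['trait']:>8}: h2={rec['h2']:.3f}±{rec['h2_se']:.3f}  "
                f"CVa={rec['cva_pct']:.1f}%  QST={rec['qst']:.3f}"
                f"±{rec['qst_se']:.3f} ({sres['qst_fst_verdicts'][rec['trait']]})")
        for level, ires in sres["integration"].items():
            lines.append(
                f"  PINT[{level}]: corrected={ires['pint_corrected']:.3f} "
                f"relative={ires['pint_relative_pct']:.2f}% p={ires['p_value']:.3f}")
    path.write_text("\n".join(lines) + "\n")
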