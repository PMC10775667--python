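"""Mother-tree breeding values at two levels of variation.

From each univariate fit, the family-term BLUP is the *within-population*
breeding value (population effect excluded: selection acting inside each
population), and the sum of the population-term and family-term BLUPs is
the *total* breeding value (population effect included: selection acting
across the species).  Values are family-level predictions in trait units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mixed_model import ModelSpec, VarianceComponents, predict_random_effects

__all__ = ["breeding_values", "standardize", "breeding_value_table"]


def breeding_values(fit: VarianceComponents, table: pd.DataFrame,
                    spec: ModelSpec | None = None) -> pd.DataFrame:
    """Within-population and total breeding values for one trait.

    Returns one row per family with columns ``family``, ``population``,
    ``bv_within`` and ``bv_total``; ``bv_total - bv_within`` equals the
    population-level prediction of the family's population.
    """
    spec = spec or fit.spec
    preds = predict_random_effects(fit, table, spec)
    fam = preds["family"]
    fam_pop = (
        table.dropna(subset=[spec.response])[["family", "population"]]
        .drop_duplicates()
        .set_index("family")["population"]
    )
    out = pd.DataFrame({
        "family": fam.index,
        "population": fam_pop.reindex(fam.index).to_numpy(),
        "bv_within": fam.to_numpy(),
    })
    if "population" in preds:
        pop = preds["population"]
        out["bv_total"] = out["bv_within"] + pop.reindex(out["population"]).to_numpy()
    else:
        out["bv_total"] = out["bv_within"]
    return out


def breeding_value_table(fits: dict[str, VarianceComponents],
                         table: pd.DataFrame, site: str) -> pd.DataFrame:
    """Wide family x trait breeding-value table for one site.

    Columns are a two-level layout: ``<trait>__within`` / ``<trait>__total``
    plus ``family`` and ``population``.
    """
    merged: pd.DataFrame | None = None
    for trait, fit in fits.items():
        bv = breeding_values(fit, table)
        bv = bv.rename(columns={"bv_within": f"{trait}__within",
                                "bv_total": f"{trait}__total"})
        merged = bv if merged is None else merged.merge(
            bv, on=["family", "population"], how="outer")
    merged.insert(0, "site", site)
    return merged


def standardize(bvs: pd.DataFrame, trait_cols: list[str] | None = None,
                exclude: tuple[str, ...] = ()) -> pd.DataFrame:
    """Center and scale breeding-value columns to mean 0, sample SD 1.

    The sample SD (n-1 denominator) is used.  Columns named in ``exclude``
    (typically the fitness trait) are left untouched.  A zero-variance
    column raises, naming the trait.
    """
    out = bvs.copy()
    if trait_cols is None:
        trait_cols = [c for c in bvs.columns
                      if bvs[c].dtype.kind == "f" and c not in exclude]
    if len(bvs) < 2:
        raise ValueError("need at least two families to standardize")
    for c in trait_cols:
        if c in exclude:
            continue
        x = out[c].to_numpy(dtype=float)
        sd = np.nanstd(x, ddof=1)
        if not sd > 0:
            raise ValueError(f"zero-variance breeding-value column: {c}")
        out[c] = (x - np.nanmean(x)) / sd
    return out
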