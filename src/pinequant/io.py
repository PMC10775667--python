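"""Reading and writing the trial tables and genotype panels.

Observation tables travel as plain CSV with the documented header
(site, block, row, col, population, family, tree, then one column per
trait); missing trait values are empty fields.  Genotype panels are CSV
matrices (individuals x loci) with a two-column population map, or a
biallelic VCF (GT field only) when cyvcf2 is available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import SnpMatrix

DESIGN_COLS = ["site", "block", "row", "col", "population", "family", "tree"]

__all__ = ["read_observations", "write_observations",
           "read_snps", "write_snps", "read_vcf", "DESIGN_COLS"]


def write_observations(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_observations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DESIGN_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table lacks columns: {missing}")
    dup = df.duplicated(subset=["site", "tree"])
    if dup.any():
        raise ValueError("(site, tree) pairs must be unique")
    trait_cols = [c for c in df.columns if c not in DESIGN_COLS]
    vals = df[trait_cols].to_numpy(dtype=float)
    if np.isinf(vals).any():
        raise ValueError("non-finite trait values present")
    return df


def write_snps(snps: SnpMatrix, geno_path: str | Path,
               popmap_path: str | Path) -> None:
    snps.genotypes.to_csv(geno_path, index_label="individual")
    snps.populations.rename_axis("individual").to_csv(popmap_path)


def read_snps(geno_path: str | Path, popmap_path: str | Path) -> SnpMatrix:
    geno = pd.read_csv(geno_path, index_col="individual")
    popmap = pd.read_csv(popmap_path, index_col="individual")["population"]
    return SnpMatrix(geno.astype(float), popmap.reindex(geno.index))


def read_vcf(path: str | Path, popmap_path: str | Path) -> SnpMatrix:
    """Read biallelic genotypes (GT only) from a VCF into a dosage panel.

    Requires the optional cyvcf2 dependency.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional reader
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    loci, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan  # unknown
        rows.append(gt)
        loci.append(f"{var.CHROM}:{var.POS}")
    geno = pd.DataFrame(np.array(rows).T, index=samples, columns=loci)
    popmap = pd.read_csv(popmap_path, index_col="individual")["population"]
    return SnpMatrix(geno, popmap.reindex(geno.index))
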