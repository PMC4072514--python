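"""Core in-memory containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "ExpressionMatrix", "validate_gene_annotation"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage table with per-SNP metadata.

    ``dosages`` is indexed by individual id with one column per SNP id
    (values in [0, 2]; hard calls are {0,1,2}).  ``snps`` is indexed by SNP
    id with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``, ``maf``
    and optionally ``r2`` (imputation quality).
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame
    subpop: pd.Series | None = None

    def __post_init__(self):
        if not self.snps.index.is_unique:
            raise ValueError("duplicate SNP ids")
        if list(self.dosages.columns) != list(self.snps.index):
            raise ValueError("dosage columns and SNP metadata index disagree")
        vals = self.dosages.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages outside [0, 2]")
        for _, sub in self.snps.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("SNP positions not sorted within chromosome")

    @property
    def individuals(self) -> pd.Index:
        return self.dosages.index

    @property
    def n_individuals(self) -> int:
        return len(self.dosages.index)

    @property
    def n_snps(self) -> int:
        return len(self.snps.index)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[list(snp_ids)], self.snps.loc[list(snp_ids)], self.subpop
        )


@dataclass
class ExpressionMatrix:
    """Individuals x genes normalized expression on the natural-log scale."""

    values: pd.DataFrame
    state: str = "rest"

    def __post_init__(self):
        if self.state not in ("rest", "stim"):
            raise ValueError(f"state must be 'rest' or 'stim', got {self.state!r}")
        vals = self.values.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def individuals(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


def validate_gene_annotation(genes: pd.DataFrame) -> pd.DataFrame:
    """Check a gene annotation table (index gene id; chrom, tss, strand)."""
    if not genes.index.is_unique:
        raise ValueError("duplicate gene ids")
    if (genes["tss"] < 1).any():
        raise ValueError("tss positions must be 1-based (>= 1)")
    return genes
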