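"""Genome-wide association of cell traits and disease-SNP enrichment.

Abundance scans adjust for gender, age and the top five genotype PCs;
proliferation scans additionally adjust for measured T_EM abundance.
Genomic-control lambda (median association chi-square over its null
median, 0.4549) diagnoses stratification-driven inflation.  Enrichment of
nominal associations among disease SNP-gene pairs uses the exact
one-tailed binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .regression import design_matrix, ols_dosage_scan

__all__ = [
    "ScanResult",
    "genome_scan",
    "lambda_gc",
    "binomial_enrichment",
    "qq_table",
    "GENOME_WIDE_P",
    "SUGGESTIVE_P",
]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 5e-5
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, df=1))   # 0.4549364...


@dataclass
class ScanResult:
    phenotype: str
    table: pd.DataFrame       # index snp; beta, se, p (sorted by p)
    covariate_columns: list[str]
    lambda_gc: float
    n_skipped: int = 0


def genome_scan(
    phenotype,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    name: str = "phenotype",
) -> ScanResult:
    """Per-SNP OLS of a cell trait on dosage plus covariates.

    Monomorphic SNPs are skipped (counted in ``n_skipped``); results are
    sorted by p-value and the genomic-control lambda is attached.
    """
    y = np.asarray(phenotype, dtype=float)
    X = design_matrix(covariates)
    D = genotypes.dosages.to_numpy(dtype=float)
    beta, se, _, p, _, _, _ = ols_dosage_scan(y, D, X)
    table = pd.DataFrame(
        {"beta": beta, "se": se, "p": p},
        index=genotypes.snps.index,
    )
    skipped = int(table["p"].isna().sum())
    table = table.dropna().sort_values("p", kind="mergesort")
    return ScanResult(
        phenotype=name,
        table=table,
        covariate_columns=list(covariates.columns),
        lambda_gc=lambda_gc(table["p"].to_numpy()),
        n_skipped=skipped,
    )


def lambda_gc(p_values) -> float:
    """Genomic-control lambda: median chi2(1) quantile of p over 0.4549."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / CHI2_NULL_MEDIAN)


def binomial_enrichment(n_pairs: int, n_nominal: int, alpha: float = 0.05):
    """Expected nominal count and exact upper-tail binomial p.

    Returns ``(expected, p)`` with expected = n_pairs * alpha and
    p = P(X >= n_nominal) for X ~ Binomial(n_pairs, alpha).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 <= n_nominal <= n_pairs:
        raise ValueError("n_nominal must be between 0 and n_pairs")
    expected = n_pairs * alpha
    p = float(stats.binom.sf(n_nominal - 1, n_pairs, alpha))
    return expected, p


def qq_table(p_values, ci: float = 0.95) -> pd.DataFrame:
    """Observed vs expected -log10 p with an order-statistics Beta band.

    The i-th smallest of n uniform p-values is Beta(i, n - i + 1); the
    band is its central ``ci`` interval.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    i = np.arange(1, n + 1)
    lo = stats.beta.ppf((1 - ci) / 2, i, n - i + 1)
    hi = stats.beta.ppf(1 - (1 - ci) / 2, i, n - i + 1)
    return pd.DataFrame(
        {
            "expected": -np.log10(i / (n + 1)),
            "observed": -np.log10(p),
            "band_lo": -np.log10(hi),
            "band_hi": -np.log10(lo),
        }
    )
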