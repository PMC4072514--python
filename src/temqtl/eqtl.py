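"""Cis-eQTL mapping with permutation empirical p-values.

Per gene and cell state, expression is regressed on allelic dosage with
gender and the top five genotype principal components as covariates:

    expression = b0 + b1*dosage + b2*PC1 + ... + b6*PC5 + b7*gender

Multiple testing within a gene region is handled by permuting the
covariate-residual expression values (10,000 permutations by default,
one shared permutation stream across the region's SNPs) and reporting,
per SNP, the proportion of permutations whose p-value is at least as
small as the observed analytic p, with add-one smoothing.  Per-gene lead
associations are then controlled at FDR 5% by Benjamini-Hochberg across
genes within each state.  Conditional analysis re-runs the scan with a
candidate (disease) SNP's dosage as an additional covariate; a region is
"fully explained" when no residual SNP reaches permutation p < 0.05.
Cross-state effect differences are tested with a normal z-statistic on
the two states' estimates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix
from .regression import design_matrix, ols_dosage_scan, residualize, single_ols

__all__ = [
    "GeneScanResult",
    "StateComparison",
    "ConditionalResult",
    "genotype_qc_filter",
    "compute_genotype_pcs",
    "cis_window_snps",
    "fit_snp_association",
    "scan_gene_cis",
    "fdr_select",
    "conditional_scan",
    "state_difference_test",
    "beta_to_fold",
    "ld_r2",
    "define_disease_locus",
]

DEFAULT_CIS_WINDOW = 250_000
COVARIATE_COLUMNS = ["PC1", "PC2", "PC3", "PC4", "PC5", "gender"]


@dataclass
class GeneScanResult:
    gene: str
    state: str
    table: pd.DataFrame        # index snp; beta, se, analytic_p, empirical_p, fold, n
    lead_snp: str
    n_perm: int

    @property
    def lead(self) -> pd.Series:
        return self.table.loc[self.lead_snp]


@dataclass
class StateComparison:
    gene: str
    snp: str
    z: float
    p_delta: float


@dataclass
class ConditionalResult:
    gene: str
    condition_snp: str
    residual: GeneScanResult
    fully_explained: bool


def genotype_qc_filter(
    genotypes: GenotypeMatrix,
    min_maf: float = 0.01,
    min_imputation_r2: float = 0.4,
) -> GenotypeMatrix:
    """Drop SNPs with MAF < ``min_maf`` or imputation quality < ``min_r2``.

    Both filters are strict: a SNP sitting exactly at a threshold is kept.
    SNPs lacking a quality score pass the quality filter.
    """
    meta = genotypes.snps
    keep = meta["maf"] >= min_maf
    if "r2" in meta.columns:
        keep &= meta["r2"].fillna(1.0) >= min_imputation_r2
    if not keep.any():
        raise ValueError("all SNPs removed by QC filters")
    return genotypes.subset_snps(meta.index[keep])


def compute_genotype_pcs(genotypes: GenotypeMatrix, k: int = 5):
    """Top-k genotype principal components, EIGENSTRAT-normalized.

    Dosages are centered and scaled by sqrt(2p(1-p)) per SNP (monomorphic
    SNPs dropped), and the leading eigenvectors of the individual-by-
    individual covariance are returned with the sign convention that the
    largest-magnitude entry of each PC is positive.  Returns
    ``(DataFrame PC1..PCk, variance fractions)``.
    """
    n = genotypes.n_individuals
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} individuals for {k} PCs")
    G = genotypes.dosages.to_numpy(dtype=float)
    p = G.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < k:
        raise ValueError("too few polymorphic SNPs")
    G = G[:, poly]
    p = p[poly]
    Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
    Z = Z - Z.mean(axis=0)
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    var = S ** 2
    frac = var / var.sum()
    pcs = U[:, :k] * S[:k]
    for j in range(k):
        if pcs[np.abs(pcs[:, j]).argmax(), j] < 0:
            pcs[:, j] = -pcs[:, j]
    cols = [f"PC{j + 1}" for j in range(k)]
    return (
        pd.DataFrame(pcs, index=genotypes.individuals, columns=cols),
        frac[:k],
    )


def cis_window_snps(
    gene: pd.Series,
    genotypes: GenotypeMatrix,
    half_window: int = DEFAULT_CIS_WINDOW,
) -> list[str]:
    """SNP ids within [tss - w, tss + w] (inclusive) on the gene's chromosome."""
    meta = genotypes.snps
    sel = (
        (meta["chrom"] == gene["chrom"])
        & (meta["pos"] >= gene["tss"] - half_window)
        & (meta["pos"] <= gene["tss"] + half_window)
    )
    sub = meta.loc[sel].sort_values("pos")
    return list(sub.index)


def fit_snp_association(expression, dosage, covariates):
    """OLS of one gene's expression on one SNP's dosage plus covariates.

    Returns ``(beta, se, analytic_p, residuals)`` where the two-tailed t
    test on the dosage effect uses the full-model residual df.
    """
    y = np.asarray(expression, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if len(y) < 10:
        raise ValueError("fewer than 10 complete cases")
    X = design_matrix(covariates)
    return single_ols(y, d, X)


def _gene_rng(gene: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(gene.encode()) % (2**31)])


def scan_gene_cis(
    gene: str,
    annotation: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression,
    covariates: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    half_window: int = DEFAULT_CIS_WINDOW,
    region_min: bool = True,
    state: str = "rest",
) -> GeneScanResult | None:
    """Scan all cis SNPs of ``gene`` with permutation empirical p-values.

    Expression and dosages are residualized on the covariates once; the
    analytic p per SNP equals the full-model t-test by Frisch-Waugh.  One
    permutation stream (derived from the master seed and the gene id, so
    parallel and serial runs agree) is shared across SNPs.

    By default (``region_min=True``) each SNP's observed statistic is
    compared against the permutation distribution of the region-wide best
    statistic, which adjusts for the number of correlated SNPs in the
    window: the lead SNP's empirical p is then uniform under the regional
    null.  ``region_min=False`` compares each SNP against its own
    permutation distribution (no within-region adjustment).

    Returns ``None`` when the cis window holds no polymorphic SNP.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives too coarse a permutation resolution")
    snp_ids = cis_window_snps(annotation.loc[gene], genotypes, half_window)
    if not snp_ids:
        return None
    y = np.asarray(expression[gene] if hasattr(expression, "columns") else expression,
                   dtype=float)
    D = genotypes.dosages[snp_ids].to_numpy(dtype=float)
    X = design_matrix(covariates)
    beta, se, t, p, df, e, Dr = ols_dosage_scan(y, D, X)
    ok = ~np.isnan(beta)
    if not ok.any():
        return None

    # permutations on standardized residuals: |r| ordering == p ordering at fixed df
    sd_e = e.std(ddof=0)
    ez = (e - e.mean()) / (sd_e if sd_e > 0 else 1.0)
    Dn = Dr[:, ok]
    Dn = Dn / np.sqrt(np.einsum("ij,ij->j", Dn, Dn))
    r_obs = np.abs(ez @ Dn) / np.sqrt(len(ez))
    rng = _gene_rng(gene, seed)
    n = len(ez)
    exceed = np.zeros(ok.sum())
    block = 500
    for start in range(0, n_perm, block):
        b = min(block, n_perm - start)
        P = np.stack([rng.permutation(n) for _ in range(b)])
        R = np.abs((ez[P] @ Dn)) / np.sqrt(n)
        if region_min:
            exceed += (R.max(axis=1)[:, None] >= r_obs[None, :] - 1e-15).sum(axis=0)
        else:
            exceed += (R >= r_obs[None, :] - 1e-15).sum(axis=0)
    emp = np.full(len(snp_ids), np.nan)
    emp[ok] = (1.0 + exceed) / (n_perm + 1.0)

    table = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "analytic_p": p,
            "empirical_p": emp,
            "fold": np.exp(beta),
            "n": len(y),
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    cand = table.loc[ok]
    pos = genotypes.snps.loc[cand.index, "pos"]
    order = cand.assign(pos=pos).sort_values(
        ["empirical_p", "analytic_p", "pos"], kind="mergesort"
    )
    return GeneScanResult(
        gene=gene, state=state, table=table, lead_snp=order.index[0], n_perm=n_perm
    )


def fdr_select(lead_results: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg over per-gene lead empirical p-values within a state.

    ``lead_results`` must carry an ``empirical_p`` column indexed by gene;
    returns a copy with ``fdr_q`` and a boolean ``significant`` column.
    """
    out = lead_results.copy()
    rej, qv, _, _ = multipletests(out["empirical_p"].to_numpy(), alpha=q,
                                  method="fdr_bh")
    out["fdr_q"] = qv
    out["significant"] = qv <= q
    return out


def conditional_scan(
    gene: str,
    condition_snp: str,
    annotation: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression,
    covariates: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    half_window: int = DEFAULT_CIS_WINDOW,
    alpha: float = 0.05,
    state: str = "rest",
) -> ConditionalResult:
    """Re-scan the region with the condition SNP's dosage as a covariate."""
    if condition_snp not in genotypes.snps.index:
        raise KeyError(f"condition SNP {condition_snp!r} not in panel")
    cov = covariates.copy()
    cov["_condition_dosage"] = genotypes.dosages[condition_snp].to_numpy()
    res = scan_gene_cis(
        gene, annotation, genotypes, expression, cov,
        n_perm=n_perm, seed=seed, half_window=half_window, state=state,
    )
    tab = res.table.drop(index=condition_snp, errors="ignore")
    # r^2=1 proxies of the condition SNP carry no residual information;
    # their dosage residualizes to ~0 and the scan marks them NaN
    res = GeneScanResult(gene=res.gene, state=res.state, table=tab,
                         lead_snp=tab["empirical_p"].idxmin(), n_perm=n_perm) \
        if tab["empirical_p"].notna().any() else res
    residual_p = tab["empirical_p"].dropna()
    fully = bool((residual_p >= alpha).all()) if len(residual_p) else True
    return ConditionalResult(
        gene=gene, condition_snp=condition_snp, residual=res, fully_explained=fully
    )


def state_difference_test(beta_rest, se_rest, beta_stim, se_stim,
                          gene: str = "", snp: str = "") -> StateComparison:
    """z-test for a cross-state effect-size difference.

    z = (beta_stim - beta_rest) / sqrt(se_rest^2 + se_stim^2), two-tailed
    standard-normal p; the two states are treated as independent samples.
    """
    if se_rest <= 0 or se_stim <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_stim - beta_rest) / np.hypot(se_rest, se_stim)
    p = 2.0 * stats.norm.sf(abs(z))
    return StateComparison(gene=gene, snp=snp, z=float(z), p_delta=float(max(p, np.finfo(float).tiny)))


def beta_to_fold(beta: float) -> float:
    """Per-allele fold change: exp(beta) on the natural-log expression scale."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(np.exp(beta))


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of dosage vectors (composite LD)."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ValueError("LD undefined for a monomorphic SNP")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def define_disease_locus(
    lead_snp: str,
    genotypes: GenotypeMatrix,
    hotspots,
    genes: pd.DataFrame | None = None,
    ld_threshold: float = 0.5,
    pad: int = 250_000,
) -> tuple[int, int]:
    """Locus interval around a lead SNP: LD span, then flanking hotspots.

    The interval spans the furthest same-chromosome partners with
    r^2 > ``ld_threshold`` in each direction, extended outward to the
    nearest recombination hotspot on each side; if no gene TSS overlaps
    the result (when ``genes`` is given), it is extended a further
    ``pad`` bp each side.  ``hotspots`` is a sorted sequence of positions
    on the lead SNP's chromosome.
    """
    if lead_snp not in genotypes.snps.index:
        raise KeyError(f"lead SNP {lead_snp!r} not in panel")
    meta = genotypes.snps
    chrom = meta.loc[lead_snp, "chrom"]
    pos0 = int(meta.loc[lead_snp, "pos"])
    a = genotypes.dosages[lead_snp].to_numpy()
    lo = hi = pos0
    for snp in meta.index[meta["chrom"] == chrom]:
        if snp == lead_snp:
            continue
        b = genotypes.dosages[snp].to_numpy()
        if b.std(ddof=0) == 0:
            continue
        if ld_r2(a, b) > ld_threshold:
            p = int(meta.loc[snp, "pos"])
            lo, hi = min(lo, p), max(hi, p)
    hs = np.asarray(sorted(hotspots), dtype=int)
    left = hs[hs <= lo]
    right = hs[hs >= hi]
    lo = int(left[-1]) if len(left) else lo
    hi = int(right[0]) if len(right) else hi
    if genes is not None:
        sub = genes[(genes["chrom"] == chrom) & genes["tss"].between(lo, hi)]
        if sub.empty:
            lo, hi = lo - pad, hi + pad
    return max(lo, 1), hi
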