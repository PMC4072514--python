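"""Synthetic cohort generator.

Emulates the data layers of an immunoprofiling cohort of healthy adults:
structured diploid genotypes with local LD, paired resting/stimulated
log-scale expression with planted (possibly state-specific) cis-eQTLs,
CFSE dye-dilution event data, 7-population 3-marker flow cytometry events,
and cell-level phenotypes (CD4+ T_EM abundance, division and proliferation
indices) with known age, gender and abundance effects.  Every generator is
seeded and returns ground truth alongside the data so downstream stages
can be tested for parameter recovery.

Population structure follows the Balding–Nichols model: subpopulation
allele frequencies are drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) around an
ancestral frequency p, which yields PCA-detectable stratification at
modest F.  LD within a block arises from a first-order copying process on
haplotypes, giving pairwise r^2 decaying geometrically with SNP distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix
from .flow import FlowSample, PopulationTemplate

__all__ = [
    "SimCohortConfig",
    "CohortTruth",
    "SimCohort",
    "CfseWellSet",
    "simulate_genotypes",
    "simulate_expression_pair",
    "simulate_cfse_experiment",
    "simulate_flow_sample",
    "simulate_cohort",
    "simulate_second_visit",
    "default_population_template",
    "division_weights_from_di",
]

LOG10_2 = float(np.log10(2.0))

# salts for deriving independent per-stage rng streams from the master seed
_SALT = {"geno": 11, "expr": 23, "cfse": 37, "flow": 41, "pheno": 53}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _SALT[stage]])


@dataclass
class SimCohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort the pipeline is designed for: 174 European-
    descent adults aged 19-57 (134/225 female), T_EM abundance mean 9.57%
    (SD 4.85%) rising 0.11%/year and 2.22% higher in men, division index
    1.46 (SD 0.35) and proliferation index 2.16 (SD 0.21), 215 assayed
    genes of which ~22% carry a cis-eQTL, most active only after TCR
    stimulation.
    """

    n_individuals: int = 174
    n_snps: int = 2000
    n_genes: int = 215
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 2
    fst: float = 0.01
    ld_block_size: int = 10
    ld_rho: float = 0.9
    snp_spacing: int = 10_000
    cis_window: int = 250_000
    eqtl_fraction: float = 46 / 205
    state_specific_fraction: float = 32 / 46
    stim_only_fraction: float = 29 / 32   # of state-specific eQTLs
    effect_sd: float = 0.6
    noise_sd: float = 1.0
    gamma_gender: float = 0.1
    gamma_pc: float = 0.1
    age_range: tuple[float, float] = (19.0, 57.0)
    female_frac: float = 134 / 225
    age_slope: float = 0.11        # % abundance per year
    gender_diff: float = 2.22      # % abundance, male - female
    abundance_mean: float = 9.57
    abundance_sd: float = 4.85
    di_mean: float = 1.46
    di_sd: float = 0.35
    pi_mean: float = 2.16
    pi_sd: float = 0.21
    signature_size: int = 17
    signature_n_pos: int = 2
    signature_loading: float = 1.0   # factor loading of signature genes, log-units
    signature_r: float = 0.55        # target corr(signature score, DI)
    abundance_di_r: float = -0.24
    di_pi_r: float = 0.7
    cfse: tuple[float, float, float, int] = (2.5, LOG10_2, 0.1, 5000)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError(f"maf_range must be ordered within (0, 0.5): {self.maf_range}")
        for name in ("effect_sd", "noise_sd", "abundance_sd", "di_sd", "pi_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("eqtl_fraction", "state_specific_fraction", "stim_only_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")


@dataclass
class CohortTruth:
    """Ground truth bookkeeping for parameter-recovery tests."""

    eqtl_map: pd.DataFrame            # index gene; causal_snp, beta_rest, beta_stim
    gene_annotation: pd.DataFrame     # index gene; chrom, tss, strand
    signature_genes: pd.DataFrame | None = None  # index gene; sign (+1/-1)
    subpop_labels: pd.Series | None = None
    covariates: pd.DataFrame | None = None
    phenotypes: pd.DataFrame | None = None
    latent_factor: pd.Series | None = None       # proliferation propensity u

    def __post_init__(self):
        missing = set(self.eqtl_map.index) - set(self.gene_annotation.index)
        if missing:
            raise ValueError(f"eqtl_map genes absent from annotation: {sorted(missing)}")
        betas = self.eqtl_map[["beta_rest", "beta_stim"]].to_numpy()
        if betas.size and not np.isfinite(betas).all():
            raise ValueError("non-finite planted effect sizes")


@dataclass
class CfseWellSet:
    """Pooled resting events plus replicate stimulated wells (log10 CFSE)."""

    resting: np.ndarray
    stimulated: list[np.ndarray]
    true_weights: np.ndarray | None = None

    @property
    def empty_wells(self) -> list[int]:
        return [i for i, w in enumerate(self.stimulated) if len(w) == 0]


@dataclass
class SimCohort:
    genotypes: GenotypeMatrix
    expr_rest: ExpressionMatrix
    expr_stim: ExpressionMatrix
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: CohortTruth


def _individual_ids(n: int) -> pd.Index:
    return pd.Index([f"I{i:04d}" for i in range(n)], name="individual")


def simulate_genotypes(config: SimCohortConfig) -> GenotypeMatrix:
    """Draw structured hard-call genotypes with blockwise LD.

    Each LD block shares an ancestral allele frequency; subpopulation
    frequencies follow Balding–Nichols around it.  Haplotypes within a
    block copy the previous SNP's allele with probability ``ld_rho`` and
    redraw otherwise, so adjacent-SNP correlation is ~rho and r^2 decays
    with distance.
    """
    rng = _rng(config.seed, "geno")
    n, m = config.n_individuals, config.n_snps
    k = config.n_subpops
    F = config.fst
    lo, hi = config.maf_range

    subpop = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    n_blocks = int(np.ceil(m / config.ld_block_size))
    anc = rng.uniform(lo, hi, size=n_blocks)
    if F > 0:
        a = anc * (1 - F) / F
        b = (1 - anc) * (1 - F) / F
        pop_freq = rng.beta(a[:, None], b[:, None], size=(n_blocks, k))
    else:
        pop_freq = np.repeat(anc[:, None], k, axis=1)
    pop_freq = np.clip(pop_freq, 1e-4, 1 - 1e-4)

    haps = np.empty((2 * n, m), dtype=np.int8)
    hap_pop = np.repeat(subpop, 2)
    for blk in range(n_blocks):
        j0 = blk * config.ld_block_size
        j1 = min(j0 + config.ld_block_size, m)
        p = pop_freq[blk, hap_pop]          # per-haplotype block frequency
        fresh = (rng.random((2 * n, j1 - j0)) < p[:, None]).astype(np.int8)
        block = fresh.copy()
        copy = rng.random((2 * n, j1 - j0)) < config.ld_rho
        for j in range(1, j1 - j0):
            block[:, j] = np.where(copy[:, j], block[:, j - 1], fresh[:, j])
        haps[:, j0:j1] = block
    dosage = haps[0::2] + haps[1::2]

    snp_ids = [f"snp{j:05d}" for j in range(m)]
    pos = (np.arange(m) + 1) * config.snp_spacing
    freq = dosage.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    snps = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "maf": maf,
            "r2": 1.0,
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    ids = _individual_ids(n)
    return GenotypeMatrix(
        pd.DataFrame(dosage.astype(float), index=ids, columns=snp_ids),
        snps,
        subpop=pd.Series(subpop, index=ids, name="subpop"),
    )


def _make_gene_annotation(genotypes: GenotypeMatrix, config: SimCohortConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    pos = genotypes.snps["pos"].to_numpy()
    tss = rng.choice(pos, size=config.n_genes, replace=True)
    return pd.DataFrame(
        {
            "chrom": "1",
            "tss": np.sort(tss),
            "strand": rng.choice(["+", "-"], size=config.n_genes),
        },
        index=pd.Index([f"gene{g:04d}" for g in range(config.n_genes)], name="gene"),
    )


def simulate_expression_pair(
    genotypes: GenotypeMatrix,
    config: SimCohortConfig,
    covariates: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, CohortTruth]:
    """Generate paired resting/stimulated expression with planted cis-eQTLs.

    Per gene and state: y = mu_g + beta_state * dosage(causal SNP)
    + gamma_gender * gender + sum_k gamma_k * PC_k + N(0, noise_sd^2),
    on the natural-log scale.  Planted causal SNPs lie within the cis
    window of the gene's TSS.  A fraction of planted eQTLs is active in
    exactly one state (mostly stimulated-only, as in activated T cells).
    """
    from .eqtl import compute_genotype_pcs

    rng = _rng(config.seed, "expr")
    n = genotypes.n_individuals
    if covariates is None:
        gender = (rng.random(n) >= config.female_frac).astype(float)  # 1 = male
        pcs, _ = compute_genotype_pcs(genotypes, k=min(5, n - 2))
        covariates = pcs.copy()
        covariates.insert(0, "gender", gender)
    pc_cols = [c for c in covariates.columns if c.startswith("PC")]

    annot = _make_gene_annotation(genotypes, config, rng)
    n_eqtl = int(round(config.eqtl_fraction * config.n_genes))
    eqtl_genes = rng.choice(annot.index.to_numpy(), size=n_eqtl, replace=False)

    snp_pos = genotypes.snps["pos"].to_numpy()
    snp_maf = genotypes.snps["maf"].to_numpy()
    snp_ids = genotypes.snps.index.to_numpy()

    rows = []
    for g in eqtl_genes:
        tss = annot.loc[g, "tss"]
        in_cis = (snp_pos >= tss - config.cis_window) & (snp_pos <= tss + config.cis_window)
        usable = in_cis & (snp_maf >= 0.1)
        if not usable.any():
            usable = in_cis & (snp_maf > 0)
        if not usable.any():
            raise ValueError(f"no SNP within the cis window of {g}; cannot plant eQTL")
        causal = rng.choice(snp_ids[usable])
        beta = rng.normal(0.0, config.effect_sd)
        if abs(beta) < 0.2 * config.effect_sd:      # keep planted effects non-trivial
            beta = np.sign(beta or 1.0) * 0.2 * config.effect_sd
        if rng.random() < config.state_specific_fraction:
            if rng.random() < config.stim_only_fraction:
                b_rest, b_stim = 0.0, beta
            else:
                b_rest, b_stim = beta, 0.0
        else:
            b_rest = b_stim = beta
        rows.append((g, causal, b_rest, b_stim))
    eqtl_map = pd.DataFrame(
        rows, columns=["gene", "causal_snp", "beta_rest", "beta_stim"]
    ).set_index("gene")

    mu = rng.normal(5.0, 1.0, size=config.n_genes)
    stim_shift = rng.normal(0.0, 0.8, size=config.n_genes)
    gender_v = covariates["gender"].to_numpy(dtype=float)
    pcs_v = covariates[pc_cols].to_numpy(dtype=float) if pc_cols else np.zeros((n, 0))
    if pcs_v.shape[1]:
        pcs_v = (pcs_v - pcs_v.mean(axis=0)) / pcs_v.std(axis=0, ddof=0)
    covar_part = config.gamma_gender * gender_v + config.gamma_pc * pcs_v.sum(axis=1)

    ids = genotypes.individuals
    out = {}
    for state, shift in (("rest", 0.0), ("stim", 1.0)):
        Y = np.empty((n, config.n_genes))
        for gi, g in enumerate(annot.index):
            base = mu[gi] + shift * stim_shift[gi] + covar_part
            if g in eqtl_map.index:
                b = eqtl_map.loc[g, "beta_rest" if state == "rest" else "beta_stim"]
                dos = genotypes.dosages[eqtl_map.loc[g, "causal_snp"]].to_numpy()
                base = base + b * dos
            Y[:, gi] = base + rng.normal(0.0, config.noise_sd, size=n)
        out[state] = ExpressionMatrix(
            pd.DataFrame(Y, index=ids, columns=annot.index), state=state
        )

    truth = CohortTruth(
        eqtl_map=eqtl_map,
        gene_annotation=annot,
        subpop_labels=genotypes.subpop,
        covariates=covariates,
    )
    return out["rest"], out["stim"], truth


def simulate_cfse_experiment(
    weights,
    config: SimCohortConfig,
    n_wells: int = 2,
    n_events: int | None = None,
    seed: int | None = None,
) -> CfseWellSet:
    """Simulate a CFSE dilution assay.

    Resting events come from a single Gaussian N(mu0, sigma^2); stimulated
    events from a mixture whose k-th component sits at mu0 - k * spacing
    with shared sigma (CFSE halves per division, so peaks are equally
    spaced on the log10 scale).
    """
    w = np.asarray(weights, dtype=float)
    if len(w) > 6:
        raise ValueError("at most 6 division components (5 divisions)")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    mu0, spacing, sigma, default_events = config.cfse
    n_ev = default_events if n_events is None else int(n_events)
    rng = _rng(config.seed if seed is None else seed, "cfse")

    resting = rng.normal(mu0, sigma, size=n_ev)
    wells = []
    for _ in range(n_wells):
        if n_ev == 0:
            wells.append(np.empty(0))
            continue
        comp = rng.choice(len(w), size=n_ev, p=w)
        wells.append(rng.normal(mu0 - comp * spacing, sigma))
    return CfseWellSet(resting=resting, stimulated=wells, true_weights=w)


def default_population_template(tem_frac: float = 9.57 / 100.0,
                                debris_frac: float = 0.10) -> PopulationTemplate:
    """Seven-population template on (CD45RA, CD45RO, CD62L) log10 intensities.

    The T_EM component (CD45RA-, CD45RO+, CD62L low) carries ``tem_frac``
    of the non-debris mass by default.
    """
    means = np.array(
        [
            [3.5, 1.5, 3.5],   # naive: RA+ RO- L+
            [1.5, 3.5, 3.5],   # central memory: RA- RO+ L+
            [1.5, 3.5, 1.6],   # effector memory: RA- RO+ L low
            [3.5, 1.5, 1.5],   # TEMRA: RA+ RO- L-
            [2.2, 3.0, 2.6],   # activated/transitional
            [2.9, 2.5, 2.1],   # other lymphocytes
            [0.9, 0.9, 0.9],   # debris: all-negative
        ]
    )
    base_cov = np.array(
        [[0.07, 0.01, 0.0], [0.01, 0.07, 0.0], [0.0, 0.0, 0.09]]
    )
    covs = np.stack([base_cov] * 7)
    covs[6] = np.diag([0.12, 0.12, 0.12])
    live = 1.0 - debris_frac
    tem_w = tem_frac * live
    rest = live - tem_w
    weights = np.array([0.38, 0.26, 0.0, 0.12, 0.14, 0.10, 0.0])
    weights = weights / weights.sum() * rest
    weights[2] = tem_w
    weights[6] = debris_frac
    labels = ["naive", "TCM", "TEM", "TEMRA", "activated", "other", "debris"]
    return PopulationTemplate(means=means, covariances=covs,
                              weights=weights, labels=labels)


def simulate_flow_sample(
    template: PopulationTemplate,
    weights,
    n_events: int,
    seed: int,
) -> FlowSample:
    """Draw flow events from the template mixture, retaining true labels."""
    w = np.asarray(weights, dtype=float)
    if len(w) != 7:
        raise ValueError("weights must have length 7")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    template.validate()
    rng = _rng(seed, "flow")
    comp = rng.choice(7, size=n_events, p=w)
    chol = np.linalg.cholesky(template.covariances)
    z = rng.standard_normal((n_events, 3))
    events = template.means[comp] + np.einsum("nij,nj->ni", chol[comp], z)
    return FlowSample(events=events, transform="log10", true_labels=comp)


def division_weights_from_di(di: float, max_divisions: int = 5) -> np.ndarray:
    """Division-count weights with mean ``di``: truncated Poisson over 0..5."""
    if di < 0:
        raise ValueError("division index must be >= 0")
    k = np.arange(max_divisions + 1)
    if di < 1e-9:
        w = np.zeros(max_divisions + 1)
        w[0] = 1.0
        return w
    # solve for the Poisson rate whose truncated mean matches di
    from scipy.optimize import brentq

    def trunc_mean(lam):
        logw = k * np.log(lam) - lam - np.array([float(np.sum(np.log(np.arange(1, kk + 1)))) for kk in k])
        w = np.exp(logw - logw.max())
        w /= w.sum()
        return float((k * w).sum())

    hi = 50.0
    lam = brentq(lambda l: trunc_mean(l) - min(di, max_divisions - 1e-6), 1e-9, hi)
    logw = k * np.log(lam) - lam - np.array([float(np.sum(np.log(np.arange(1, kk + 1)))) for kk in k])
    w = np.exp(logw - logw.max())
    return w / w.sum()


def _signature_latent_coef(config: SimCohortConfig, m_sig: int) -> float:
    # per-gene corr with u is loading/sqrt(loading^2+1); the +/-1 score's
    # corr with u follows from the equicorrelated factor structure, and the
    # latent-to-phenotype coefficient is set so corr(score, DI) hits the
    # configured signature_r
    load = config.signature_loading / np.hypot(config.signature_loading, 1.0)
    score_u_corr = m_sig * load / np.sqrt(m_sig + m_sig * (m_sig - 1) * load ** 2)
    return float(np.clip(config.signature_r / score_u_corr, -0.99, 0.99))


def simulate_second_visit(
    cohort: "SimCohort",
    config: SimCohortConfig,
    individuals=None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Re-assay a subset of the cohort at a later visit.

    The latent proliferation propensity u and the measured abundance are
    treated as stable individual traits; gene-expression and CFSE assay
    noise are redrawn.  Returns the visit-2 baseline expression and
    proliferation index.  eQTL effects are not re-applied (the re-assay
    emulates the signature-replication design, not a second eQTL scan).
    """
    truth = cohort.truth
    if truth.latent_factor is None:
        raise ValueError("cohort carries no latent factor; run simulate_cohort")
    ids = cohort.expr_rest.individuals if individuals is None else pd.Index(individuals)
    rng = np.random.default_rng([int(seed) % (2**31), 67])
    E1 = cohort.expr_rest.values.loc[ids]
    u = truth.latent_factor.loc[ids].to_numpy()
    lam = config.signature_loading * config.noise_sd

    E2 = pd.DataFrame(index=ids, columns=E1.columns, dtype=float)
    sig = truth.signature_genes
    for g in E1.columns:
        mu_g = cohort.expr_rest.values[g].mean()
        var_g = cohort.expr_rest.values[g].var(ddof=0)
        if g in sig.index:
            s = sig.loc[g, "sign"]
            resid_sd = np.sqrt(max(var_g - lam ** 2, 0.05))
            E2[g] = mu_g + s * lam * u + rng.normal(0, resid_sd, len(ids))
        else:
            E2[g] = mu_g + rng.normal(0, np.sqrt(max(var_g, 0.05)), len(ids))

    ab = cohort.phenotypes["abundance"]
    ab_z = ((ab - ab.mean()) / ab.std(ddof=0)).loc[ids].to_numpy()
    r_u = _signature_latent_coef(config, len(sig))
    r_ab = config.abundance_di_r
    resid = max(1.0 - r_u ** 2 - r_ab ** 2, 0.0)
    pi2 = config.pi_mean + config.pi_sd * (
        r_u * u + r_ab * ab_z + np.sqrt(resid) * rng.standard_normal(len(ids)))
    pi2 = pd.Series(np.maximum(pi2, 1.0), index=ids, name="pi")
    return ExpressionMatrix(E2, state="rest"), pi2


def simulate_cohort(config: SimCohortConfig) -> SimCohort:
    """Generate the full cohort bundle with consistent individual ids.

    Abundance (% of CD4 T cells) = mean + age_slope*(age - mean age)
    + gender_diff*male + noise, truncated to (0, 100).  The division index
    is driven by a signed combination of the planted signature genes'
    baseline expression plus a negative abundance term plus noise; the
    proliferation index co-varies with DI and never falls below it.
    """
    genotypes = simulate_genotypes(config)
    rng = _rng(config.seed, "pheno")
    n = config.n_individuals
    ids = genotypes.individuals

    age = rng.uniform(*config.age_range, size=n)
    male = (rng.random(n) >= config.female_frac).astype(float)

    from .eqtl import compute_genotype_pcs

    pcs, _ = compute_genotype_pcs(genotypes, k=min(5, n - 2, genotypes.n_snps))
    covariates = pcs.copy()
    covariates.insert(0, "gender", male)
    covariates.insert(0, "age", age)

    expr_rest, expr_stim, truth = simulate_expression_pair(
        genotypes, config, covariates=covariates
    )

    # abundance with planted age and gender effects
    explained = (config.age_slope ** 2) * np.var(age) + \
        (config.gender_diff ** 2) * np.var(male)
    resid_sd = np.sqrt(max(config.abundance_sd ** 2 - explained, 0.25))
    abundance = (
        config.abundance_mean
        + config.age_slope * (age - age.mean())
        + config.gender_diff * (male - male.mean())
        + rng.normal(0.0, resid_sd, size=n)
    )
    abundance = np.clip(abundance, 0.05, 99.95)

    # Proliferation-potential signature.  The signature genes share a latent
    # "proliferation propensity" factor u (they are co-regulated, as any set
    # of individually detectable predictor genes must be): the gene's signed
    # baseline expression loads on u, and the division index is driven by u.
    non_eqtl = truth.gene_annotation.index.difference(truth.eqtl_map.index)
    m_sig = min(config.signature_size, len(non_eqtl))
    if m_sig < 2:
        raise ValueError("too few non-eQTL genes to host the proliferation signature")
    sig_genes = rng.choice(non_eqtl.to_numpy(), size=m_sig, replace=False)
    signs = np.full(m_sig, -1.0)
    signs[: min(config.signature_n_pos, m_sig - 1)] = 1.0
    rng.shuffle(signs)
    u = rng.standard_normal(n)
    lam = config.signature_loading * config.noise_sd
    for s, g in zip(signs, sig_genes):
        expr_rest.values[g] += s * lam * u

    r_u = _signature_latent_coef(config, m_sig)

    # DI and PI both load on u (and negatively on abundance); their residual
    # noises are correlated, as for indices derived from the same CFSE fit
    ab_z = (abundance - abundance.mean()) / abundance.std(ddof=0)
    r_ab = config.abundance_di_r
    resid = max(1.0 - r_u ** 2 - r_ab ** 2, 0.0)
    e1 = rng.standard_normal(n)
    e2 = config.di_pi_r * e1 + np.sqrt(max(1 - config.di_pi_r ** 2, 0.0)) \
        * rng.standard_normal(n)
    di_z = r_u * u + r_ab * ab_z + np.sqrt(resid) * e1
    pi_z = r_u * u + r_ab * ab_z + np.sqrt(resid) * e2
    di = np.clip(config.di_mean + config.di_sd * di_z, 0.02, 5.0)
    pi = config.pi_mean + config.pi_sd * pi_z
    pi = np.maximum.reduce([pi, di + 1e-6, np.full(n, 1.0)])

    phenotypes = pd.DataFrame(
        {"age": age, "gender": male, "abundance": abundance, "di": di, "pi": pi},
        index=ids,
    )
    truth.signature_genes = pd.DataFrame(
        {"sign": signs}, index=pd.Index(sig_genes, name="gene")
    )
    truth.covariates = covariates
    truth.phenotypes = phenotypes
    truth.latent_factor = pd.Series(u, index=ids, name="latent")
    return SimCohort(
        genotypes=genotypes,
        expr_rest=expr_rest,
        expr_stim=expr_stim,
        covariates=covariates,
        phenotypes=phenotypes,
        truth=truth,
    )
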