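"""Proliferation-potential gene signature.

Baseline (resting) expression of each gene is correlated with the
proliferation index; two-tailed significance comes from permuting the
proliferation vector (one shared stream across genes).  Genes passing the
threshold form a +/-1-weighted signature (weight = sign of the training
correlation); an individual's score is the signed sum of the genes'
standardized expression.  The significant-gene count is calibrated
against a permutation null, and the signature is validated by split-half
cross-validation and by cross-visit replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneProlifCorr",
    "SignatureModel",
    "correlate_genes",
    "build_signature",
    "score_individuals",
    "null_gene_count",
    "split_half_validate",
    "cross_visit_replicate",
]


@dataclass
class SignatureModel:
    weights: pd.Series            # index gene; values +1 / -1
    threshold: float
    training_ids: list | None = None

    def __post_init__(self):
        if len(self.weights) and not set(np.unique(self.weights)).issubset({-1.0, 1.0}):
            raise ValueError("weights must be +1 or -1")

    @property
    def empty(self) -> bool:
        return len(self.weights) == 0


# a simple record-per-gene frame is more convenient than one object per gene
GeneProlifCorr = pd.DataFrame


def _expr_frame(expression) -> pd.DataFrame:
    return expression.values if hasattr(expression, "values") and not isinstance(
        expression, pd.DataFrame
    ) else expression


def _standardize(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, np.nan)
    return (M - M.mean(axis=0)) / sd


def correlate_genes(
    expression,
    proliferation,
    n_perm: int = 1000,
    seed: int = 0,
    min_individuals: int = 20,
) -> pd.DataFrame:
    """Pearson r of every gene vs proliferation with permutation p-values.

    permutation_p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1), two-tailed,
    with one shared permutation stream across genes.  Constant genes are
    skipped (reported with NaN r).
    """
    E = _expr_frame(expression)
    y = np.asarray(proliferation, dtype=float)
    if len(y) < min_individuals:
        raise ValueError(f"need at least {min_individuals} individuals")
    Z = _standardize(E.to_numpy(dtype=float))
    ok = ~np.isnan(Z).any(axis=0)
    yz = (y - y.mean()) / y.std(ddof=0)
    n = len(y)
    r_obs = np.full(E.shape[1], np.nan)
    r_obs[ok] = yz @ Z[:, ok] / n

    rng = np.random.default_rng(seed)
    exceed = np.zeros(int(ok.sum()))
    block = 250
    for start in range(0, n_perm, block):
        b = min(block, n_perm - start)
        P = np.stack([rng.permutation(n) for _ in range(b)])
        R = np.abs(yz[P] @ Z[:, ok]) / n
        exceed += (R >= np.abs(r_obs[ok])[None, :] - 1e-15).sum(axis=0)
    perm_p = np.full(E.shape[1], np.nan)
    perm_p[ok] = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame(
        {"pearson_r": r_obs, "permutation_p": perm_p, "n": n},
        index=E.columns.rename("gene"),
    )


def build_signature(corr: pd.DataFrame, threshold: float = 0.01) -> SignatureModel:
    """Retain genes with permutation p < threshold; weight = sign(r)."""
    sel = corr.dropna(subset=["pearson_r"])
    sel = sel[sel["permutation_p"] < threshold]
    weights = np.sign(sel["pearson_r"]).astype(float)
    return SignatureModel(weights=weights, threshold=threshold)


def score_individuals(model: SignatureModel, expression, proliferation=None):
    """Signed sum of standardized gene expression; optionally r vs proliferation.

    Returns ``(scores, r)`` where ``r`` is None without a proliferation
    vector.  Standardization is across the scored individuals.
    """
    if model.empty:
        raise ValueError("empty signature; nothing to score")
    E = _expr_frame(expression)
    missing = [g for g in model.weights.index if g not in E.columns]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    Z = _standardize(E[list(model.weights.index)].to_numpy(dtype=float))
    scores = pd.Series(Z @ model.weights.to_numpy(), index=E.index, name="score")
    r = None
    if proliferation is not None:
        r = float(np.corrcoef(scores.to_numpy(), np.asarray(proliferation, float))[0, 1])
    return scores, r


def null_gene_count(
    expression,
    proliferation,
    n_perm: int = 1000,
    threshold: float = 0.01,
    seed: int = 0,
    observed_count: int | None = None,
):
    """Null distribution of the significant-gene count under permutation.

    For each permutation of the proliferation vector, counts genes whose
    two-tailed (analytic t-based) correlation p falls below ``threshold``.
    Returns a dict with the counts, their median and max, and the add-one
    one-tailed p for ``observed_count`` (when given).
    """
    E = _expr_frame(expression)
    y = np.asarray(proliferation, dtype=float)
    Z = _standardize(E.to_numpy(dtype=float))
    ok = ~np.isnan(Z).any(axis=0)
    Z = Z[:, ok]
    n = len(y)
    yz = (y - y.mean()) / y.std(ddof=0)
    df = n - 2
    # two-tailed p < threshold  <=>  |r| above the matching t quantile
    t_crit = stats.t.isf(threshold / 2.0, df)
    r_crit = t_crit / np.sqrt(df + t_crit ** 2)

    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    block = 250
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        P = np.stack([rng.permutation(n) for _ in range(b)])
        R = np.abs(yz[P] @ Z) / n
        counts[done:done + b] = (R > r_crit).sum(axis=1)
        done += b
    out = {
        "counts": counts,
        "median": float(np.median(counts)),
        "max": int(counts.max()),
    }
    if observed_count is not None:
        out["p"] = float((1 + (counts >= observed_count).sum()) / (n_perm + 1))
    return out


def _one_tailed_perm_p(scores, y, r_obs, n_perm, rng):
    n = len(y)
    yz = (y - y.mean()) / y.std(ddof=0)
    sz = (scores - scores.mean()) / scores.std(ddof=0)
    P = np.stack([rng.permutation(n) for _ in range(n_perm)])
    r_perm = (yz[P] @ sz) / n
    return float((1 + (r_perm >= r_obs - 1e-15).sum()) / (n_perm + 1))


def split_half_validate(
    expression,
    proliferation,
    seed: int = 0,
    threshold: float = 0.01,
    n_perm: int = 1000,
):
    """Two-way cross-validation of the signature.

    The cohort is split at random into halves; a signature trained on one
    half is scored on the other, reporting held-out r and a one-tailed
    permutation p.  Both directions are returned as a list of per-fold
    dicts; a fold whose training signature is empty is flagged
    non-informative.
    """
    E = _expr_frame(expression)
    y = np.asarray(proliferation, dtype=float)
    n = len(y)
    if n < 40:
        raise ValueError("need at least 40 individuals for split-half validation")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = [perm[: n // 2], perm[n // 2:]]
    folds = []
    for train, test in (halves, halves[::-1]):
        corr = correlate_genes(E.iloc[train], y[train], n_perm=n_perm,
                               seed=int(rng.integers(2**31)))
        model = build_signature(corr, threshold=threshold)
        if model.empty:
            folds.append({"informative": False, "r": np.nan, "p": np.nan,
                          "signature": model})
            continue
        scores, r = score_individuals(model, E.iloc[test], y[test])
        p = _one_tailed_perm_p(scores.to_numpy(), y[test], r, n_perm, rng)
        folds.append({"informative": True, "r": r, "p": p, "signature": model})
    return folds


def cross_visit_replicate(
    expr_visit1,
    prolif_visit1,
    expr_visit2,
    prolif_visit2,
    threshold: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Train the signature on each visit, score the other, both directions.

    Returns ``(r_forward, p_forward, r_backward, p_backward)`` with
    one-tailed permutation p-values.  Requires >= 10 shared individuals.
    """
    E1full, E2full = _expr_frame(expr_visit1), _expr_frame(expr_visit2)
    shared = E1full.index.intersection(E2full.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared individuals across visits")
    y1 = pd.Series(np.asarray(prolif_visit1, float), index=E1full.index) \
        .loc[shared].to_numpy()
    y2 = pd.Series(np.asarray(prolif_visit2, float), index=E2full.index) \
        .loc[shared].to_numpy()
    E1, E2 = E1full.loc[shared], E2full.loc[shared]
    rng = np.random.default_rng(seed)

    out = []
    for (Ea, ya, Eb, yb) in ((E1, y1, E2, y2), (E2, y2, E1, y1)):
        corr = correlate_genes(Ea, ya, n_perm=n_perm, seed=int(rng.integers(2**31)))
        model = build_signature(corr, threshold=threshold)
        if model.empty:
            out.extend([np.nan, np.nan])
            continue
        scores, r = score_individuals(model, Eb, yb)
        out.extend([r, _one_tailed_perm_p(scores.to_numpy(), yb, r, n_perm, rng)])
    return tuple(out)
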