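"""Shared least-squares machinery for association scans.

Every association in the package is an ordinary least-squares fit of a
phenotype (expression level, abundance, division index) on allelic dosage
plus nuisance covariates.  The scans are vectorised over SNPs via the
Frisch–Waugh–Lovell decomposition: phenotype and dosages are residualised
on the covariate design once, and each per-SNP slope is then a simple
regression of residuals on residuals.  The t statistic is computed with
the full-model degrees of freedom, so the result is numerically identical
to refitting the full model per SNP.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "design_matrix",
    "residualize",
    "ols_dosage_scan",
    "single_ols",
]


def design_matrix(covariates, columns=None) -> np.ndarray:
    """Build an intercept-plus-covariates design from a DataFrame.

    Parameters
    ----------
    covariates : pandas.DataFrame or None
        Covariate table (one row per individual).  ``None`` yields an
        intercept-only design.
    columns : sequence of str, optional
        Subset of columns to use, in order.  Defaults to all columns.
    """
    if covariates is None:
        raise ValueError("covariates is None; pass an (n,0) frame or use n explicitly")
    cols = list(columns) if columns is not None else list(covariates.columns)
    n = len(covariates)
    X = np.ones((n, 1 + len(cols)))
    for j, c in enumerate(cols):
        v = np.asarray(covariates[c], dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"covariate {c!r} contains missing values")
        X[:, 1 + j] = v
    return X


def residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project out the column space of ``X`` from each column of ``Y``.

    Raises on a rank-deficient design, naming the offending columns.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by comparing ranks of leave-one-out designs
        bad = [
            j for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef


def ols_dosage_scan(y: np.ndarray, D: np.ndarray, X: np.ndarray):
    """Per-SNP OLS of ``y`` on each column of ``D``, adjusting for ``X``.

    Returns ``(beta, se, t, p, df, y_resid, D_resid)`` where the analytic
    two-tailed p uses ``df = n - X.shape[1] - 1`` (full-model residual df).
    Monomorphic columns (zero residual variance) yield NaN across the board.
    """
    y = np.asarray(y, dtype=float).ravel()
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if D.shape[0] != y.shape[0]:
        D = D.T
    n = y.shape[0]
    df = n - X.shape[1] - 1
    if df < 2:
        raise ValueError(f"too few residual degrees of freedom (df={df})")
    e = residualize(y[:, None], X)[:, 0]
    Dr = residualize(D, X)
    ss_d = np.einsum("ij,ij->j", Dr, Dr)
    ok = ss_d > 1e-12
    beta = np.full(D.shape[1], np.nan)
    se = np.full(D.shape[1], np.nan)
    t = np.full(D.shape[1], np.nan)
    beta[ok] = (e @ Dr[:, ok]) / ss_d[ok]
    resid_ss = e @ e - beta[ok] ** 2 * ss_d[ok]
    resid_ss = np.maximum(resid_ss, 0.0)
    sigma2 = resid_ss / df
    se[ok] = np.sqrt(np.maximum(sigma2 / ss_d[ok], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t[ok] = np.where(se[ok] > 0, beta[ok] / se[ok], np.inf * np.sign(beta[ok]))
    p = np.full(D.shape[1], np.nan)
    finite = ok & np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df)
    p[ok & ~np.isfinite(t)] = 0.0
    # analytic p of exactly zero would break downstream log-scale summaries
    p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
    return beta, se, t, p, df, e, Dr


def single_ols(y: np.ndarray, d: np.ndarray, X: np.ndarray):
    """Fit one phenotype-on-dosage regression; returns (beta, se, p, residuals).

    ``residuals`` are the full-model residuals (useful for permutations).
    """
    beta, se, _, p, _, e, Dr = ols_dosage_scan(y, d.reshape(-1, 1), X)
    if np.isnan(beta[0]):
        raise ValueError("zero dosage variance (monomorphic SNP)")
    resid = e - beta[0] * Dr[:, 0]
    return float(beta[0]), float(se[0]), float(p[0]), resid
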