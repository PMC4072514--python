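"""Template-guided flow cytometry gating.

CD4+ T_EM abundance is quantified by fitting a seven-component
multivariate Gaussian mixture to (CD45RA, CD45RO, CD62L) intensities,
initialized at a labelled population template.  After EM, each fitted
component is relabelled by the nearest template component (Mahalanobis
distance between means under the template covariance), and T_EM abundance
is the posterior mass of the TEM component as a percentage of all
non-debris mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal

__all__ = [
    "FlowSample",
    "PopulationTemplate",
    "PopulationFit",
    "fit_population_model",
    "quantify_tem_abundance",
]

_COV_DET_FLOOR = 1e-12
_MIN_EVENTS_PER_COMPONENT = 50


@dataclass
class FlowSample:
    """Events x 3 matrix of transformed intensities (CD45RA, CD45RO, CD62L)."""

    events: np.ndarray
    transform: str = "log10"
    true_labels: np.ndarray | None = None

    def __post_init__(self):
        self.events = np.atleast_2d(np.asarray(self.events, dtype=float))
        if self.events.size and self.events.shape[1] != 3:
            raise ValueError("events must have 3 columns (CD45RA, CD45RO, CD62L)")
        if self.events.size and not np.isfinite(self.events).all():
            raise ValueError("non-finite event intensities")
        if self.transform not in ("log10", "arcsinh"):
            raise ValueError("transform must be 'log10' or 'arcsinh'")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]


@dataclass
class PopulationTemplate:
    """Seven labelled Gaussian components, exactly one TEM and one debris."""

    means: np.ndarray          # (7, 3)
    covariances: np.ndarray    # (7, 3, 3)
    weights: np.ndarray        # (7,)
    labels: list[str]

    def validate(self) -> "PopulationTemplate":
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.means.shape != (7, 3) or self.covariances.shape != (7, 3, 3):
            raise ValueError("template must have exactly 7 three-dimensional components")
        if len(self.labels) != 7:
            raise ValueError("template must carry 7 labels")
        if self.labels.count("TEM") != 1 or self.labels.count("debris") != 1:
            raise ValueError("labels must include exactly one 'TEM' and one 'debris'")
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be nonnegative and sum to 1")
        for k in range(7):
            C = self.covariances[k]
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError(f"component {k} covariance not symmetric")
            if np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError(f"component {k} covariance not positive-definite")
        return self

    @property
    def tem_index(self) -> int:
        return self.labels.index("TEM")

    @property
    def debris_index(self) -> int:
        return self.labels.index("debris")


@dataclass
class PopulationFit:
    """EM result: fitted template, per-event posteriors, and diagnostics."""

    template: PopulationTemplate
    posteriors: np.ndarray          # (n_events, 7), rows sum to 1
    log_likelihood: float
    loglik_path: np.ndarray
    converged: bool
    failed_components: list[int] = field(default_factory=list)

    @property
    def assignments(self) -> np.ndarray:
        return self.posteriors.argmax(axis=1)


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    return multivariate_normal.logpdf(X, mean=mean, cov=cov, allow_singular=False)


def _e_step(X, means, covs, weights):
    n, K = X.shape[0], len(weights)
    logp = np.empty((n, K))
    for k in range(K):
        logp[:, k] = np.log(max(weights[k], 1e-300)) + _log_gauss(X, means[k], covs[k])
    m = logp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
    resp = np.exp(logp - lse[:, None])
    return resp, float(lse.sum())


def fit_population_model(
    sample: FlowSample,
    template: PopulationTemplate,
    max_iter: int = 200,
    tol: float = 1e-6,
    min_events: int = 7 * _MIN_EVENTS_PER_COMPONENT,
) -> PopulationFit:
    """EM on a 7-component full-covariance 3-D Gaussian mixture.

    Initialized at the template's parameters and run to log-likelihood
    tolerance; the log-likelihood is asserted non-decreasing each
    iteration.  A collapsing component (covariance determinant below
    floor) is re-seeded at its template values once; a second collapse
    marks it failed.  ``max_iter=0`` returns the template unchanged with
    assignments from the template posteriors.
    """
    template = template.validate()
    X = sample.events
    if X.shape[0] < min_events:
        raise ValueError(
            f"insufficient events for a 7-component fit: {X.shape[0]} < {min_events}"
        )
    means = template.means.copy()
    covs = template.covariances.copy()
    weights = template.weights.copy()
    weights = np.maximum(weights, 1e-6)
    weights /= weights.sum()

    resp, ll = _e_step(X, means, covs, weights)
    path = [ll]
    if max_iter == 0:
        return PopulationFit(
            template=template, posteriors=resp, log_likelihood=ll,
            loglik_path=np.array(path), converged=False,
        )

    reseeded = set()
    failed: list[int] = []
    converged = False
    for _ in range(max_iter):
        intervened = False
        nk = resp.sum(axis=0)
        weights = nk / nk.sum()
        for k in range(7):
            if nk[k] < 1e-8:
                covs[k] = template.covariances[k]
                means[k] = template.means[k]
                intervened = True
                continue
            means[k] = resp[:, k] @ X / nk[k]
            d = X - means[k]
            C = (resp[:, k][:, None] * d).T @ d / nk[k]
            C = 0.5 * (C + C.T) + 1e-8 * np.eye(3)
            if np.linalg.det(C) < _COV_DET_FLOOR:
                intervened = True
                if k in reseeded:
                    if k not in failed:
                        failed.append(k)
                    C = template.covariances[k]
                else:
                    reseeded.add(k)
                    means[k] = template.means[k]
                    C = template.covariances[k]
            covs[k] = C
        resp, ll_new = _e_step(X, means, covs, weights)
        # a re-seeded (collapsed/starved) component breaks the EM ascent
        # guarantee for that iteration by design
        if not intervened and ll_new < path[-1] - 1e-6 * max(1.0, abs(path[-1])):
            raise AssertionError("EM log-likelihood decreased")
        path.append(ll_new)
        if ll_new - path[-2] < tol * max(1.0, abs(ll_new)) * 1e-3 or \
                ll_new - path[-2] < tol:
            converged = True
            break

    # relabel fitted components by nearest template component under the
    # template covariance metric (one-to-one assignment)
    cost = np.empty((7, 7))
    inv = np.linalg.inv(template.covariances)
    for k in range(7):          # fitted
        for j in range(7):      # template
            d = means[k] - template.means[j]
            cost[k, j] = d @ inv[j] @ d
    rows, cols = linear_sum_assignment(cost)
    order = np.empty(7, dtype=int)
    order[cols] = rows          # order[j] = fitted component carrying label j
    fitted = PopulationTemplate(
        means=means[order], covariances=covs[order],
        weights=weights[order], labels=list(template.labels),
    ).validate()
    return PopulationFit(
        template=fitted,
        posteriors=resp[:, order],
        log_likelihood=path[-1],
        loglik_path=np.array(path),
        converged=converged,
        failed_components=sorted(int(order.tolist().index(k)) for k in failed) if failed else [],
    )


def quantify_tem_abundance(fit: PopulationFit) -> float:
    """T_EM abundance as % of non-debris posterior mass, in [0, 100]."""
    mass = fit.posteriors.sum(axis=0)
    tem = mass[fit.template.tem_index]
    live = mass.sum() - mass[fit.template.debris_index]
    if live <= 0:
        raise ValueError("all posterior mass assigned to debris; abundance undefined")
    return float(100.0 * tem / live)
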