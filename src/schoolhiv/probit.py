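"""Univariate probit maximum likelihood with household-cluster-robust inference.

The seroconversion hazard Pr(y_it = 1 | x_it, s_it) = Phi(x_it'pi + s_it beta)
is a discrete-time hazard model: one row per woman per at-risk year, with age
dummies absorbing duration dependence.  Standard errors are clustered at the
household level, and the quantity of interest is the at-means discrete-change
partial effect of attendance on the probability scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .exceptions import (
    CollinearityError,
    InvalidParameterError,
    SeparationError,
)

__all__ = [
    "ProbitFit",
    "PartialEffect",
    "probit_loglik",
    "fit_probit",
    "discrete_change_at_means",
    "detect_separation",
]

_Z95 = norm.ppf(0.975)


@dataclass
class PartialEffect:
    """Probability-scale discrete change with a delta-method standard error."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    se_estimable: bool = True


@dataclass
class ProbitFit:
    """ML probit fit with cluster-robust sandwich covariance."""

    params: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_clusters: int
    converged: bool
    names: list[str]
    exog_means: np.ndarray = field(repr=False, default=None)
    binary_cols: frozenset = frozenset()

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.cov[i, i]))


def _check_binary(y: np.ndarray, what: str = "outcome") -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise InvalidParameterError(f"{what} must be binary 0/1")
    return y


def probit_loglik(params, y, X) -> float:
    """Log likelihood sum_i [y log Phi(x'theta) + (1-y) log Phi(-x'theta)].

    Computed through the log-CDF so extreme indices neither overflow nor
    collapse to -inf prematurely.
    """
    y = _check_binary(y)
    X = np.asarray(X, dtype=float)
    q = 2.0 * y - 1.0
    return float(np.sum(log_ndtr(q * (X @ np.asarray(params, dtype=float)))))


def _mills(z: np.ndarray) -> np.ndarray:
    # phi(z)/Phi(z), stable for very negative z
    return np.exp(norm.logpdf(z) - log_ndtr(z))


def _score_obs(params, y, X):
    q = 2.0 * y - 1.0
    lam = _mills(q * (X @ params))
    return (q * lam)[:, None] * X


def _neg_hessian(params, y, X):
    q = 2.0 * y - 1.0
    z = q * (X @ params)
    lam = _mills(z)
    w = lam * (lam + z)
    return (X * w[:, None]).T @ X


def detect_separation(y, X, names) -> list[str]:
    """Columns (binary dummies) that perfectly predict the outcome.

    A dummy whose rows are all-events or all-nonevents drives its
    coefficient to +/-infinity; returns the offending column names.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    bad = []
    for j, name in enumerate(names):
        col = X[:, j]
        vals = np.unique(col)
        if not np.isin(vals, (0.0, 1.0)).all() or len(vals) < 2:
            continue
        sub = y[col == 1.0]
        if sub.size and (sub.max() == 0.0 or sub.min() == 1.0):
            bad.append(name)
    return bad


def _cluster_sandwich(scores_obs, neg_hess, cluster_ids):
    """G/(G-1)-corrected cluster sandwich; bread from observed information."""
    cluster_ids = np.asarray(cluster_ids)
    _, inv = np.unique(cluster_ids, return_inverse=True)
    n_g = inv.max() + 1
    p = scores_obs.shape[1]
    sums = np.zeros((n_g, p))
    np.add.at(sums, inv, scores_obs)
    meat = sums.T @ sums
    if n_g > 1:
        meat *= n_g / (n_g - 1.0)
    bread = np.linalg.pinv(neg_hess)
    return bread @ meat @ bread, int(n_g)


def fit_probit(y, X, cluster_ids, names=None, *, tol=1e-9, max_iter=100) -> ProbitFit:
    """Newton ML with analytic gradient/Hessian and cluster-robust covariance.

    Convergence requires gradient max-norm below 1e-6 and a relative
    log-likelihood change below 1e-10; the ``converged`` flag is honest.
    """
    y = _check_binary(y)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(_name_collinear(X, names))
    sep = detect_separation(y, X, names)
    if sep:
        raise SeparationError(
            "perfect separation in column(s): " + ", ".join(sep)
        )
    if len(cluster_ids) != len(y):
        raise InvalidParameterError("cluster_ids length mismatch")

    theta = np.zeros(X.shape[1])
    ll = probit_loglik(theta, y, X)
    converged = False
    for _ in range(max_iter):
        g = _score_obs(theta, y, X).sum(axis=0)
        H = _neg_hessian(theta, y, X)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # damped Newton: halve until the likelihood improves
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            ll_new = probit_loglik(cand, y, X)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        theta, ll = cand, ll_new
        if np.max(np.abs(_score_obs(theta, y, X).sum(axis=0))) < 1e-6 and rel < 1e-10:
            converged = True
            break

    scores = _score_obs(theta, y, X)
    cov, n_g = _cluster_sandwich(scores, _neg_hessian(theta, y, X), cluster_ids)
    return ProbitFit(
        params=theta,
        cov=cov,
        loglik=ll,
        n=len(y),
        n_clusters=n_g,
        converged=converged,
        names=names,
        exog_means=X.mean(axis=0),
        binary_cols=frozenset(
            n for n, col in zip(names, X.T) if np.isin(col, (0.0, 1.0)).all()
        ),
    )


def _name_collinear(X, names) -> str:
    # report columns whose removal restores full rank
    offenders = []
    for j in range(X.shape[1]):
        rest = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(X):
            offenders.append(names[j])
    return "rank-deficient design; involved columns: " + ", ".join(offenders)


def discrete_change_at_means(fit: ProbitFit, variable: str) -> PartialEffect:
    """Phi(xbar'theta with v=1) - Phi(xbar'theta with v=0), delta-method SE.

    All other columns (dummies included) are held at their sample means;
    ``variable`` must be binary in the design.
    """
    j = fit.names.index(variable)
    if fit.binary_cols and variable not in fit.binary_cols:
        raise InvalidParameterError(f"{variable} is not binary in the design")
    xbar = np.array(fit.exog_means, dtype=float)
    base = float(xbar @ fit.params - xbar[j] * fit.params[j])
    c1 = base + float(fit.params[j])
    eff = float(ndtr(c1) - ndtr(base))
    grad = (norm.pdf(c1) - norm.pdf(base)) * xbar
    grad[j] = norm.pdf(c1)
    var = float(grad @ fit.cov @ grad)
    if var >= 0.0:
        se = float(np.sqrt(var))
        return PartialEffect(eff, se, eff - _Z95 * se, eff + _Z95 * se)
    return PartialEffect(eff, np.nan, np.nan, np.nan, se_estimable=False)
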