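"""Recursive bivariate probit and selection-on-unobservables sensitivity tools.

Two jointly-normal latent-index equations drive the analysis:

    s_it = 1(x_it'delta + z_it'gamma + u_it > 0)      (attendance)
    y_it = 1(x_it'pi    + s_it beta  + eps_it > 0)    (seroconversion)

with corr(u, eps) = rho.  With instruments z (distance to secondary school)
the system is identified and rho is estimated; without instruments it is
under-identified and rho is imposed on a grid of values phi, tracing out how
the attendance effect moves with the assumed degree of selection on
unobservables.  The grid's upper bound is the correlation implied if
selection on unobservables equalled selection on the observed control
indices, Cov(x'delta, x'pi)/Var(x'pi).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from ._bvn import bvn_cdf, bvn_pdf
from .exceptions import InvalidParameterError, UndefinedBoundError
from .probit import PartialEffect, ProbitFit, _cluster_sandwich, fit_probit

__all__ = [
    "BiprobitParams",
    "BiprobitFit",
    "SensitivityEntry",
    "SensitivityGrid",
    "SelectionBound",
    "cell_probabilities",
    "biprobit_loglik",
    "fit_biprobit",
    "fit_constrained_biprobit",
    "selection_upper_bound",
    "sensitivity_grid",
    "DEFAULT_PHI_GRID",
]

_Z95 = norm.ppf(0.975)
DEFAULT_PHI_GRID = (0.0, -0.05, -0.10, -0.15, -0.20, -0.25, -0.30)
_LOG_TINY = 1e-300


@dataclass
class BiprobitParams:
    """Structural parameters of the two-equation system."""

    delta: np.ndarray
    gamma: np.ndarray
    pi: np.ndarray
    beta: float
    rho: float

    def __post_init__(self):
        if not -1.0 < self.rho < 1.0:
            raise InvalidParameterError("rho must lie strictly inside (-1, 1)")


@dataclass
class BiprobitFit:
    params: BiprobitParams
    cov: np.ndarray  # on the internal (delta, [gamma,] pi, beta, atanh rho) scale
    loglik: float
    partial_effect: PartialEffect
    rho_test_p: float
    rho_ci: tuple[float, float]
    n: int
    n_clusters: int
    converged: bool
    x_names: list[str]
    z_names: list[str]
    se_estimable: bool = True
    rho_fixed: bool = False
    extra: dict = field(default_factory=dict, repr=False)

    @property
    def beta_se(self) -> float:
        """Cluster-robust SE of the latent attendance coefficient."""
        j = (len(self.params.delta) + len(self.params.gamma)
             + len(self.params.pi))
        return float(np.sqrt(max(self.cov[j, j], 0.0)))

    @property
    def rho_se(self) -> float:
        """Delta-method SE of rho, mapped back from the atanh scale."""
        if self.rho_fixed:
            return 0.0
        v = self.cov[-1, -1]
        return float(np.sqrt(max(v, 0.0)) * (1.0 - self.params.rho**2))


@dataclass
class SensitivityEntry:
    phi: float
    partial_effect: float
    se: float
    ci_low: float
    ci_high: float
    se_estimable: bool
    is_bound: bool = False
    error: str | None = None


@dataclass
class SensitivityGrid:
    entries: list[SensitivityEntry]
    bound: "SelectionBound"


@dataclass
class SelectionBound:
    rho_upper: float


def cell_probabilities(a, b0, beta, rho):
    """Orthant probabilities of the four (s, y) cells for fixed indices.

    With b1 = b0 + beta:
        P(1,1) = Phi2(a, b1, rho)          P(1,0) = Phi(a) - P(1,1)
        P(0,1) = Phi(b0) - Phi2(a, b0, rho)
        P(0,0) = 1 - Phi(a) - Phi(b0) + Phi2(a, b0, rho)
    Returns (p11, p10, p01, p00); broadcasts over array inputs.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho_arr) >= 1.0):
        raise InvalidParameterError("rho must lie strictly inside (-1, 1)")
    a = np.asarray(a, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    b1 = b0 + beta
    p11 = bvn_cdf(a, b1, rho)
    p10 = ndtr(a) - p11
    c = bvn_cdf(a, b0, rho)
    p01 = ndtr(b0) - c
    p00 = 1.0 - ndtr(a) - ndtr(b0) + c
    clip = lambda p: np.clip(p, 0.0, 1.0)
    return clip(p11), clip(p10), clip(p01), clip(p00)


def _loglik_terms(w1, w2, r):
    """log Phi2(w1, w2, r) and its partials wrt (w1, w2, r), elementwise."""
    p = np.maximum(bvn_cdf(w1, w2, r), _LOG_TINY)
    logp = np.log(p)
    om = np.sqrt(1.0 - r * r)
    g1 = np.exp(norm.logpdf(w1) + log_ndtr((w2 - r * w1) / om) - logp)
    g2 = np.exp(norm.logpdf(w2) + log_ndtr((w1 - r * w2) / om) - logp)
    gr = bvn_pdf(w1, w2, r) / p
    return logp, g1, g2, gr


def _pack_indices(y, s, X, Z, delta, gamma, pi, beta, rho):
    qs = 2.0 * s - 1.0
    qy = 2.0 * y - 1.0
    a = X @ delta
    if Z is not None and Z.shape[1]:
        a = a + Z @ gamma
    w1 = qs * a
    w2 = qy * (X @ pi + beta * s)
    r = qs * qy * rho
    return qs, qy, w1, w2, r


def biprobit_loglik(params: BiprobitParams, y, s, X, Z=None) -> float:
    """Joint log likelihood: each observation contributes its (s, y) cell."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = None if Z is None else np.asarray(Z, dtype=float)
    _, _, w1, w2, r = _pack_indices(
        y, s, X, Z, params.delta, params.gamma, params.pi, params.beta, params.rho
    )
    return float(np.sum(np.log(np.maximum(bvn_cdf(w1, w2, r), _LOG_TINY))))


def _nll_and_grad(theta, y, s, X, Z, p, q, rho_fixed):
    """Negative loglik and gradient on the internal parameter vector.

    Layout: delta (p), gamma (q), pi (p), beta, [eta = atanh(rho)].
    """
    delta = theta[:p]
    gamma = theta[p : p + q]
    pi = theta[p + q : 2 * p + q]
    beta = theta[2 * p + q]
    rho = rho_fixed if rho_fixed is not None else np.tanh(theta[-1])
    qs, qy, w1, w2, r = _pack_indices(y, s, X, Z, delta, gamma, pi, beta, rho)
    logp, g1, g2, gr = _loglik_terms(w1, w2, r)
    d1 = g1 * qs
    d2 = g2 * qy
    grads = [X.T @ d1]
    if q:
        grads.append(Z.T @ d1)
    grads.append(X.T @ d2)
    grads.append(np.array([d2 @ s]))
    if rho_fixed is None:
        grads.append(np.array([(gr * qs * qy).sum() * (1.0 - rho * rho)]))
    return -float(logp.sum()), -np.concatenate(grads)


def _score_obs_internal(theta, y, s, X, Z, p, q, rho_fixed):
    delta = theta[:p]
    gamma = theta[p : p + q]
    pi = theta[p + q : 2 * p + q]
    beta = theta[2 * p + q]
    rho = rho_fixed if rho_fixed is not None else np.tanh(theta[-1])
    qs, qy, w1, w2, r = _pack_indices(y, s, X, Z, delta, gamma, pi, beta, rho)
    _, g1, g2, gr = _loglik_terms(w1, w2, r)
    d1 = (g1 * qs)[:, None]
    d2 = (g2 * qy)[:, None]
    cols = [d1 * X]
    if q:
        cols.append(d1 * Z)
    cols.append(d2 * X)
    cols.append(d2 * s[:, None])
    if rho_fixed is None:
        cols.append((gr * qs * qy * (1.0 - rho * rho))[:, None])
    return np.hstack(cols)


def _numerical_hessian(grad_fn, theta, step=1e-5):
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        h = step * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _partial_effect_from(theta_pi, beta, cov_block, xbar) -> PartialEffect:
    base = float(xbar @ theta_pi)
    eff = float(ndtr(base + beta) - ndtr(base))
    grad = np.concatenate([(norm.pdf(base + beta) - norm.pdf(base)) * xbar,
                           [norm.pdf(base + beta)]])
    var = float(grad @ cov_block @ grad)
    if var >= 0.0 and np.isfinite(var):
        se = float(np.sqrt(var))
        return PartialEffect(eff, se, eff - _Z95 * se, eff + _Z95 * se)
    return PartialEffect(eff, np.nan, np.nan, np.nan, se_estimable=False)


def _fit_system(y, s, X, Z, cluster_ids, rho_fixed, x_names, z_names,
                start=None, gtol=1e-7):
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = None if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    n, p = X.shape
    q = 0 if Z is None else Z.shape[1]

    if start is None:
        XZ = X if q == 0 else np.hstack([X, Z])
        school = fit_probit(s, XZ, cluster_ids)
        outcome = fit_probit(y, np.hstack([X, s[:, None]]), cluster_ids)
        start = np.concatenate([
            school.params,
            outcome.params,
            [] if rho_fixed is not None else [np.arctanh(np.clip(rho_fixed or 0.0, -0.99, 0.99))],
        ])

    res = optimize.minimize(
        _nll_and_grad,
        start,
        args=(y, s, X, Z, p, q, rho_fixed),
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": 500},
    )
    theta = res.x
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4

    grad_fn = lambda t: _nll_and_grad(t, y, s, X, Z, p, q, rho_fixed)[1]
    neg_hess = _numerical_hessian(grad_fn, theta)  # Hessian of the NEGATIVE ll
    scores = _score_obs_internal(theta, y, s, X, Z, p, q, rho_fixed)
    cov, n_g = _cluster_sandwich(scores, neg_hess, cluster_ids)
    se_ok = bool(np.all(np.linalg.eigvalsh(0.5 * (neg_hess + neg_hess.T)) > 0))

    rho = rho_fixed if rho_fixed is not None else float(np.tanh(theta[-1]))
    params = BiprobitParams(
        delta=theta[:p],
        gamma=theta[p : p + q],
        pi=theta[p + q : 2 * p + q],
        beta=float(theta[2 * p + q]),
        rho=rho,
    )
    # attendance partial effect from the outcome equation, at covariate means
    xbar = X.mean(axis=0)
    ix = slice(p + q, 2 * p + q + 1)  # (pi, beta) block
    pe = _partial_effect_from(params.pi, params.beta, cov[ix, ix], xbar)
    if not se_ok:
        pe = PartialEffect(pe.estimate, np.nan, np.nan, np.nan, se_estimable=False)

    if rho_fixed is None:
        eta, v_eta = theta[-1], max(cov[-1, -1], 0.0)
        z = eta / np.sqrt(v_eta) if v_eta > 0 else np.inf
        p_rho = float(2.0 * norm.sf(abs(z)))
        ci = (float(np.tanh(eta - _Z95 * np.sqrt(v_eta))),
              float(np.tanh(eta + _Z95 * np.sqrt(v_eta))))
    else:
        p_rho, ci = np.nan, (rho, rho)

    return BiprobitFit(
        params=params,
        cov=cov,
        loglik=-res.fun,
        partial_effect=pe,
        rho_test_p=p_rho,
        rho_ci=ci,
        n=n,
        n_clusters=n_g,
        converged=converged,
        x_names=list(x_names) if x_names else [f"x{j}" for j in range(p)],
        z_names=list(z_names) if z_names else [f"z{j}" for j in range(q)],
        se_estimable=se_ok,
        rho_fixed=rho_fixed is not None,
    )


def fit_biprobit(y, s, X, Z, cluster_ids, x_names=None, z_names=None) -> BiprobitFit:
    """Full-information ML for the recursive system with exclusion restrictions.

    Start values come from the two univariate probits with rho = 0; rho is
    optimized on the atanh scale.  Reports the at-means attendance partial
    effect and a Wald test of rho = 0.  Non-convergence is flagged on the
    returned fit, never silent.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.size == 0 or Z.shape[1] == 0:
        raise InvalidParameterError("at least one instrument column required")
    return _fit_system(y, s, X, Z, cluster_ids, None, x_names, z_names)


def fit_constrained_biprobit(y, s, X, phi, cluster_ids, x_names=None) -> BiprobitFit:
    """Under-identified system with rho imposed at ``phi`` and no instruments."""
    if not -1.0 < phi < 1.0:
        raise InvalidParameterError("phi must lie strictly inside (-1, 1)")
    return _fit_system(y, s, X, None, cluster_ids, float(phi), x_names, None)


def selection_upper_bound(school_fit, outcome_fit, X) -> SelectionBound:
    """Cov(x'delta, x'pi)/Var(x'pi) from the phi = 0 fits of the two equations.

    ``school_fit`` is the probit of attendance on the controls; ``outcome_fit``
    is the constrained system at phi = 0 (or any object exposing ``params.pi``).
    The attendance column is not part of x for this computation.
    """
    X = np.asarray(X, dtype=float)
    sp = school_fit.params
    delta = np.asarray(sp if isinstance(sp, np.ndarray) else sp.delta, float)
    op = outcome_fit.params
    pi = np.asarray(op.pi if hasattr(op, "pi") else op, float)
    idx_s = X @ delta
    idx_y = X @ pi
    var_y = float(np.var(idx_y, ddof=1))
    if var_y <= 0.0:
        raise UndefinedBoundError("Var(x'pi) is zero; bound undefined")
    cov = float(np.cov(idx_s, idx_y, ddof=1)[0, 1])
    return SelectionBound(rho_upper=cov / var_y)


def _entry_from_fit(phi, fit, is_bound=False) -> SensitivityEntry:
    pe = fit.partial_effect
    return SensitivityEntry(
        phi=float(phi),
        partial_effect=pe.estimate,
        se=pe.se,
        ci_low=pe.ci_low,
        ci_high=pe.ci_high,
        se_estimable=pe.se_estimable,
        is_bound=is_bound,
    )


def sensitivity_grid(y, s, X, cluster_ids, grid=None, x_names=None) -> SensitivityGrid:
    """Constrained fits across imposed correlations, plus the selection bound.

    The grid runs from 0 downward (0 first); the bound
    Cov(x'delta, x'pi)/Var(x'pi) is appended as a final, flagged entry.  A
    failure in one entry is recorded on that entry and does not abort the rest.
    """
    phis = sorted(set(DEFAULT_PHI_GRID if grid is None else map(float, grid)),
                  reverse=True)
    if not phis or phis[0] != 0.0:
        phis = [0.0] + [f for f in phis if f != 0.0]
    for f in phis:
        if not -1.0 < f < 1.0:
            raise InvalidParameterError("grid values must lie inside (-1, 1)")

    entries = []
    fit0 = None
    for f in phis:
        try:
            fit = fit_constrained_biprobit(y, s, X, f, cluster_ids, x_names=x_names)
            if f == 0.0:
                fit0 = fit
            entries.append(_entry_from_fit(f, fit))
        except Exception as exc:  # pragma: no cover - per-entry resilience
            entries.append(SensitivityEntry(f, np.nan, np.nan, np.nan, np.nan,
                                            False, error=str(exc)))

    school = fit_probit(np.asarray(s, float), np.asarray(X, float), cluster_ids)
    bound = selection_upper_bound(school, fit0, X)
    try:
        bfit = fit_constrained_biprobit(
            y, s, X, float(np.clip(bound.rho_upper, -0.99, 0.99)), cluster_ids,
            x_names=x_names)
        entries.append(_entry_from_fit(bound.rho_upper, bfit, is_bound=True))
    except Exception as exc:  # pragma: no cover
        entries.append(SensitivityEntry(bound.rho_upper, np.nan, np.nan, np.nan,
                                        np.nan, False, is_bound=True,
                                        error=str(exc)))
    return SensitivityGrid(entries=entries, bound=bound)
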