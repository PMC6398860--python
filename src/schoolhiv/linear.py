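"""Linear robustness suite: LPM, individual fixed effects, LIML IV, and the
coefficient-stability (proportional-selection) bound delta*.

The linear probability model complements the probit battery: OLS with
household-cluster standard errors, a within (fixed-effects) estimator for
time-constant heterogeneity, a k-class LIML estimator for the
distance instruments, and the sensitivity statistic delta* — how strong
selection on unobservables must be, relative to selection on observables,
to drive the attendance coefficient to a target value (0 by default).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .exceptions import CollinearityError, InvalidParameterError

__all__ = ["LinearFit", "DeltaStar", "fit_lpm", "fit_fe_within", "fit_liml",
           "delta_star"]

_Z95 = 1.959963984540054


@dataclass
class LinearFit:
    params: np.ndarray
    cov: np.ndarray
    r_squared: float
    n: int
    n_clusters: int
    names: list[str]
    estimator: str
    notes: list[str] = field(default_factory=list)
    kappa: float | None = None

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        j = self.names.index(name)
        return float(np.sqrt(self.cov[j, j]))


@dataclass
class DeltaStar:
    delta_star: float
    r_max: float
    beta_target: float
    unbounded: bool = False


def _cluster_cov(bread: np.ndarray, scores: np.ndarray, cluster_ids) -> tuple[np.ndarray, int]:
    _, inv = np.unique(np.asarray(cluster_ids), return_inverse=True)
    G = inv.max() + 1
    sums = np.zeros((G, scores.shape[1]))
    np.add.at(sums, inv, scores)
    meat = sums.T @ sums
    if G > 1:
        meat *= G / (G - 1.0)
    return bread @ meat @ bread, int(G)


def _check_rank(X, names):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("rank-deficient design: " + ", ".join(names))


def fit_lpm(y, X, cluster_ids, names=None) -> LinearFit:
    """OLS linear probability model, G/(G-1)-corrected cluster sandwich."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = list(names) if names else [f"x{j}" for j in range(X.shape[1])]
    _check_rank(X, names)
    XtX = X.T @ X
    beta = linalg.solve(XtX, X.T @ y, assume_a="pos")
    e = y - X @ beta
    bread = linalg.inv(XtX)
    cov, G = _cluster_cov(bread, X * e[:, None], cluster_ids)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(e @ e) / tss if tss > 0 else 0.0
    return LinearFit(beta, cov, r2, len(y), G, names, "ols")


def _demean_within(values, person_ids):
    uniq, inv = np.unique(person_ids, return_inverse=True)
    out = np.asarray(values, dtype=float).copy()
    if out.ndim == 1:
        out = out[:, None]
    for j in range(out.shape[1]):
        sums = np.bincount(inv, out[:, j], minlength=len(uniq))
        cnt = np.bincount(inv, minlength=len(uniq))
        out[:, j] -= (sums / cnt)[inv]
    return out


def fit_fe_within(y, X, person_ids, cluster_ids, names=None) -> LinearFit:
    """Within (individual fixed effects) estimator.

    Time-constant columns vanish under demeaning and are dropped with a
    note; degrees of freedom are adjusted for the absorbed person effects.
    Numerically identical to OLS with one indicator per person (LSDV).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = list(names) if names else [f"x{j}" for j in range(X.shape[1])]
    Xd = _demean_within(X, person_ids)
    yd = _demean_within(y, person_ids)[:, 0]
    keep = [j for j in range(Xd.shape[1]) if np.max(np.abs(Xd[:, j])) > 1e-10]
    notes = [f"time-constant column dropped: {names[j]}"
             for j in range(Xd.shape[1]) if j not in keep]
    if not keep:
        raise InvalidParameterError("all columns time-constant: nothing to estimate")
    Xd = Xd[:, keep]
    kept_names = [names[j] for j in keep]
    # demeaning can leave exact collinearity (e.g. age and year dummies both
    # advance one-for-one within person); drop trailing dependents via
    # pivoted QR, keeping the earliest columns
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        _, _, piv = linalg.qr(Xd, mode="economic", pivoting=True)
        rank = np.linalg.matrix_rank(Xd)
        drop = sorted(piv[rank:], reverse=True)
        for j in drop:
            notes.append(f"collinear after demeaning, dropped: {kept_names[j]}")
            kept_names.pop(j)
        Xd = np.delete(Xd, drop, axis=1)
    _check_rank(Xd, kept_names)
    XtX = Xd.T @ Xd
    beta = linalg.solve(XtX, Xd.T @ yd, assume_a="pos")
    e = yd - Xd @ beta
    bread = linalg.inv(XtX)
    cov, G = _cluster_cov(bread, Xd * e[:, None], cluster_ids)
    # dof correction for absorbed person intercepts
    n = len(y)
    n_persons = len(np.unique(person_ids))
    k = Xd.shape[1]
    dof_factor = (n - k) / max(n - n_persons - k, 1)
    cov = cov * dof_factor
    tss = float(yd @ yd)
    r2 = 1.0 - float(e @ e) / tss if tss > 0 else 0.0
    return LinearFit(beta, cov, r2, n, G, kept_names, "fe", notes=notes)


def fit_liml(y, endog, X, Z, cluster_ids, names=None) -> LinearFit:
    """LIML k-class estimator for one endogenous regressor.

    kappa is the smallest eigenvalue of the pencil (W'M_X W, W'M_XZ W) with
    W = [y, s]; kappa >= 1, and the just-identified case collapses to the
    standard IV estimator.  Cluster sandwich uses the k-class-projected
    regressors as instruments.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(endog, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.size == 0 or Z.shape[1] == 0:
        raise InvalidParameterError("at least one instrument required")
    names = ["attendance"] + (list(names) if names
                              else [f"x{j}" for j in range(X.shape[1])])

    def annihilate(A, B):
        # residual of B on A
        coef, *_ = np.linalg.lstsq(A, B, rcond=None)
        return B - A @ coef

    W = np.column_stack([y, s])
    XZ = np.hstack([X, Z])
    M_x_W = annihilate(X, W)
    M_xz_W = annihilate(XZ, W)
    A = M_x_W.T @ M_x_W
    B = M_xz_W.T @ M_xz_W
    kappa = float(np.min(linalg.eigvals(A, B).real))
    Q = np.column_stack([s, X])
    M_xz_Q = annihilate(XZ, Q)
    H = Q - kappa * M_xz_Q  # k-class projected regressors
    HtQ = H.T @ Q
    beta = linalg.solve(HtQ, H.T @ y)
    e = y - Q @ beta
    bread = linalg.inv(HtQ)
    cov, G = _cluster_cov(bread, H * e[:, None], cluster_ids)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(e @ e) / tss if tss > 0 else 0.0
    return LinearFit(beta, cov, r2, len(y), G, names, "liml", kappa=kappa)


def delta_star(uncontrolled: LinearFit, controlled: LinearFit,
               r_max: float | None = None, beta_target: float = 0.0,
               treatment: str = "attendance") -> DeltaStar:
    """Proportional-selection coefficient-stability bound.

    With uncontrolled (treatment-only) coefficient beta0 and R^2 R0, and
    controlled coefficient beta1 and R^2 R1, the bias-adjusted coefficient
    under proportional selection of degree delta is approximately

        beta*(delta) = beta1 - delta * (beta0 - beta1) * (r_max - R1)/(R1 - R0)

    and delta* solves beta*(delta) = beta_target.  Default
    r_max = min(1.3 * R1, 1).  A coefficient unmoved by controls while R^2
    rises makes delta* diverge (flagged unbounded).
    """
    b0 = uncontrolled.coef(treatment)
    b1 = controlled.coef(treatment)
    r0, r1 = uncontrolled.r_squared, controlled.r_squared
    if r1 <= r0:
        raise InvalidParameterError(
            "controlled R^2 must exceed uncontrolled R^2 for delta*")
    if r_max is None:
        r_max = min(1.3 * r1, 1.0)
    if r_max < r1:
        raise InvalidParameterError("r_max must be at least the controlled R^2")
    if b1 == beta_target:
        return DeltaStar(0.0, r_max, beta_target)
    move = (b0 - b1) * (r_max - r1) / (r1 - r0)
    if move == 0.0:
        return DeltaStar(float("inf"), r_max, beta_target, unbounded=True)
    return DeltaStar((b1 - beta_target) / move, r_max, beta_target)
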