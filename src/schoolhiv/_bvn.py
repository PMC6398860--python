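"""Standard bivariate normal CDF and density, vectorized.

The orthant probabilities of the joint attendance/seroconversion error
distribution drive the whole bivariate-probit likelihood, and the
likelihood's curvature in the error correlation is sensitive near the
optimum, so the CDF here is computed from Owen's T function, which is
accurate to near machine precision uniformly in the correlation.
"""
from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "bvn_pdf"]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _phi(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z * z) / _SQRT_2PI


def bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard normal (Z1, Z2) with correlation rho.

    Uses the identity
        Phi2(h, k, rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - beta
    with a_h = (k - rho h)/(h sqrt(1-rho^2)) (and symmetrically a_k), and
    beta = 1/2 when hk < 0 or hk = 0 with h + k < 0, else 0.  T is Owen's T
    function.  Broadcasts over all three arguments; requires |rho| < 1.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("correlation must lie strictly inside (-1, 1)")
    h, k, rho = np.broadcast_arrays(h, k, rho)
    denom = np.sqrt(1.0 - rho * rho)

    with np.errstate(divide="ignore", invalid="ignore"):
        a_h = (k - rho * h) / (h * denom)
        a_k = (h - rho * k) / (k * denom)
    # h = 0 (or k = 0) gives a = +/-inf with the sign of the numerator,
    # which is the correct directional limit; owens_t handles infinities.
    # Both zero is the one genuinely indeterminate case, patched below.
    both_zero = (h == 0.0) & (k == 0.0)
    a_h = np.where(both_zero, 0.0, a_h)
    a_k = np.where(both_zero, 0.0, a_k)

    hk = h * k
    beta = np.where((hk < 0.0) | ((hk == 0.0) & (h + k < 0.0)), 0.5, 0.0)
    p = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta
    p = np.where(both_zero, 0.25 + np.arcsin(rho) / (2.0 * np.pi), p)
    return np.clip(p, 0.0, 1.0)


def bvn_pdf(h, k, rho):
    """Standard bivariate normal density at (h, k); equals dPhi2/drho."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    om = 1.0 - rho * rho
    q = (h * h - 2.0 * rho * h * k + k * k) / om
    return np.exp(-0.5 * q) / (2.0 * np.pi * np.sqrt(om))
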