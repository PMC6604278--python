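"""Bivariate standard-normal rectangle probabilities.

Owen's T identity gives the CDF of a standard bivariate normal at (h, k)
with correlation rho in terms of two Owen's T evaluations; this is fast
enough to sit inside the calibration root-finders, where a quadrature-based
CDF would dominate runtime.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri, owens_t

__all__ = ["bvn_cdf", "orthant_prob", "binary_phi", "latent_orthant_phi"]

_RHO_CAP = 1.0 - 1e-12


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    if np.isneginf(h) or np.isneginf(k):
        return 0.0
    if np.isposinf(h):
        return float(ndtr(k))
    if np.isposinf(k):
        return float(ndtr(h))
    if rho >= _RHO_CAP:
        return float(ndtr(min(h, k)))
    if rho <= -_RHO_CAP:
        return float(max(ndtr(h) + ndtr(k) - 1.0, 0.0))
    if abs(rho) < 1e-14:
        return float(ndtr(h) * ndtr(k))

    s = np.sqrt(1.0 - rho * rho)
    # Owen (1956): Phi2 = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - beta
    if h == 0.0 and k == 0.0:
        return 0.25 + np.arcsin(rho) / (2.0 * np.pi)
    if h == 0.0:
        h = 1e-300 if k > 0 else -1e-300
    if k == 0.0:
        k = 1e-300 if h > 0 else -1e-300
    a_h = (k - rho * h) / (h * s)
    a_k = (h - rho * k) / (k * s)
    beta = 0.0 if h * k > 0 or (h * k == 0.0 and h + k >= 0) else 0.5
    val = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta
    return float(min(max(val, 0.0), 1.0))


def orthant_prob(p1: float, p2: float, rho: float) -> float:
    """P(Z1 > q(1-p1), Z2 > q(1-p2)) under correlation rho.

    This is the joint success probability of two binary variables obtained by
    dichotomizing a bivariate normal so that the marginal success
    probabilities are p1 and p2.
    """
    h = ndtri(1.0 - p1)
    k = ndtri(1.0 - p2)
    return bvn_cdf(-h, -k, rho)


def binary_phi(p1: float, p2: float, p11: float) -> float:
    """Pearson (phi) correlation of two binary variables from their joint cell."""
    v = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return float((p11 - p1 * p2) / v)


def latent_orthant_phi(p1: float, p2: float, rho: float) -> float:
    """Phi correlation implied by dichotomizing a bivariate normal with latent rho."""
    return binary_phi(p1, p2, orthant_prob(p1, p2, rho))
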