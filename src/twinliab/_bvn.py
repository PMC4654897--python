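"""Bivariate standard-normal orthant probabilities.

Everything downstream (tetrachoric likelihoods, liability models, model-based
case-wise concordance) reduces to cell probabilities of a 2x2 dichotomisation
of a bivariate standard normal at thresholds (h1, h2) with correlation rho.
The CDF is evaluated through Owen's T function, which is exact to machine
precision and vectorises; the quadrature-based `scipy.stats.multivariate_normal`
is deliberately left free to serve as an independent cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri, owens_t

__all__ = ["bvn_cdf", "bvn_upper", "cell_probs", "ndtr", "ndtri"]

# Below this, probabilities are clipped before taking logs.
_TINY = 1e-300


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses the Owen's T identity
        Phi2(h, k; rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - c,
    with a_h = (k - rho*h) / (h * sqrt(1-rho^2)) and c = (1 - sgn(h)sgn(k))/4.
    Inputs broadcast; |rho| -> 1 handled by the comonotone limits.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)

    out = np.empty(h.shape, dtype=float)

    near_one = np.abs(rho) >= 1.0 - 1e-12
    if np.any(near_one):
        pos = near_one & (rho > 0)
        neg = near_one & (rho < 0)
        out[pos] = np.minimum(ndtr(h[pos]), ndtr(k[pos]))
        out[neg] = np.maximum(0.0, ndtr(h[neg]) + ndtr(k[neg]) - 1.0)

    reg = ~near_one
    if np.any(reg):
        hr, kr, rr = h[reg], k[reg], rho[reg]
        # nudge exact zeros off the axis; the induced error is O(phi(0)*1e-12)
        hr = np.where(hr == 0.0, 1e-12, hr)
        kr = np.where(kr == 0.0, 1e-12, kr)
        den = np.sqrt(1.0 - rr * rr)
        ah = (kr - rr * hr) / (hr * den)
        ak = (hr - rr * kr) / (kr * den)
        c = (1.0 - np.sign(hr) * np.sign(kr)) / 4.0
        val = 0.5 * (ndtr(hr) + ndtr(kr)) - owens_t(hr, ah) - owens_t(kr, ak) - c
        out[reg] = val

    return np.clip(out, 0.0, 1.0)


def bvn_upper(h, k, rho):
    """P(X > h, Y > k) — the upper orthant probability."""
    return np.clip(1.0 - ndtr(h) - ndtr(k) + bvn_cdf(h, k, rho), 0.0, 1.0)


def cell_probs(h1, h2, rho):
    """2x2 cell probabilities (p11, p10, p01, p00) of the dichotomised pair.

    Cell (1,1) is "both above threshold" (both affected). Probabilities are
    clipped away from zero so they are always safe to log.
    """
    p11 = bvn_upper(h1, h2, rho)
    p10 = np.clip((1.0 - ndtr(h1)) - p11, 0.0, 1.0)
    p01 = np.clip((1.0 - ndtr(h2)) - p11, 0.0, 1.0)
    p00 = np.clip(1.0 - p11 - p10 - p01, 0.0, 1.0)
    return (np.maximum(p11, _TINY), np.maximum(p10, _TINY),
            np.maximum(p01, _TINY), np.maximum(p00, _TINY))
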