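"""Standard bivariate normal CDF via Owen's T function.

The tetrachoric estimator evaluates Phi2 thousands of times inside the
permutation engine, so this needs to be vectorized and deterministic.
Owen (1956): Phi2(h, k, rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k)
- delta, with delta = 1/2 when h*k < 0 (or h*k = 0 and h + k < 0).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf"]


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    All arguments broadcast; returns an ndarray (0-d for scalars).
    |rho| = 1 is handled as the degenerate comonotone/antimonotone limit.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    r = np.clip(rho, -1.0 + 1e-15, 1.0 - 1e-15)
    denom = np.sqrt(1.0 - r * r)
    # Shift exact zeros off the singular axis of a_h, a_k; the CDF is
    # continuous there so the perturbation is below double precision noise.
    eps = 1e-300
    hh = np.where(h == 0.0, eps, h)
    kk = np.where(k == 0.0, eps, k)
    ah = (kk - r * hh) / (hh * denom)
    ak = (hh - r * kk) / (kk * denom)
    delta = np.where((hh * kk > 0) | ((hh * kk == 0) & (hh + kk >= 0)), 0.0, 0.5)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(hh, ah) - owens_t(kk, ak) - delta
    out = np.clip(out, 0.0, 1.0)
    # degenerate limits
    lo = rho <= -1.0 + 1e-15
    hi = rho >= 1.0 - 1e-15
    if np.any(hi):
        out = np.where(hi, ndtr(np.minimum(h, k)), out)
    if np.any(lo):
        out = np.where(lo, np.maximum(ndtr(h) + ndtr(k) - 1.0, 0.0), out)
    return out
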