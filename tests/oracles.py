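"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the tetrachoric
oracle integrates the bivariate normal density on a Gauss-Legendre grid
(the implementation uses Owen's T), the EAP oracle is a dense
10,001-point grid posterior (the implementation uses a 49-node
quadrature), and the Fisher-information oracle differentiates the
log-likelihood numerically (the implementation uses the closed form).
"""

import numpy as np
from scipy.special import ndtri, roots_legendre
from scipy.stats import norm

_GL_X, _GL_W = roots_legendre(64)


def bvn_quadrant_prob(tx: float, ty: float, rho: float, upper: float = 9.0) -> float:
    """P(X > tx, Y > ty) by 2-D Gauss-Legendre integration of the density."""
    xs = 0.5 * (upper - tx) * _GL_X + 0.5 * (upper + tx)
    ys = 0.5 * (upper - ty) * _GL_X + 0.5 * (upper + ty)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    det = 1.0 - rho**2
    dens = np.exp(-(X**2 - 2 * rho * X * Y + Y**2) / (2 * det)) / (
        2 * np.pi * np.sqrt(det)
    )
    W = np.outer(_GL_W, _GL_W) * 0.25 * (upper - tx) * (upper - ty)
    return float((dens * W).sum())


def tetrachoric_oracle(table, iters: int = 60) -> float:
    """Bisection on rho until the BVN quadrant probability matches p11."""
    t = np.asarray(table, float)
    n = t.sum()
    p11 = t[0, 0] / n
    tx = ndtri(1.0 - (t[0, 0] + t[0, 1]) / n)
    ty = ndtri(1.0 - (t[0, 0] + t[1, 0]) / n)
    lo, hi = -0.999, 0.999
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if bvn_quadrant_prob(tx, ty, mid) < p11:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def eap_grid_oracle(y, a, b, D, n_grid: int = 10001, span: float = 10.0):
    """Posterior mean/SD of theta on a dense uniform grid, N(0,1) prior.

    ``y`` is one person's response vector with NaN for missing.
    """
    grid = np.linspace(-span, span, n_grid)
    y = np.asarray(y, float)
    obs = ~np.isnan(y)
    z = D * np.asarray(a)[None, :] * (grid[:, None] - np.asarray(b)[None, :])
    p = 1.0 / (1.0 + np.exp(-z))
    lik = np.prod(
        np.where(obs[None, :], np.where(y[None, :] == 1.0, p, 1.0 - p), 1.0), axis=1
    )
    post = lik * norm.pdf(grid)
    post /= post.sum()
    mu = float((grid * post).sum())
    sd = float(np.sqrt((grid**2 * post).sum() - mu**2))
    return mu, sd


def fisher_information_fd(theta, a, b, D, h: float = 1e-4) -> float:
    """-E[d^2 log L / d theta^2] for a single 2PL item, by central differences."""

    def loglik(y, t):
        p = 1.0 / (1.0 + np.exp(-D * a * (t - b)))
        return y * np.log(p) + (1 - y) * np.log(1 - p)

    p0 = 1.0 / (1.0 + np.exp(-D * a * (theta - b)))
    total = 0.0
    for y, w in ((1, p0), (0, 1 - p0)):
        d2 = (loglik(y, theta + h) - 2 * loglik(y, theta) + loglik(y, theta - h)) / h**2
        total -= w * d2
    return total


def cfi_rmsea_oracle(chi2, df, chi2_b, df_b, n):
    """Hand-coded comparative fit index and RMSEA formulas."""
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, 0.0)
    cfi = 1.0 if den == 0 else min(max(1.0 - num / den, 0.0), 1.0)
    rmsea = 0.0 if df == 0 else np.sqrt(num / (df * (n - 1)))
    return cfi, rmsea


def item_info_closed_form(theta, a, b, D):
    p = 1.0 / (1.0 + np.exp(-D * a * (theta - b)))
    return (D * a) ** 2 * p * (1.0 - p)
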