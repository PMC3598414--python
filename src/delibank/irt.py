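"""Two-parameter logistic IRT: estimation, information, and trait scoring.

The 2PL model gives the probability that evaluee i expresses symptom j as

    P_j(theta_i) = 1 / (1 + exp(-D a_j (theta_i - b_j)))

with discrimination a_j, difficulty (symptom severity) b_j, latent trait
theta ~ N(0, 1), and scaling constant D (1.7 by default, placing the
logistic parameters close to the normal-ogive metric). Item information is
I_j(theta) = (D a_j)^2 P_j (1 - P_j), peaking at theta = b_j; information
is additive over locally independent items, and the marginal reliability
at a trait level theta* is TI(theta*) / (TI(theta*) + 1) under the
unit-variance prior.

Estimation is marginal maximum likelihood via EM on a fixed quadrature
grid; missing responses simply drop out of the person likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthetic import ResponseMatrix

__all__ = [
    "ItemParams",
    "ThetaEstimate",
    "ConvergenceError",
    "prob_correct",
    "item_information",
    "test_information",
    "fit_2pl",
    "eap_scores",
    "marginal_reliability",
]

DEFAULT_D = 1.7


class ConvergenceError(RuntimeError):
    """EM failed to converge; ``.trace`` holds per-iteration diagnostics."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


def prob_correct(theta, a, b, D: float = DEFAULT_D):
    """2PL response probability 1 / (1 + exp(-D a (theta - b)))."""
    theta, a, b = np.broadcast_arrays(
        np.asarray(theta, float), np.asarray(a, float), np.asarray(b, float)
    )
    z = D * a * (theta - b)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def item_information(theta, a, b, D: float = DEFAULT_D):
    """Fisher information (D a)^2 P (1 - P); peaks at theta = b."""
    p = np.asarray(prob_correct(theta, a, b, D))
    a = np.broadcast_to(np.asarray(a, float), p.shape)
    out = (D * a) ** 2 * p * (1.0 - p)
    return out if out.ndim else float(out)


def quadrature_grid(n_nodes: int = 49, bound: float = 6.0):
    """Fixed quadrature under the N(0,1) prior: equally spaced nodes on
    [-bound, bound] with renormalized normal-density weights."""
    nodes = np.linspace(-bound, bound, n_nodes)
    w = norm.pdf(nodes)
    return nodes, w / w.sum()


@dataclass
class ItemParams:
    """Fitted 2PL parameters in slope/difficulty form."""

    indicator_ids: list[str]
    a: np.ndarray
    b: np.ndarray
    D: float = DEFAULT_D
    link: str = "logistic"
    quadrature_nodes: np.ndarray = field(default_factory=lambda: quadrature_grid()[0])
    quadrature_weights: np.ndarray = field(default_factory=lambda: quadrature_grid()[1])
    n_iterations: int = 0
    max_param_change: float = float("nan")
    log_likelihood: float = float("nan")

    def __post_init__(self):
        self.a = np.asarray(self.a, float)
        self.b = np.asarray(self.b, float)
        if not np.isclose(self.quadrature_weights.sum(), 1.0):
            raise ValueError("quadrature weights must sum to 1")

    def subset(self, indicator_ids) -> "ItemParams":
        idx = [self.indicator_ids.index(i) for i in indicator_ids]
        return ItemParams(
            indicator_ids=list(indicator_ids), a=self.a[idx], b=self.b[idx],
            D=self.D, link=self.link,
            quadrature_nodes=self.quadrature_nodes,
            quadrature_weights=self.quadrature_weights,
            n_iterations=self.n_iterations,
            max_param_change=self.max_param_change,
            log_likelihood=self.log_likelihood,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"a": self.a, "b": self.b}, index=pd.Index(self.indicator_ids, name="indicator_id")
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dict(
            indicator_ids=self.indicator_ids, a=self.a.tolist(), b=self.b.tolist(),
            D=self.D, link=self.link,
            convergence=dict(n_iterations=self.n_iterations,
                             max_param_change=self.max_param_change,
                             log_likelihood=self.log_likelihood),
        ), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ItemParams":
        obj = json.loads(Path(path).read_text())
        conv = obj.get("convergence", {})
        return cls(indicator_ids=obj["indicator_ids"], a=obj["a"], b=obj["b"],
                   D=obj["D"], link=obj.get("link", "logistic"),
                   n_iterations=conv.get("n_iterations", 0),
                   max_param_change=conv.get("max_param_change", float("nan")),
                   log_likelihood=conv.get("log_likelihood", float("nan")))


@dataclass
class ThetaEstimate:
    """Per-person EAP trait estimates with posterior SDs."""

    person_ids: list[str]
    eap: np.ndarray
    sd: np.ndarray
    n_observed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"eap": self.eap, "sd": self.sd, "n_items": self.n_observed},
            index=pd.Index(self.person_ids, name="person_id"),
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def test_information(theta, params: ItemParams, subset: list[str] | None = None):
    """Test information: sum of item informations over ``subset``."""
    ids = list(subset) if subset is not None else list(params.indicator_ids)
    if not ids:
        return np.zeros_like(np.asarray(theta, float)) if np.ndim(theta) else 0.0
    idx = [params.indicator_ids.index(i) for i in ids]
    theta_arr = np.asarray(theta, float)
    ti = sum(
        item_information(theta_arr, params.a[j], params.b[j], params.D) for j in idx
    )
    return ti if np.ndim(theta) else float(ti)


def _loglik_matrix(y: np.ndarray, p_nodes: np.ndarray):
    """Person x node log-likelihood of observed responses.

    ``y`` is persons x items with NaN missing; ``p_nodes`` nodes x items.
    """
    obs = ~np.isnan(y)
    y1 = np.where(obs, y, 0.0)
    y0 = np.where(obs, 1.0 - y, 0.0)
    logp = np.log(p_nodes)
    logq = np.log1p(-p_nodes)
    return y1 @ logp.T + y0 @ logq.T


def fit_2pl(
    matrix: ResponseMatrix,
    subset: list[str] | None = None,
    D: float = DEFAULT_D,
    n_nodes: int = 49,
    tol: float = 1e-4,
    max_iter: int = 500,
    min_items: int = 4,
) -> ItemParams:
    """Fit the 2PL by marginal maximum likelihood EM.

    E-step: posterior weights of each person over the fixed quadrature
    grid under the N(0,1) prior (missing responses contribute nothing).
    M-step: per-item weighted logistic regressions of expected correct
    counts on the nodes, solved by Newton-Raphson in slope/intercept form.
    Converges when the largest absolute change in any (a, b) falls below
    ``tol``. The marginal log-likelihood is checked to be non-decreasing
    every iteration (EM ascent property).
    """
    ids = list(subset) if subset is not None else matrix.indicator_ids
    if len(ids) < min_items:
        raise ValueError(f"need >= {min_items} indicators, got {len(ids)}")
    y = matrix.values[ids].to_numpy(float)
    obs = ~np.isnan(y)
    pos = np.nansum(y, axis=0)
    tot = obs.sum(axis=0)
    for j, ind in enumerate(ids):
        if pos[j] == 0 or pos[j] == tot[j]:
            raise ValueError(f"indicator {ind!r} has only one response category")

    nodes, weights = quadrature_grid(n_nodes)
    q, j_items = n_nodes, len(ids)
    # initialize from the point-biserial-ish heuristic: moderate slope,
    # difficulty from the marginal proportion
    a = np.full(j_items, 1.0)
    with np.errstate(divide="ignore"):
        b = np.clip(-norm.ppf(pos / tot) / 1.0, -4.0, 4.0)
    y1 = np.where(obs, y, 0.0)
    y0 = np.where(obs, 1.0 - y, 0.0)

    last_ll = -np.inf
    trace = []
    for it in range(1, max_iter + 1):
        p_nodes = prob_correct(nodes[:, None], a[None, :], b[None, :], D)
        p_nodes = np.clip(p_nodes, 1e-12, 1 - 1e-12)
        ll_mat = _loglik_matrix(y, p_nodes)  # persons x nodes
        ll_max = ll_mat.max(axis=1, keepdims=True)
        lik = np.exp(ll_mat - ll_max) * weights[None, :]
        norm_c = lik.sum(axis=1, keepdims=True)
        post = lik / norm_c
        ll = float((np.log(norm_c[:, 0]) + ll_max[:, 0]).sum())
        if ll < last_ll - 1e-6 * max(1.0, abs(ll)):
            raise ConvergenceError(
                f"log-likelihood decreased at iteration {it}", trace
            )
        last_ll = ll
        # expected counts per node
        r = post.T @ y1  # nodes x items: expected positives
        s = post.T @ y0  # expected negatives
        nq = r + s
        a_new = np.empty_like(a)
        b_new = np.empty_like(b)
        for j in range(j_items):
            beta = D * a[j]
            alpha = -D * a[j] * b[j]
            for _ in range(25):
                eta = alpha + beta * nodes
                pj = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
                w = nq[:, j] * pj * (1.0 - pj)
                g0 = float((r[:, j] - nq[:, j] * pj).sum())
                g1 = float(((r[:, j] - nq[:, j] * pj) * nodes).sum())
                h00 = float(w.sum())
                h01 = float((w * nodes).sum())
                h11 = float((w * nodes * nodes).sum())
                det = h00 * h11 - h01 * h01
                if det <= 1e-12:
                    break
                d_alpha = (h11 * g0 - h01 * g1) / det
                d_beta = (-h01 * g0 + h00 * g1) / det
                # dampen huge steps for stability
                step = max(abs(d_alpha), abs(d_beta))
                if step > 2.0:
                    d_alpha *= 2.0 / step
                    d_beta *= 2.0 / step
                alpha += d_alpha
                beta += d_beta
                if max(abs(d_alpha), abs(d_beta)) < 1e-10:
                    break
            beta = max(beta, 1e-6)  # identification: positive slope
            a_new[j] = beta / D
            b_new[j] = -alpha / beta
        delta = max(np.abs(a_new - a).max(), np.abs(b_new - b).max())
        a, b = a_new, b_new
        trace.append((it, ll, delta))
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations "
            f"(last max parameter change {delta:.2e})", trace
        )

    return ItemParams(
        indicator_ids=ids, a=a, b=b, D=D,
        quadrature_nodes=nodes, quadrature_weights=weights,
        n_iterations=it, max_param_change=float(delta), log_likelihood=last_ll,
    )


def eap_scores(
    matrix: ResponseMatrix,
    params: ItemParams,
    subset: list[str] | None = None,
) -> ThetaEstimate:
    """Expected a posteriori trait scores under the N(0,1) prior.

    Posterior mean and SD over the quadrature grid; persons with no
    observed responses on the subset get the prior back (theta = 0,
    SD = 1).
    """
    ids = list(subset) if subset is not None else list(params.indicator_ids)
    sub = params.subset(ids)
    y = matrix.values[ids].to_numpy(float)
    nodes, weights = sub.quadrature_nodes, sub.quadrature_weights
    p_nodes = prob_correct(nodes[:, None], sub.a[None, :], sub.b[None, :], sub.D)
    p_nodes = np.clip(p_nodes, 1e-12, 1 - 1e-12)
    ll = _loglik_matrix(y, p_nodes)
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll) * weights[None, :]
    post /= post.sum(axis=1, keepdims=True)
    eap = post @ nodes
    var = post @ (nodes**2) - eap**2
    sd = np.sqrt(np.maximum(var, 0.0))
    n_obs = (~np.isnan(y)).sum(axis=1)
    none = n_obs == 0
    eap[none] = 0.0
    sd[none] = 1.0
    return ThetaEstimate(
        person_ids=matrix.person_ids, eap=eap, sd=sd, n_observed=n_obs
    )


def marginal_reliability(
    params: ItemParams, subset: list[str] | None, theta_star: float
) -> float:
    """Reliability at theta*: TI / (TI + 1) under the unit-variance prior.

    Equals 1 - SE^2(theta*) with SE^2 = 1 / (TI + 1); 0 for an empty set.
    """
    if not np.isfinite(theta_star):
        raise ValueError("theta_star must be finite")
    ids = list(subset) if subset is not None else list(params.indicator_ids)
    if not ids:
        return 0.0
    ti = test_information(float(theta_star), params, ids)
    return float(ti / (ti + 1.0))
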