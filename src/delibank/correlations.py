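"""Tetrachoric correlations and local-dependency screening.

Dichotomous delirium indicators are modeled as thresholded bivariate
normals; the tetrachoric correlation is the maximum-likelihood latent
correlation given the 2x2 cross-tabulation. Pairs whose tables carry
structural voids (empty cells, e.g. from logically dependent indicator
pairs) or degenerate margins cannot be estimated and are flagged; an
iterative screen then drops the indicators most frequently involved in
inestimable pairs, honoring clinically forced retentions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from ._bvn import bvn_cdf
from .synthetic import ResponseMatrix

__all__ = [
    "TetrachoricResult",
    "ScreeningLog",
    "tetrachoric",
    "tetrachoric_matrix",
    "iterative_screen",
    "repair_psd",
]

#: degenerate-margin cutoff: a variable with fewer than this many positive
#: (or negative) responses in the pairwise complete cases is inestimable
MIN_MARGIN = 5

#: boundary cutoff: |rho| above this is treated as a boundary solution
RHO_BOUND = 0.995

_BISECT_ITER = 52  # interval 2 * 2^-52 ~ 4e-16


def _solve_rho(n11, n10, n01, n00):
    """Vectorized tetrachoric MLE via bisection on the BVN quadrant probability.

    Arguments are broadcastable count arrays. Returns (rho, tau_x, tau_y)
    where tau are the normal quantiles of the negative-response proportions.
    Cells where the margins are degenerate (a variable all 0 or all 1)
    return NaN.
    """
    n11, n10, n01, n00 = np.broadcast_arrays(
        *(np.asarray(x, float) for x in (n11, n10, n01, n00))
    )
    n = n11 + n10 + n01 + n00
    with np.errstate(invalid="ignore", divide="ignore"):
        p1x = (n11 + n10) / n
        p1y = (n11 + n01) / n
        p11 = n11 / n
        tau_x = ndtri(1.0 - p1x)
        tau_y = ndtri(1.0 - p1y)
    solvable = np.isfinite(tau_x) & np.isfinite(tau_y) & (n > 0)
    tx = np.where(solvable, tau_x, 0.0)
    ty = np.where(solvable, tau_y, 0.0)
    target = np.where(solvable, p11, 0.25)
    sx = 1.0 - ndtr(tx)
    sy = 1.0 - ndtr(ty)

    lo = np.full(n.shape, -1.0 + 1e-12)
    hi = np.full(n.shape, 1.0 - 1e-12)
    for _ in range(_BISECT_ITER):
        mid = 0.5 * (lo + hi)
        # survival P(X > tau_x, Y > tau_y) at correlation mid
        surv = sx + sy - 1.0 + bvn_cdf(tx, ty, mid)
        take_hi = surv < target
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    rho = 0.5 * (lo + hi)
    rho = np.where(solvable, rho, np.nan)
    return rho, tau_x, tau_y


def _estimable_mask(n11, n10, n01, n00, rho):
    """Apply the operational inestimability rule to solved tables."""
    counts = [np.asarray(x, float) for x in (n11, n10, n01, n00)]
    n11, n10, n01, n00 = counts
    n = n11 + n10 + n01 + n00
    void = (n11 == 0) | (n10 == 0) | (n01 == 0) | (n00 == 0)
    margin_x = np.minimum(n11 + n10, n01 + n00)
    margin_y = np.minimum(n11 + n01, n10 + n00)
    degenerate = (margin_x < MIN_MARGIN) | (margin_y < MIN_MARGIN)
    boundary = ~np.isfinite(rho) | (np.abs(rho) > RHO_BOUND)
    return (n > 0) & ~void & ~degenerate & ~boundary


def tetrachoric(table) -> tuple[float, bool]:
    """Tetrachoric correlation of one 2x2 table of counts.

    ``table`` is [[n11, n10], [n01, n00]] with the first index the row
    variable's response (1 then 0). Returns ``(rho, estimable)``; when the
    table has an empty cell, a degenerate margin (< MIN_MARGIN on either
    side for either variable), or the MLE sits at the |rho| boundary, the
    pair is flagged inestimable (rho is still the boundary/bisection value
    when one exists, NaN when no threshold is defined).
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    if t.sum() < 1:
        raise ValueError("table total must be >= 1")
    n11, n10, n01, n00 = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    rho, _, _ = _solve_rho(n11, n10, n01, n00)
    estimable = bool(_estimable_mask(n11, n10, n01, n00, rho))
    return float(rho), estimable


@dataclass
class TetrachoricResult:
    """Pairwise latent correlations with estimability bookkeeping.

    ``matrix`` holds the working correlations (inestimable entries set to
    0); ``raw`` keeps NaN at inestimable entries; ``estimable`` is the
    symmetric pair mask (diagonal True); ``thresholds`` are per-indicator
    normal quantiles of the negative-response proportion; ``n_pairs`` the
    complete-case counts per pair.
    """

    indicator_ids: list[str]
    matrix: np.ndarray
    raw: np.ndarray
    estimable: np.ndarray
    thresholds: np.ndarray
    n_pairs: np.ndarray
    n_persons: int = 0

    def repaired(self) -> np.ndarray:
        """PSD-repaired working matrix for eigen-analysis and factoring."""
        return repair_psd(self.matrix)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.indicator_ids,
                            columns=self.indicator_ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def repair_psd(matrix: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and rescale to unit diagonal."""
    m = np.asarray(matrix, float)
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    if w.min() >= floor:
        return (m + m.T) / 2.0
    fixed = (v * np.maximum(w, floor)) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _pairwise_counts(y: np.ndarray):
    """Complete-case 2x2 counts for every column pair of a 0/1/NaN matrix."""
    obs = ~np.isnan(y)
    a1 = np.where(obs, y, 0.0)
    a0 = np.where(obs, 1.0 - y, 0.0)
    n11 = a1.T @ a1
    n10 = a1.T @ a0
    n01 = a0.T @ a1
    n00 = a0.T @ a0
    return n11, n10, n01, n00


def tetrachoric_matrix_from_values(
    y: np.ndarray, indicator_ids: list[str]
) -> TetrachoricResult:
    """Tetrachoric matrix of a raw 0/1/NaN value array (internal fast path).

    Solves only the upper triangle and mirrors it; the bisection is the
    dominant cost inside the parallel-analysis permutation engine.
    """
    k = y.shape[1]
    n11, n10, n01, n00 = _pairwise_counts(y)
    iu, ju = np.triu_indices(k, 1)
    rho_u, _, _ = _solve_rho(n11[iu, ju], n10[iu, ju], n01[iu, ju], n00[iu, ju])
    est_u = _estimable_mask(n11[iu, ju], n10[iu, ju], n01[iu, ju], n00[iu, ju], rho_u)
    rho = np.zeros((k, k))
    rho[iu, ju] = rho_u
    rho += rho.T
    estimable = np.zeros((k, k), dtype=bool)
    estimable[iu, ju] = est_u
    estimable |= estimable.T
    np.fill_diagonal(estimable, True)
    raw = np.where(estimable, rho, np.nan)
    np.fill_diagonal(raw, 1.0)
    work = np.where(np.isnan(raw), 0.0, raw)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = ~np.isnan(y)
        neg = np.where(obs, 1.0 - y, 0.0).sum(axis=0)
        tot = obs.sum(axis=0)
        thresholds = ndtri(np.where(tot > 0, neg / np.maximum(tot, 1), 0.5))
    return TetrachoricResult(
        indicator_ids=list(indicator_ids),
        matrix=work,
        raw=raw,
        estimable=estimable & estimable.T,
        thresholds=thresholds,
        n_pairs=(n11 + n10 + n01 + n00),
        n_persons=int(y.shape[0]),
    )


def tetrachoric_matrix(
    matrix: ResponseMatrix, subset: list[str] | None = None
) -> TetrachoricResult:
    """Pairwise tetrachoric correlations over an indicator subset.

    Uses pairwise complete cases. Every pair is classified estimable or
    inestimable; an indicator with zero complete cases against all others
    is flagged throughout its row, not fatal.
    """
    ids = list(subset) if subset is not None else matrix.indicator_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 indicators")
    y = matrix.values[ids].to_numpy(float)
    return tetrachoric_matrix_from_values(y, ids)


@dataclass
class ScreeningLog:
    """Audit trail of the iterative multicollinearity screen."""

    dropped: list[tuple[str, int]] = field(default_factory=list)
    retained_forced: list[str] = field(default_factory=list)
    final_set: list[str] = field(default_factory=list)
    warning: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            dict(dropped=self.dropped, retained_forced=self.retained_forced,
                 final_set=self.final_set, warning=self.warning), indent=1))


def iterative_screen(
    matrix: ResponseMatrix,
    forced_retain: list[str] | tuple[str, ...] = (),
    subset: list[str] | None = None,
) -> ScreeningLog:
    """Iteratively drop indicators most involved in inestimable pairs.

    Repeatedly counts, per indicator, the number of inestimable pairs with
    other retained indicators, and drops the non-forced indicator with the
    highest count until no inestimable pair with a droppable member
    remains. Ties are broken by the more extreme marginal proportion
    (farther from 0.5), then lexicographically by indicator id, so the
    result is invariant to input column order. If inestimable pairs
    survive only between forced indicators, nothing more is dropped and a
    warning is recorded.
    """
    ids = list(subset) if subset is not None else matrix.indicator_ids
    if len(ids) < 3:
        raise ValueError("need at least 3 indicators to screen")
    forced = set(forced_retain)
    unknown = forced - set(ids)
    if unknown:
        raise KeyError(f"forced indicators not in matrix: {sorted(unknown)}")

    tet = tetrachoric_matrix(matrix, ids)
    bad = ~tet.estimable
    np.fill_diagonal(bad, False)
    y = matrix.values[ids].to_numpy(float)
    with np.errstate(invalid="ignore"):
        pbar = np.nanmean(y, axis=0)

    idx = {ind: i for i, ind in enumerate(ids)}
    current = list(ids)
    log = ScreeningLog(retained_forced=sorted(forced))
    for _ in range(len(ids)):
        cur = np.array([idx[c] for c in current])
        sub_bad = bad[np.ix_(cur, cur)]
        counts = sub_bad.sum(axis=1)
        nonforced = np.array([c not in forced for c in current])
        # a pair is resolvable only if at least one member can be dropped
        droppable_pair = sub_bad & (nonforced[:, None] | nonforced[None, :])
        if not droppable_pair.any():
            if sub_bad.any():
                log.warning = (
                    "inestimable pairs remain between forced-retain indicators"
                )
            break
        cand = np.flatnonzero(nonforced & (counts > 0))
        order = sorted(
            cand,
            key=lambda i: (-counts[i], -abs(pbar[cur[i]] - 0.5), current[i]),
        )
        victim = order[0]
        log.dropped.append((current[victim], int(counts[victim])))
        current.pop(victim)
    log.final_set = current
    return log
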