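"""Dimensionality assessment for indicator sets.

Decides how many latent dimensions an indicator set carries before IRT
modeling: permuted parallel analysis on the tetrachoric spectrum, an
exploratory factor analysis at the indicated number of factors, a
simple-structure confirmatory model, and a bifactor model (general factor
plus orthogonal specifics). The adjudication rule retains more than one
dimension only on a preponderance of evidence, and splits the indicator
set by the simple-structure pattern when it does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .correlations import TetrachoricResult, tetrachoric_matrix_from_values
from .synthetic import ResponseMatrix

__all__ = [
    "ParallelAnalysisResult",
    "FactorModelFit",
    "DimensionDecision",
    "eigenvalues",
    "permuted_parallel_analysis",
    "efa",
    "assign_simple_structure",
    "fit_cfa",
    "fit_bifactor",
    "fit_indices",
    "adjudicate_dimensions",
]

#: minimum indicators for a sub-set to be IRT-modeled after a split
MIN_MODELED = 4

#: CFI improvement of the m-factor CFA over the 1-factor CFA that counts
#: as evidence of multidimensionality
CFI_IMPROVEMENT = 0.01


# ---------------------------------------------------------------------------
# eigenvalues and parallel analysis


def eigenvalues(tet: TetrachoricResult) -> np.ndarray:
    """Full spectrum of the (PSD-repaired) tetrachoric matrix, descending."""
    w = np.linalg.eigvalsh(tet.repaired())
    return w[::-1]


@dataclass
class ParallelAnalysisResult:
    """Observed vs permutation-null eigenvalues and the significant count m."""

    observed_eigenvalues: np.ndarray
    permutation_quantiles: np.ndarray
    n_permutations: int
    m_significant: int
    seed: int | None
    quantile: float = 97.5
    n_redrawn: int = 0
    n_zero_filled: int = 0


def permuted_parallel_analysis(
    matrix: ResponseMatrix,
    subset: list[str] | None = None,
    n_permutations: int = 100,
    seed: int | None = None,
    quantile: float = 97.5,
    max_redraws: int = 5,
) -> ParallelAnalysisResult:
    """Permutation test on the eigenvalues of the tetrachoric matrix.

    Each permutation independently shuffles every indicator's responses
    across persons, which breaks all inter-indicator association while
    preserving each indicator's margin exactly; eigenvalues of the
    permuted tetrachoric matrix form the null reference. Root j is
    significant iff the observed root exceeds the ``quantile`` percentile
    of the permuted j-th roots; ``m_significant`` counts the leading run
    of significant roots (stops at the first failure).

    Permutations whose tetrachoric matrix contains inestimable pairs are
    redrawn up to ``max_redraws`` times (and logged); if a draw still
    contains inestimable pairs after the cap, those pairs enter the null
    matrix as 0 — their true association under the permutation null.
    """
    if n_permutations < 40:
        raise ValueError("need >= 40 permutations to resolve the 97.5th percentile")
    ids = list(subset) if subset is not None else matrix.indicator_ids
    y = matrix.values[ids].to_numpy(float)
    k = len(ids)
    tet = tetrachoric_matrix_from_values(y, ids)
    observed = eigenvalues(tet)

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, k))
    n_redrawn = 0
    n_zero_filled = 0
    offdiag = ~np.eye(k, dtype=bool)
    for p in range(n_permutations):
        for attempt in range(max_redraws + 1):
            yp = rng.permuted(y, axis=0)
            tp = tetrachoric_matrix_from_values(yp, ids)
            if tp.estimable[offdiag].all():
                break
            n_redrawn += 1
        else:
            n_zero_filled += 1
        null[p] = eigenvalues(tp)

    quantiles = np.percentile(null, quantile, axis=0)
    m = 0
    for j in range(k):
        if observed[j] > quantiles[j]:
            m += 1
        else:
            break
    return ParallelAnalysisResult(
        observed_eigenvalues=observed,
        permutation_quantiles=quantiles,
        n_permutations=n_permutations,
        m_significant=m,
        seed=seed,
        quantile=quantile,
        n_redrawn=n_redrawn,
        n_zero_filled=n_zero_filled,
    )


# ---------------------------------------------------------------------------
# factor models on the tetrachoric matrix


@dataclass
class FactorModelFit:
    """A fitted factor model with least-squares fit statistics.

    ``loadings`` is indicators x factors; for the bifactor model column 0
    is the general factor and the remaining columns the specifics.
    ``pattern`` maps indicator id -> factor index (None for EFA).
    """

    model_kind: str  # "EFA" | "CFA" | "BFA"
    m_factors: int
    indicator_ids: list[str]
    loadings: np.ndarray
    pattern: dict[str, int] | None
    factor_correlations: np.ndarray | None
    chi_square: float
    df: int
    CFI: float
    RMSEA: float
    discrepancy: float
    n: int
    large_secondary: bool | None = None
    converged: bool = True

    def loadings_frame(self) -> pd.DataFrame:
        m = self.loadings.shape[1]
        if self.model_kind == "BFA":
            cols = ["general"] + [f"specific{i}" for i in range(1, m)]
        else:
            cols = [f"factor{i + 1}" for i in range(m)]
        return pd.DataFrame(self.loadings, index=self.indicator_ids, columns=cols)


def fit_indices(
    chi_square: float, df: int, baseline_chi_square: float, baseline_df: int, n: int
) -> tuple[float, float]:
    """CFI and RMSEA from model and baseline chi-squares.

    CFI = 1 - max(chi2 - df, 0) / max(chi2_B - df_B, 0) (1 when the
    baseline excess is 0); RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1)))
    (0 when df = 0).
    """
    if df < 0 or baseline_df < 0:
        raise ValueError("degrees of freedom must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    excess = max(chi_square - df, 0.0)
    excess_b = max(baseline_chi_square - baseline_df, 0.0)
    cfi = 1.0 if excess_b == 0.0 else 1.0 - excess / excess_b
    cfi = min(max(cfi, 0.0), 1.0)
    rmsea = 0.0 if df == 0 else float(np.sqrt(excess / (df * (n - 1))))
    return cfi, rmsea


def _discrepancy(R: np.ndarray, sigma: np.ndarray) -> float:
    """Unweighted least-squares discrepancy over off-diagonal entries."""
    iu = np.triu_indices(R.shape[0], 1)
    d = R[iu] - sigma[iu]
    return float(d @ d)


def _fit_stats(R: np.ndarray, sigma: np.ndarray, df: int, n: int):
    """chi2 ~ (n-1) * F_min with F_min the ULS discrepancy; baseline = independence."""
    f = _discrepancy(R, sigma)
    f_b = _discrepancy(R, np.eye(R.shape[0]))
    p = R.shape[0]
    df_b = p * (p - 1) // 2
    chi2 = (n - 1) * f
    chi2_b = (n - 1) * f_b
    cfi, rmsea = fit_indices(chi2, df, chi2_b, df_b, n)
    return chi2, cfi, rmsea, f


def _clip_heywood(loadings: np.ndarray, bound: float = 0.995) -> np.ndarray:
    """Rescale any indicator's loading row whose communality exceeds 1."""
    h2 = (loadings**2).sum(axis=1)
    bad = h2 > bound
    if bad.any():
        warnings.warn(
            f"Heywood case: {int(bad.sum())} communality value(s) > 1 clipped",
            stacklevel=3,
        )
        scale = np.where(bad, np.sqrt(bound / h2), 1.0)
        loadings = loadings * scale[:, None]
    return loadings


def efa(tet: TetrachoricResult, m: int, n: int | None = None) -> FactorModelFit:
    """Exploratory factor analysis of the tetrachoric matrix.

    Principal-axis extraction (statsmodels) on the PSD-repaired matrix
    with promax (oblique) rotation when m >= 2; no rotation for m = 1.
    Fit statistics come from the unrotated solution (rotation leaves the
    implied correlation matrix unchanged).
    """
    from statsmodels.multivariate.factor import Factor
    from statsmodels.multivariate.factor_rotation import promax

    p = len(tet.indicator_ids)
    if not (1 <= m < p):
        raise ValueError("need 1 <= m < number of indicators")
    n = n or tet.n_persons
    R = tet.repaired()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = Factor(corr=pd.DataFrame(R), n_factor=m, method="pa", smc=True).fit()
    L = np.asarray(res.loadings, float)[:, :m]
    L = _clip_heywood(L)
    sigma = L @ L.T
    np.fill_diagonal(sigma, 1.0)
    # EFA df: correlations minus free loadings (less rotational indeterminacy)
    df = p * (p - 1) // 2 - (p * m - m * (m - 1) // 2)
    chi2, cfi, rmsea, f = _fit_stats(R, sigma, max(df, 0), n)
    phi = np.eye(m)
    if m >= 2:
        L, T = promax(L)
        phi = T.T @ T
        d = np.sqrt(np.diag(phi))
        phi = phi / np.outer(d, d)
    return FactorModelFit(
        model_kind="EFA", m_factors=m, indicator_ids=list(tet.indicator_ids),
        loadings=L, pattern=None, factor_correlations=phi,
        chi_square=chi2, df=max(df, 0), CFI=cfi, RMSEA=rmsea,
        discrepancy=f, n=n,
    )


def assign_simple_structure(fit: FactorModelFit) -> dict[str, int]:
    """Assign each indicator to the factor with its largest |loading|.

    Exact ties go to the lower factor index.
    """
    if fit.m_factors < 2:
        raise ValueError("simple-structure assignment needs m >= 2")
    absL = np.abs(fit.loadings)
    pattern = {}
    for i, ind in enumerate(fit.indicator_ids):
        pattern[ind] = int(np.argmax(absL[i]))  # argmax takes first on ties
    return pattern


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def _pattern_blocks(pattern: dict[str, int], ids: list[str]) -> list[list[int]]:
    m = max(pattern.values()) + 1
    blocks = [[] for _ in range(m)]
    for i, ind in enumerate(ids):
        blocks[pattern[ind]].append(i)
    return blocks


def fit_cfa(
    tet: TetrachoricResult, pattern: dict[str, int], n: int | None = None
) -> FactorModelFit:
    """Simple-structure CFA by unweighted least squares on the tetrachorics.

    Each indicator loads on exactly one factor; factor correlations are
    free (bounded away from +/-1). Minimizes the ULS discrepancy between
    observed and implied off-diagonal correlations.
    """
    ids = list(tet.indicator_ids)
    p = len(ids)
    n = n or tet.n_persons
    blocks = _pattern_blocks(pattern, ids)
    if any(len(b) < 2 for b in blocks):
        raise ValueError("every factor needs >= 2 indicators")
    m = len(blocks)
    R = tet.repaired()
    fac = np.empty(p, dtype=int)
    for f, b in enumerate(blocks):
        fac[b] = f
    i_phi = np.triu_indices(m, 1)

    def implied(x):
        lam, phi_v = x[:p], x[p:]
        phi = np.eye(m)
        phi[i_phi] = phi_v
        phi += np.triu(phi, 1).T
        sigma = (lam[:, None] * phi[np.ix_(fac, fac)]) * lam[None, :]
        return sigma

    iu = np.triu_indices(p, 1)

    def objective(x):
        d = R[iu] - implied(x)[iu]
        lam = x[:p]
        heywood = np.maximum(lam**2 - 0.995, 0.0)
        return d @ d + 10.0 * (heywood @ heywood)

    x0 = np.concatenate([np.full(p, 0.7), np.full(m * (m - 1) // 2, 0.3)])
    bounds = [(-1.2, 1.2)] * p + [(-0.99, 0.99)] * (m * (m - 1) // 2)
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options=dict(maxiter=2000, ftol=1e-14, gtol=1e-10))
    if not res.success and res.fun > 1e-8:
        raise ConvergenceError(f"CFA did not converge: {res.message}", res.x)
    lam, phi_v = res.x[:p], res.x[p:]
    phi = np.eye(m)
    phi[i_phi] = phi_v
    phi += np.triu(phi, 1).T
    L = np.zeros((p, m))
    L[np.arange(p), fac] = lam
    df = p * (p - 1) // 2 - p - m * (m - 1) // 2
    chi2, cfi, rmsea, f = _fit_stats(R, implied(res.x), max(df, 0), n)
    return FactorModelFit(
        model_kind="CFA", m_factors=m, indicator_ids=ids, loadings=L,
        pattern=dict(pattern), factor_correlations=phi,
        chi_square=chi2, df=max(df, 0), CFI=cfi, RMSEA=rmsea,
        discrepancy=f, n=n, converged=True,
    )


def fit_bifactor(
    tet: TetrachoricResult, pattern: dict[str, int], n: int | None = None
) -> FactorModelFit:
    """Bifactor model: one general factor on all indicators plus orthogonal
    specific factors following the simple-structure pattern.

    Factor correlations are constrained to zero. ``large_secondary`` is
    True iff any indicator's specific loading exceeds its general loading
    in absolute value. Specific factors with a single indicator have their
    loading fixed at zero (not identified from off-diagonal correlations).
    """
    ids = list(tet.indicator_ids)
    p = len(ids)
    n = n or tet.n_persons
    blocks = _pattern_blocks(pattern, ids)
    m = len(blocks)
    if m < 2:
        raise ValueError("bifactor model needs >= 2 specific factors")
    R = tet.repaired()
    fac = np.empty(p, dtype=int)
    for f, b in enumerate(blocks):
        fac[b] = f
    free_spec = np.array([len(blocks[fac[i]]) >= 2 for i in range(p)])
    same_block = fac[:, None] == fac[None, :]
    iu = np.triu_indices(p, 1)

    def implied(x):
        g, s = x[:p], x[p:].copy()
        s[~free_spec] = 0.0
        return np.outer(g, g) + np.outer(s, s) * same_block

    def objective(x):
        d = R[iu] - implied(x)[iu]
        # tiny ridge on specific loadings: when a block has no specific
        # variance its loadings are empirically underidentified from
        # off-diagonals; the penalty selects the minimal-norm solution. The
        # communality penalty keeps solutions off the Heywood boundary.
        s = x[p:]
        h2 = x[:p] ** 2 + s**2
        heywood = np.maximum(h2 - 0.995, 0.0)
        return d @ d + 1e-4 * (s @ s) + 10.0 * (heywood @ heywood)

    x0 = np.concatenate([np.full(p, 0.6), np.full(p, 0.3)])
    bounds = [(-1.2, 1.2)] * p + [(-1.0, 1.0)] * p
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options=dict(maxiter=4000, ftol=1e-14, gtol=1e-10))
    if not res.success and res.fun > 1e-8:
        raise ConvergenceError(f"bifactor model did not converge: {res.message}", res.x)
    g, s = res.x[:p], res.x[p:].copy()
    s[~free_spec] = 0.0
    # sign convention: general factor majority-positive, each specific too
    if np.sum(g) < 0:
        g = -g
    for f in range(m):
        if np.sum(s[fac == f]) < 0:
            s[fac == f] *= -1
    L = np.zeros((p, m + 1))
    L[:, 0] = g
    L[np.arange(p), fac + 1] = s
    df = p * (p - 1) // 2 - p - int(free_spec.sum())
    chi2, cfi, rmsea, fval = _fit_stats(R, implied(res.x), max(df, 0), n)
    large_secondary = bool((np.abs(s) > np.abs(g) + 1e-12).any())
    return FactorModelFit(
        model_kind="BFA", m_factors=m, indicator_ids=ids, loadings=L,
        pattern=dict(pattern), factor_correlations=np.eye(m + 1),
        chi_square=chi2, df=max(df, 0), CFI=cfi, RMSEA=rmsea,
        discrepancy=fval, n=n, large_secondary=large_secondary,
    )


# ---------------------------------------------------------------------------
# adjudication


@dataclass
class DimensionDecision:
    """Retained dimensionality and the resulting indicator sub-sets."""

    m_retained: int
    subsets: list[list[str]]
    modeled: list[bool]
    evidence: dict[str, bool] = field(default_factory=dict)


def adjudicate_dimensions(
    pa: ParallelAnalysisResult,
    fits: list[FactorModelFit],
    cfi_improvement: float = CFI_IMPROVEMENT,
    min_modeled: int = MIN_MODELED,
) -> DimensionDecision:
    """Decide the retained dimensionality by preponderance of evidence.

    One dimension is retained when parallel analysis finds at most one
    significant eigenvalue. Otherwise m > 1 is retained iff at least two
    of three signs hold: (a) m_significant > 1, (b) the m-factor CFA
    improves CFI over the 1-factor model by >= ``cfi_improvement``,
    (c) the bifactor model shows large secondary loadings. On a split,
    indicators are partitioned by the simple-structure pattern; sub-sets
    with fewer than ``min_modeled`` indicators are flagged not-modeled.
    """
    cfa1 = next((f for f in fits if f.model_kind == "CFA" and f.m_factors == 1), None)
    m = pa.m_significant
    cfam = next(
        (f for f in fits if f.model_kind == "CFA" and f.m_factors == m and m > 1), None
    )
    bfa = next((f for f in fits if f.model_kind == "BFA"), None)
    ids = fits[0].indicator_ids if fits else []

    if m <= 1:
        return DimensionDecision(
            m_retained=1, subsets=[list(ids)], modeled=[len(ids) >= min_modeled],
            evidence={"m_significant_gt1": False},
        )
    votes = {
        "m_significant_gt1": True,
        "cfi_improvement": bool(
            cfam is not None and cfa1 is not None
            and cfam.CFI - cfa1.CFI >= cfi_improvement
        ),
        "large_secondary": bool(bfa is not None and bfa.large_secondary),
    }
    if sum(votes.values()) >= 2:
        pattern = (cfam or bfa).pattern
        blocks = _pattern_blocks(pattern, ids)
        subsets = [[ids[i] for i in b] for b in blocks if b]
        return DimensionDecision(
            m_retained=len(subsets), subsets=subsets,
            modeled=[len(s) >= min_modeled for s in subsets], evidence=votes,
        )
    return DimensionDecision(
        m_retained=1, subsets=[list(ids)], modeled=[len(ids) >= min_modeled],
        evidence=votes,
    )
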