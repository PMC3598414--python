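"""Synthetic delirium-screening cohorts.

Generates persons x indicators binary response matrices with the structure
the downstream psychometric pipeline assumes: multidimensional 2PL item
responses on correlated latent traits, per-person CAM feature-positive
labels obtained by thresholding a designated latent trait (with optional
symmetric misclassification noise), completely-at-random missingness, and
logically dependent indicator pairs that produce structural voids in 2x2
cross-tabulations.

The default cohort mirrors a large post-acute-care delirium screening
sample: n = 4,598 evaluees, eight indicator sets (four CAM features, each
split into direct-interview and observational modes), ten latent
dimensions, and an overall CAM-delirium prevalence calibrated to 13.3%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

__all__ = [
    "ConfigurationError",
    "DimensionSpec",
    "CohortSpec",
    "SyntheticTruth",
    "ResponseMatrix",
    "default_cohort_spec",
    "generate_truth",
    "simulate_responses",
    "inject_logical_dependency",
    "calibrate_thresholds",
    "cam_positive_rate",
    "write_responses",
    "write_labels",
    "read_responses",
]

FEATURES = (1, 2, 3, 4)


class ConfigurationError(ValueError):
    """Raised when a cohort spec or truth object is internally inconsistent."""


# ---------------------------------------------------------------------------
# specs and truth


@dataclass
class DimensionSpec:
    """Shape of one latent dimension in a cohort spec.

    ``a_range``/``b_range`` bound the uniform draws of discrimination and
    difficulty; explicit ``a``/``b`` arrays override the draws.
    """

    dim_id: str
    feature: int
    mode: str  # "direct" | "observational"
    n_indicators: int = 0
    a_range: tuple[float, float] = (0.5, 3.5)
    b_range: tuple[float, float] = (-1.0, 4.5)
    a: list[float] | None = None
    b: list[float] | None = None
    indicator_ids: list[str] | None = None

    def __post_init__(self):
        if self.a is not None:
            self.n_indicators = len(self.a)
        if self.feature not in FEATURES:
            raise ConfigurationError(f"feature must be 1-4, got {self.feature}")
        if self.mode not in ("direct", "observational"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.n_indicators < 2:
            raise ConfigurationError(
                f"dimension {self.dim_id!r} has {self.n_indicators} indicators; "
                "at least 2 are required"
            )


@dataclass
class CohortSpec:
    """Generator configuration for :func:`generate_truth`."""

    dimensions: list[DimensionSpec]
    corr_within_feature: float = 0.6
    corr_between_feature: float = 0.45
    label_dimensions: dict[int, str] = field(default_factory=dict)
    base_feature_rates: dict[int, float] = field(
        default_factory=lambda: {1: 0.20, 2: 0.30, 3: 0.25, 4: 0.20}
    )
    target_prevalence: float = 0.133
    positivity_noise: float = 0.02
    missing_rate: float = 0.02
    dependency_pairs: list[tuple[str, str]] = field(default_factory=list)
    D: float = 1.7

    def __post_init__(self):
        if not self.dimensions:
            raise ConfigurationError("cohort spec must name at least one dimension")
        if not self.label_dimensions:
            # default: first dimension listed for each feature
            for d in self.dimensions:
                self.label_dimensions.setdefault(d.feature, d.dim_id)
        dim_ids = [d.dim_id for d in self.dimensions]
        if len(set(dim_ids)) != len(dim_ids):
            raise ConfigurationError("duplicate dimension ids")
        for f, did in self.label_dimensions.items():
            if did not in dim_ids:
                raise ConfigurationError(
                    f"label dimension {did!r} for feature {f} not in spec"
                )


@dataclass
class SyntheticTruth:
    """Fully specified generative model for a synthetic cohort."""

    dimensions: list[DimensionSpec]  # with a, b, indicator_ids filled in
    factor_correlations: np.ndarray  # dims x dims
    positivity_thresholds: dict[int, float]  # feature -> cut on latent trait
    label_dimensions: dict[int, str]
    positivity_noise: float
    missing_rate: float
    dependency_pairs: list[tuple[str, str]]
    seed: int
    D: float = 1.7

    def __post_init__(self):
        R = np.asarray(self.factor_correlations, float)
        k = len(self.dimensions)
        if R.shape != (k, k):
            raise ConfigurationError("factor_correlations shape mismatch")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ConfigurationError(
                "factor_correlations must be symmetric with unit diagonal"
            )
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ConfigurationError("factor_correlations is not positive definite")
        ids = self.indicator_ids
        if len(set(ids)) != len(ids):
            raise ConfigurationError("an indicator belongs to more than one dimension")
        for parent, child in self.dependency_pairs:
            if parent == child:
                raise ConfigurationError(f"dependency pair {parent!r} -> itself")
        self.factor_correlations = R

    @property
    def indicator_ids(self) -> list[str]:
        out = []
        for d in self.dimensions:
            out.extend(d.indicator_ids)
        return out

    @property
    def dim_index(self) -> dict[str, int]:
        """indicator id -> index of its dimension."""
        out = {}
        for i, d in enumerate(self.dimensions):
            for ind in d.indicator_ids:
                out[ind] = i
        return out

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.dimensions:
            for ind, a, b in zip(d.indicator_ids, d.a, d.b):
                rows.append(
                    dict(indicator_id=ind, dim_id=d.dim_id, feature=d.feature,
                         mode=d.mode, a=a, b=b)
                )
        return pd.DataFrame(rows).set_index("indicator_id")

    def to_json(self, path: str | Path) -> None:
        obj = asdict(self)
        obj["factor_correlations"] = self.factor_correlations.tolist()
        obj["positivity_thresholds"] = {
            str(k): v for k, v in self.positivity_thresholds.items()
        }
        obj["label_dimensions"] = {str(k): v for k, v in self.label_dimensions.items()}
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        obj = json.loads(Path(path).read_text())
        dims = [DimensionSpec(**{k: v for k, v in d.items()}) for d in obj.pop("dimensions")]
        for d in dims:
            if isinstance(d.a_range, list):
                d.a_range = tuple(d.a_range)
            if isinstance(d.b_range, list):
                d.b_range = tuple(d.b_range)
        return cls(
            dimensions=dims,
            factor_correlations=np.asarray(obj["factor_correlations"], float),
            positivity_thresholds={int(k): v for k, v in obj["positivity_thresholds"].items()},
            label_dimensions={int(k): v for k, v in obj["label_dimensions"].items()},
            positivity_noise=obj["positivity_noise"],
            missing_rate=obj["missing_rate"],
            dependency_pairs=[tuple(p) for p in obj["dependency_pairs"]],
            seed=obj["seed"],
            D=obj.get("D", 1.7),
        )


@dataclass
class ResponseMatrix:
    """Persons x indicators dichotomous responses with CAM feature labels.

    ``values`` holds 0.0 / 1.0 / NaN (missing). ``feature_labels`` has one
    column per CAM feature (``feature1`` .. ``feature4``), entries in {0, 1}.
    """

    values: pd.DataFrame
    feature_labels: pd.DataFrame | None = None

    def __post_init__(self):
        v = self.values.to_numpy(float)
        obs = ~np.isnan(v)
        if v.size:
            if not obs.any(axis=1).all():
                raise ConfigurationError("a person has no observed responses")
            if not obs.any(axis=0).all():
                raise ConfigurationError("an indicator has no observed responses")
            bad = v[obs]
            if not np.isin(bad, (0.0, 1.0)).all():
                raise ConfigurationError("responses must be 0, 1 or missing")
        if self.feature_labels is not None:
            lab = self.feature_labels.to_numpy()
            if np.isnan(np.asarray(lab, float)).any():
                raise ConfigurationError("feature labels must be complete")

    @property
    def person_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    def subset(self, indicator_ids) -> "ResponseMatrix":
        return ResponseMatrix(self.values[list(indicator_ids)], self.feature_labels)


# ---------------------------------------------------------------------------
# default cohort

_DEFAULT_LAYOUT = [
    # dim_id, feature, mode, n_indicators, b_range
    # Difficulty spans differ by feature: most symptom sets run from mild
    # to moderately severe (b up to ~3), while the altered-level-of-
    # consciousness observational items include very severe, rare signs
    # (stupor, agitation) reaching b ~ 4.5 — which is why that set alone
    # loses many indicators to degenerate margins at screening.
    ("f1_direct", 1, "direct", 15, (-1.0, 3.0)),
    ("f1_obs", 1, "observational", 11, (-1.0, 3.0)),
    ("f2_direct_orient", 2, "direct", 10, (-1.0, 2.5)),
    ("f2_direct_attn", 2, "direct", 5, (-1.0, 2.5)),
    ("f2_obs", 2, "observational", 8, (-1.0, 3.0)),
    ("f3_direct", 3, "direct", 13, (-1.0, 2.5)),
    ("f3_obs_main", 3, "observational", 10, (-1.0, 3.0)),
    ("f3_obs_minor", 3, "observational", 3, (-1.0, 3.0)),
    ("f4_direct", 4, "direct", 10, (-1.0, 2.5)),
    ("f4_obs", 4, "observational", 14, (-1.0, 4.5)),
]


def default_cohort_spec() -> CohortSpec:
    """The packaged default screening-cohort configuration.

    Ten latent dimensions across eight feature x mode indicator sets; two
    sets carry two dimensions each (inattention direct-interview and
    disorganized-thinking observational, the latter with a 3-indicator
    minor dimension that is reported but too small to model). One
    logically dependent indicator pair is planted in the acute-change
    observational set (a symptom-presence parent with a symptom-frequency
    child).
    """
    dims = [
        DimensionSpec(dim_id=d, feature=f, mode=m, n_indicators=n, b_range=b)
        for d, f, m, n, b in _DEFAULT_LAYOUT
    ]
    return CohortSpec(
        dimensions=dims,
        label_dimensions={1: "f1_obs", 2: "f2_direct_attn",
                          3: "f3_obs_main", 4: "f4_obs"},
        dependency_pairs=[("f1_obs_02", "f1_obs_03")],
    )


# ---------------------------------------------------------------------------
# prevalence calibration

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(101)


def cam_positive_rate(
    thresholds: np.ndarray,
    label_corr: np.ndarray,
    noise: float,
) -> float:
    """Exact CAM-delirium probability under the generative label model.

    ``thresholds`` are the four per-feature latent cuts; ``label_corr`` is
    the 4x4 correlation matrix of the four label traits and must be
    equicorrelated (one common factor), which the default cohort satisfies;
    ``noise`` is the symmetric misclassification probability per feature.

    Uses the one-factor reduction t_f = sqrt(rho) F + sqrt(1-rho) e_f and
    101-node Gauss-Hermite quadrature over F, so the result is
    deterministic to machine precision.
    """
    R = np.asarray(label_corr, float)
    off = R[~np.eye(4, dtype=bool)]
    rho = float(off.mean())
    if rho < 0 or np.abs(off - rho).max() > 1e-9:
        raise ConfigurationError(
            "label-trait correlations must be equicorrelated (>=0) for "
            "deterministic calibration"
        )
    lam = np.sqrt(rho)
    s = np.sqrt(1.0 - rho)
    f = np.sqrt(2.0) * _GH_NODES  # F ~ N(0,1)
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    c = np.asarray(thresholds, float)
    # q[f, node] = P(label_f = 1 | F)
    z = (c[:, None] - lam * f[None, :]) / s
    q_true = 1.0 - ndtr(z)
    q = (1.0 - noise) * q_true + noise * (1.0 - q_true)
    cam = q[0] * q[1] * (1.0 - (1.0 - q[2]) * (1.0 - q[3]))
    return float(np.sum(w * cam))


def calibrate_thresholds(
    base_rates: dict[int, float],
    label_corr: np.ndarray,
    noise: float,
    target: float,
) -> dict[int, float]:
    """Shift per-feature thresholds by a common delta to hit the CAM target.

    Base thresholds are the unit-normal quantiles Phi^-1(1 - p_f) of the
    requested marginal feature-positive rates; a single additive shift
    (shared across features, preserving the relative ordering of feature
    prevalences) is solved with Brent's method so that the Boolean CAM rule
    f1 & f2 & (f3 | f4) yields the target prevalence.
    """
    base = np.array([ndtri(1.0 - base_rates[f]) for f in FEATURES])

    def gap(delta):
        return cam_positive_rate(base + delta, label_corr, noise) - target

    delta = brentq(gap, -4.0, 4.0, xtol=1e-12)
    return {f: float(base[i] + delta) for i, f in enumerate(FEATURES)}


# ---------------------------------------------------------------------------
# operations


def generate_truth(spec: CohortSpec, seed: int) -> SyntheticTruth:
    """Draw a fully specified generative truth from a cohort spec.

    Deterministic: identical (spec, seed) produce identical truths. Item
    discriminations and difficulties are sampled uniformly within each
    dimension's configured ranges unless given explicitly; feature
    positivity thresholds are calibrated so the CAM rule hits the spec's
    target prevalence.
    """
    rng = np.random.default_rng(seed)
    k = len(spec.dimensions)
    R = np.full((k, k), spec.corr_between_feature)
    for i, di in enumerate(spec.dimensions):
        for j, dj in enumerate(spec.dimensions):
            if i != j and di.feature == dj.feature:
                R[i, j] = spec.corr_within_feature
    np.fill_diagonal(R, 1.0)

    dims = []
    for d in spec.dimensions:
        n = d.n_indicators
        a = np.array(d.a, float) if d.a is not None else rng.uniform(*d.a_range, n)
        b = np.array(d.b, float) if d.b is not None else rng.uniform(*d.b_range, n)
        ids = d.indicator_ids or [f"{d.dim_id}_{j:02d}" for j in range(n)]
        dims.append(
            DimensionSpec(dim_id=d.dim_id, feature=d.feature, mode=d.mode,
                          n_indicators=n, a_range=d.a_range, b_range=d.b_range,
                          a=list(a), b=list(b), indicator_ids=list(ids))
        )

    dim_ids = [d.dim_id for d in spec.dimensions]
    if set(spec.label_dimensions) == set(FEATURES):
        # full CAM cohort: calibrate the common threshold shift to the
        # target delirium prevalence under the Boolean CAM rule
        lab_idx = [dim_ids.index(spec.label_dimensions[f]) for f in FEATURES]
        thresholds = calibrate_thresholds(
            spec.base_feature_rates, R[np.ix_(lab_idx, lab_idx)],
            spec.positivity_noise, spec.target_prevalence,
        )
    else:
        # partial cohort: per-feature marginal rates taken at face value
        thresholds = {
            f: float(ndtri(1.0 - spec.base_feature_rates[f]))
            for f in spec.label_dimensions
        }
    return SyntheticTruth(
        dimensions=dims,
        factor_correlations=R,
        positivity_thresholds=thresholds,
        label_dimensions=dict(spec.label_dimensions),
        positivity_noise=spec.positivity_noise,
        missing_rate=spec.missing_rate,
        dependency_pairs=list(spec.dependency_pairs),
        seed=seed,
        D=spec.D,
    )


def simulate_responses(truth: SyntheticTruth, n_persons: int, seed: int) -> ResponseMatrix:
    """Simulate a cohort from a generative truth.

    Latent traits are multivariate normal with the truth's factor
    correlations; responses are Bernoulli draws from the 2PL curve
    P(y=1) = logistic(D a (theta - b)); feature labels threshold the
    designated label trait and are flipped with the misclassification
    probability; missingness is completely at random; logically dependent
    children are forced to 0 wherever the parent is 0.
    """
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    R = truth.factor_correlations
    if R.shape[0] != len(truth.dimensions):
        raise ConfigurationError("factor_correlations shape mismatch")
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as e:
        raise ValueError("factor_correlations is not positive definite") from e

    rng = np.random.default_rng(seed)
    k = R.shape[0]
    theta = rng.standard_normal((n_persons, k)) @ L.T

    ids = truth.indicator_ids
    a = np.concatenate([d.a for d in truth.dimensions])
    b = np.concatenate([d.b for d in truth.dimensions])
    dim_of = np.concatenate(
        [np.full(len(d.indicator_ids), i) for i, d in enumerate(truth.dimensions)]
    )
    z = truth.D * a[None, :] * (theta[:, dim_of] - b[None, :])
    p = 1.0 / (1.0 + np.exp(-z))
    y = (rng.random((n_persons, len(ids))) < p).astype(float)

    dim_ids = [d.dim_id for d in truth.dimensions]
    labels = np.zeros((n_persons, 4), dtype=int)
    for i, f in enumerate(FEATURES):
        if f not in truth.label_dimensions:
            continue
        t = theta[:, dim_ids.index(truth.label_dimensions[f])]
        labels[:, i] = (t > truth.positivity_thresholds[f]).astype(int)
    flips = rng.random((n_persons, 4)) < truth.positivity_noise
    labels = labels ^ flips

    # structural dependencies before missingness so complete-case
    # cross-tabs retain the (parent=0, child=1) void
    col = {ind: j for j, ind in enumerate(ids)}
    for parent, child in truth.dependency_pairs:
        y[y[:, col[parent]] == 0.0, col[child]] = 0.0

    if truth.missing_rate > 0:
        miss = rng.random(y.shape) < truth.missing_rate
        ymiss = np.where(miss, np.nan, y)
        # guarantee no fully-missing row or column
        for i in np.flatnonzero(np.isnan(ymiss).all(axis=1)):
            ymiss[i, 0] = y[i, 0]
        for j in np.flatnonzero(np.isnan(ymiss).all(axis=0)):
            ymiss[0, j] = y[0, j]
        y = ymiss

    persons = [f"p{i + 1:05d}" for i in range(n_persons)]
    values = pd.DataFrame(y, index=persons, columns=ids)
    feature_labels = pd.DataFrame(
        labels, index=persons, columns=[f"feature{f}" for f in FEATURES]
    )
    return ResponseMatrix(values=values, feature_labels=feature_labels)


def inject_logical_dependency(
    matrix: ResponseMatrix, parent: str, child: str
) -> ResponseMatrix:
    """Force ``child`` to 0 wherever ``parent`` is 0, creating a 2x2 void."""
    if parent == child:
        raise ValueError("parent and child must differ")
    for ind in (parent, child):
        if ind not in matrix.values.columns:
            raise KeyError(f"indicator {ind!r} not in matrix")
    values = matrix.values.copy()
    mask = values[parent] == 0.0
    values.loc[mask, child] = 0.0
    return ResponseMatrix(values=values, feature_labels=matrix.feature_labels)


# ---------------------------------------------------------------------------
# I/O


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    """Responses to CSV: indicator-id header, one row per person, missing empty."""
    out = matrix.values.copy()
    out.index.name = "person_id"
    # keep 0/1 unadorned in the CSV
    out.to_csv(path, float_format="%.0f")


def write_labels(matrix: ResponseMatrix, path: str | Path) -> None:
    if matrix.feature_labels is None:
        raise ValueError("matrix carries no feature labels")
    out = matrix.feature_labels.copy()
    out.index.name = "person_id"
    out.to_csv(path)


def read_responses(
    responses_csv: str | Path, labels_csv: str | Path | None = None
) -> ResponseMatrix:
    values = pd.read_csv(responses_csv, index_col="person_id").astype(float)
    labels = None
    if labels_csv is not None:
        labels = pd.read_csv(labels_csv, index_col="person_id").astype(int)
        labels = labels.loc[values.index]
    return ResponseMatrix(values=values, feature_labels=labels)
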