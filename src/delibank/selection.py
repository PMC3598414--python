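"""Information-targeted indicator selection for delirium screening.

The screening anchor theta_50+ is the median EAP trait score among
evaluees rated positive on a CAM feature; indicators are ranked by item
information evaluated at the anchor and the top five are retained.
Severe-symptom indicators (difficulty far above the anchor) rank low even
with large discriminations — they measure well only where screening does
not need precision. A sensitivity analysis re-ranks at the 25th and 75th
percentiles of the feature-positive trait distribution, and a fallback
rule moves the anchor to the 75th percentile when every indicator is
uninformative at the median.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import kendalltau

from .irt import ItemParams, ThetaEstimate, item_information

__all__ = [
    "SelectionResult",
    "CamResult",
    "theta_anchor",
    "rank_by_information",
    "select_top_k",
    "sensitivity_analysis",
    "apply_fallback",
    "cam_algorithm",
]

#: items whose best information at theta_50+ falls below this floor are
#: considered uninformative at the median (the information peak of an
#: a ~ 0.59 item at D = 1.7), triggering the 75th-percentile fallback
INFO_FLOOR = 0.25

DEFAULT_K = 5


def cam_algorithm(f1, f2, f3, f4):
    """CAM Boolean rule: delirium iff acute change with fluctuating course
    (f1) AND inattention (f2) AND (disorganized thinking (f3) OR altered
    level of consciousness (f4)). Accepts scalars or arrays."""
    f1, f2, f3, f4 = (np.asarray(f, bool) for f in (f1, f2, f3, f4))
    out = f1 & f2 & (f3 | f4)
    return bool(out) if out.ndim == 0 else out


@dataclass
class CamResult:
    """Per-person CAM feature presences and the derived delirium call."""

    person_ids: list[str]
    features: np.ndarray  # persons x 4 booleans
    delirium: np.ndarray  # persons booleans

    @classmethod
    def from_labels(cls, labels) -> "CamResult":
        """Build from a feature-labels DataFrame (feature1..feature4)."""
        f = labels.to_numpy().astype(bool)
        return cls(
            person_ids=list(labels.index),
            features=f,
            delirium=cam_algorithm(f[:, 0], f[:, 1], f[:, 2], f[:, 3]),
        )


def theta_anchor(scores: ThetaEstimate, labels, percentile: int = 50) -> float:
    """Percentile of EAP scores among feature-positive persons.

    ``labels`` is a boolean/0-1 array aligned with ``scores``;
    ``percentile`` is one of 25, 50, 75. Linear-interpolation quantile.
    """
    if percentile not in (25, 50, 75):
        raise ValueError("percentile must be 25, 50 or 75")
    lab = np.asarray(labels).astype(bool)
    if lab.shape[0] != len(scores.person_ids):
        raise ValueError("labels not aligned with scores")
    if not lab.any():
        raise ValueError(
            "no feature-positive persons: the anchor is undefined; "
            "check the labels passed for this feature"
        )
    return float(np.percentile(scores.eap[lab], percentile))


def rank_by_information(params: ItemParams, theta_star: float):
    """Rank indicators by information at theta*, descending.

    Ties break by smaller |b - theta*|, then lexicographically by id.
    Returns (ranking, info_at_star) with info keyed by indicator id.
    """
    info = {
        ind: float(item_information(theta_star, params.a[j], params.b[j], params.D))
        for j, ind in enumerate(params.indicator_ids)
    }
    dist = {
        ind: abs(float(params.b[j]) - theta_star)
        for j, ind in enumerate(params.indicator_ids)
    }
    ranking = sorted(info, key=lambda ind: (-info[ind], dist[ind], ind))
    return ranking, info


def select_top_k(ranking: list[str], k: int = DEFAULT_K) -> list[str]:
    """First min(k, len) ids of the ranking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return list(ranking[: min(k, len(ranking))])


@dataclass
class SelectionResult:
    """Anchored information ranking and the retained indicator set."""

    theta_star: float
    percentile_used: int
    info_at_star: dict[str, float]
    ranking: list[str]
    selected: list[str]
    fallback_triggered: bool = False
    sensitivity: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def run_selection(
    scores: ThetaEstimate,
    labels,
    params: ItemParams,
    k: int = DEFAULT_K,
    percentile: int = 50,
) -> SelectionResult:
    """Anchor, rank and select in one step (no fallback, no sensitivity)."""
    t = theta_anchor(scores, labels, percentile)
    ranking, info = rank_by_information(params, t)
    return SelectionResult(
        theta_star=t, percentile_used=percentile, info_at_star=info,
        ranking=ranking, selected=select_top_k(ranking, k),
    )


def sensitivity_analysis(
    scores: ThetaEstimate,
    labels,
    params: ItemParams,
    k: int = DEFAULT_K,
    overlap_threshold: int = 4,
) -> dict:
    """Re-rank at the 25th/50th/75th feature-positive percentiles.

    Reports the three rankings, pairwise top-k overlap counts, pairwise
    Kendall tau over the full rankings, and whether the selections are
    essentially the same (both outer percentiles agree with the median
    selection in >= ``overlap_threshold`` of k slots).
    """
    out = {"percentiles": {}, "top_k_overlap": {}, "kendall_tau": {}}
    rankings = {}
    for pct in (25, 50, 75):
        t = theta_anchor(scores, labels, pct)
        ranking, info = rank_by_information(params, t)
        rankings[pct] = ranking
        out["percentiles"][pct] = {
            "theta_star": t,
            "ranking": ranking,
            "selected": select_top_k(ranking, k),
        }
    ids = sorted(params.indicator_ids)
    for lo, hi in ((25, 50), (50, 75), (25, 75)):
        a = [rankings[lo].index(i) for i in ids]
        b = [rankings[hi].index(i) for i in ids]
        out["kendall_tau"][f"{lo}_vs_{hi}"] = float(kendalltau(a, b).statistic)
        sel_lo = set(select_top_k(rankings[lo], k))
        sel_hi = set(select_top_k(rankings[hi], k))
        out["top_k_overlap"][f"{lo}_vs_{hi}"] = len(sel_lo & sel_hi)
    out["essentially_same"] = bool(
        out["top_k_overlap"]["25_vs_50"] >= overlap_threshold
        and out["top_k_overlap"]["50_vs_75"] >= overlap_threshold
    )
    return out


def apply_fallback(
    result: SelectionResult,
    params: ItemParams,
    scores: ThetaEstimate,
    labels,
    floor: float = INFO_FLOOR,
    k: int = DEFAULT_K,
) -> SelectionResult:
    """Move the anchor to the 75th percentile when nothing is informative
    at the median.

    If the best item information at theta_50+ is below ``floor``, the
    anchor is recomputed at the 75th feature-positive percentile and the
    ranking and selection are redone there.
    """
    if result.percentile_used != 50:
        raise ValueError("fallback applies to a 50th-percentile selection")
    if result.info_at_star and max(result.info_at_star.values()) >= floor:
        return result
    t75 = theta_anchor(scores, labels, 75)
    ranking, info = rank_by_information(params, t75)
    return SelectionResult(
        theta_star=t75, percentile_used=75, info_at_star=info,
        ranking=ranking, selected=select_top_k(ranking, k),
        fallback_triggered=True, sensitivity=result.sensitivity,
    )
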