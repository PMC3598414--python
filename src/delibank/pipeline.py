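"""End-to-end item-bank construction workflow.

For each of the feature x mode indicator sets defined by an indicator
configuration, runs: local-dependency screening -> permuted parallel
analysis -> factor models (EFA / simple-structure CFA / bifactor) ->
dimensionality adjudication and splitting -> per-dimension 2PL fitting ->
EAP scoring -> anchored information ranking and top-k selection (with the
75th-percentile fallback) -> marginal reliability. Produces a report
shaped like the published dimensionality-summary and selection tables,
with a complete disposition audit for every input indicator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlations, dimensionality, irt, selection as sel
from .synthetic import ResponseMatrix, read_responses

__all__ = [
    "IndicatorEntry",
    "PipelineConfig",
    "PipelineReport",
    "run_pipeline",
    "report_render",
    "load_indicator_config",
]

logger = logging.getLogger("delibank.pipeline")


@dataclass
class IndicatorEntry:
    indicator_id: str
    feature: int
    mode: str
    forced_retain: bool = False
    source_item: str | None = None


def load_indicator_config(path: str | Path) -> list[IndicatorEntry]:
    raw = json.loads(Path(path).read_text())
    return [IndicatorEntry(**e) for e in raw]


def indicator_config_from_truth(truth) -> list[IndicatorEntry]:
    """Convenience: derive an indicator configuration from a synthetic truth."""
    out = []
    for d in truth.dimensions:
        for ind in d.indicator_ids:
            out.append(IndicatorEntry(ind, d.feature, d.mode))
    return out


@dataclass
class PipelineConfig:
    """Reproducible configuration for :func:`run_pipeline`.

    ``responses``/``labels``/``indicators`` may be in-memory objects or
    paths; the seed is mandatory and drives every stochastic stage.
    """

    responses: ResponseMatrix | str | Path
    indicators: list[IndicatorEntry] | str | Path
    labels: str | Path | None = None
    seed: int = 0
    n_permutations: int = 100
    D: float = 1.7
    n_nodes: int = 49
    k: int = 5
    fallback_floor: float = sel.INFO_FLOOR
    cfi_improvement: float = dimensionality.CFI_IMPROVEMENT
    min_modeled: int = dimensionality.MIN_MODELED
    overlap_threshold: int = 4
    output_dir: str | Path | None = None

    def resolve(self):
        matrix = (
            self.responses
            if isinstance(self.responses, ResponseMatrix)
            else read_responses(self.responses, self.labels)
        )
        entries = (
            self.indicators
            if isinstance(self.indicators, list)
            else load_indicator_config(self.indicators)
        )
        return matrix, entries


@dataclass
class DimensionReport:
    dim_label: str
    indicator_ids: list[str]
    modeled: bool
    status: str = "ok"  # ok | not_modeled | error
    error: str | None = None
    params: irt.ItemParams | None = None
    theta_star: float | None = None
    percentile_used: int | None = None
    fallback_triggered: bool = False
    reliability: float | None = None
    selected: list[str] = field(default_factory=list)
    ranking: list[str] = field(default_factory=list)
    info_at_star: dict[str, float] = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)


@dataclass
class SetReport:
    set_id: str
    feature: int
    mode: str
    proposed: list[str]
    status: str = "ok"  # ok | error
    error: str | None = None
    screening: correlations.ScreeningLog | None = None
    pa: dimensionality.ParallelAnalysisResult | None = None
    fits: list[dimensionality.FactorModelFit] = field(default_factory=list)
    decision: dimensionality.DimensionDecision | None = None
    dimensions: list[DimensionReport] = field(default_factory=list)

    def disposition(self) -> dict[str, str]:
        """indicator id -> selected | unselected | dropped_screening | not_modeled."""
        out = {}
        if self.screening is not None:
            for ind, _ in self.screening.dropped:
                out[ind] = "dropped_screening"
        for dim in self.dimensions:
            for ind in dim.indicator_ids:
                if dim.status != "ok":
                    out[ind] = "not_modeled"
                elif ind in dim.selected:
                    out[ind] = "selected"
                else:
                    out[ind] = "unselected"
        for ind in self.proposed:
            out.setdefault(ind, "not_modeled")
        return out


@dataclass
class PipelineReport:
    sets: dict[str, SetReport]
    seed: int

    # ------------------------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        """Dimensionality-summary table: one row per retained dimension."""
        rows = []
        for set_id, s in self.sets.items():
            cfa1 = next(
                (f for f in s.fits if f.model_kind == "CFA" and f.m_factors == 1),
                None,
            )
            cfam = next(
                (f for f in s.fits if f.model_kind == "CFA" and f.m_factors > 1),
                None,
            )
            bfa = next((f for f in s.fits if f.model_kind == "BFA"), None)
            for dim in s.dimensions or [None]:
                rows.append({
                    "set": set_id,
                    "feature": s.feature,
                    "mode": s.mode,
                    "dimension": dim.dim_label if dim else "n/a",
                    "n_proposed": len(s.proposed),
                    "n_modeled": len(dim.indicator_ids) if dim else 0,
                    "m_significant": s.pa.m_significant if s.pa else np.nan,
                    "retained_dimensions": (
                        s.decision.m_retained if s.decision else np.nan
                    ),
                    "cfi_1f": cfa1.CFI if cfa1 else np.nan,
                    "rmsea_1f": cfa1.RMSEA if cfa1 else np.nan,
                    "cfi_mf": cfam.CFI if cfam else np.nan,
                    "rmsea_mf": cfam.RMSEA if cfam else np.nan,
                    "large_secondary": bfa.large_secondary if bfa else None,
                    "marginal_reliability": dim.reliability if dim else np.nan,
                    "status": dim.status if dim else s.status,
                })
        return pd.DataFrame(rows)

    def selection_frame(self) -> pd.DataFrame:
        """Selection table: up to k rows per modeled dimension."""
        rows = []
        for set_id, s in self.sets.items():
            for dim in s.dimensions:
                if dim.status != "ok" or dim.params is None:
                    continue
                pf = dim.params.to_frame()
                for rank, ind in enumerate(dim.selected, start=1):
                    rows.append({
                        "set": set_id,
                        "dimension": dim.dim_label,
                        "theta_star": dim.theta_star,
                        "percentile": dim.percentile_used,
                        "rank": rank,
                        "indicator_id": ind,
                        "a": pf.loc[ind, "a"],
                        "b": pf.loc[ind, "b"],
                        "info_at_star": dim.info_at_star[ind],
                    })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        out = {"seed": self.seed, "sets": {}}
        for set_id, s in self.sets.items():
            sd = {
                "feature": s.feature, "mode": s.mode, "status": s.status,
                "error": s.error, "proposed": list(s.proposed),
                "disposition": s.disposition(),
            }
            if s.screening is not None:
                sd["screening"] = {
                    "dropped": conv(s.screening.dropped),
                    "retained_forced": s.screening.retained_forced,
                    "final_set": s.screening.final_set,
                    "warning": s.screening.warning,
                }
            if s.pa is not None:
                sd["parallel_analysis"] = {
                    "observed_eigenvalues": conv(s.pa.observed_eigenvalues),
                    "permutation_quantiles": conv(s.pa.permutation_quantiles),
                    "n_permutations": s.pa.n_permutations,
                    "m_significant": s.pa.m_significant,
                    "n_redrawn": s.pa.n_redrawn,
                }
            sd["fits"] = [
                {
                    "model": f.model_kind, "m": f.m_factors,
                    "chi_square": conv(f.chi_square), "df": f.df,
                    "CFI": conv(f.CFI), "RMSEA": conv(f.RMSEA),
                    "large_secondary": f.large_secondary,
                }
                for f in s.fits
            ]
            if s.decision is not None:
                sd["decision"] = {
                    "m_retained": s.decision.m_retained,
                    "subsets": s.decision.subsets,
                    "modeled": s.decision.modeled,
                    "evidence": s.decision.evidence,
                }
            sd["dimensions"] = []
            for dim in s.dimensions:
                dd = {
                    "label": dim.dim_label, "indicators": dim.indicator_ids,
                    "status": dim.status, "error": dim.error,
                    "theta_star": conv(dim.theta_star),
                    "percentile_used": dim.percentile_used,
                    "fallback_triggered": dim.fallback_triggered,
                    "marginal_reliability": conv(dim.reliability),
                    "selected": dim.selected,
                    "ranking": dim.ranking,
                    "info_at_star": conv(dim.info_at_star),
                    "sensitivity": conv(dim.sensitivity),
                }
                if dim.params is not None:
                    dd["item_parameters"] = {
                        "indicator_ids": dim.params.indicator_ids,
                        "a": conv(dim.params.a), "b": conv(dim.params.b),
                        "D": dim.params.D, "link": dim.params.link,
                    }
                sd["dimensions"].append(dd)
            out["sets"][set_id] = sd
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _set_seed(base: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full workflow over every feature x mode indicator set.

    Sets are processed independently; a failure in one set is recorded in
    its report while the others complete. Deterministic given (config,
    seed). Dimensions with fewer than ``min_modeled`` indicators are
    reported but not IRT-modeled.
    """
    matrix, entries = config.resolve()
    if matrix.feature_labels is None:
        raise ValueError("pipeline requires per-person CAM feature labels")
    sets: dict[str, list[IndicatorEntry]] = {}
    for e in entries:
        sets.setdefault(f"feature{e.feature}_{e.mode}", []).append(e)

    report = PipelineReport(sets={}, seed=config.seed)
    for set_index, set_id in enumerate(sorted(sets)):
        group = sets[set_id]
        feature, mode = group[0].feature, group[0].mode
        proposed = sorted(e.indicator_id for e in group)
        sr = SetReport(set_id=set_id, feature=feature, mode=mode, proposed=proposed)
        report.sets[set_id] = sr
        try:
            _run_set(sr, group, matrix, config, _set_seed(config.seed, set_index))
        except Exception as exc:  # per-set isolation
            logger.exception("set %s failed", set_id)
            sr.status = "error"
            sr.error = f"{type(exc).__name__}: {exc}"
    return report


def _run_set(
    sr: SetReport,
    group: list[IndicatorEntry],
    matrix: ResponseMatrix,
    config: PipelineConfig,
    set_seed: int,
) -> None:
    ids = sorted(e.indicator_id for e in group if e.indicator_id in matrix.values.columns)
    missing = sorted(set(e.indicator_id for e in group) - set(ids))
    if missing:
        raise KeyError(f"indicators not in response matrix: {missing}")
    forced = sorted(e.indicator_id for e in group if e.forced_retain)
    labels = matrix.feature_labels[f"feature{sr.feature}"].to_numpy()

    sr.screening = correlations.iterative_screen(matrix, forced, subset=ids)
    kept = sr.screening.final_set
    if len(kept) < config.min_modeled:
        sr.dimensions.append(DimensionReport(
            dim_label=f"{sr.set_id}_d1", indicator_ids=kept, modeled=False,
            status="not_modeled",
            error="fewer indicators than required for IRT modeling",
        ))
        return

    sr.pa = dimensionality.permuted_parallel_analysis(
        matrix, kept, n_permutations=config.n_permutations, seed=set_seed
    )
    tet = correlations.tetrachoric_matrix(matrix, kept)
    m = sr.pa.m_significant
    sr.fits = [dimensionality.fit_cfa(tet, {i: 0 for i in kept})]
    if m > 1:
        e = dimensionality.efa(tet, m)
        sr.fits.insert(0, e)
        pattern = dimensionality.assign_simple_structure(e)
        if all(
            len(b) >= 2
            for b in dimensionality._pattern_blocks(pattern, kept)
        ):
            sr.fits.append(dimensionality.fit_cfa(tet, pattern))
            sr.fits.append(dimensionality.fit_bifactor(tet, pattern))
    sr.decision = dimensionality.adjudicate_dimensions(
        sr.pa, [f for f in sr.fits if f.model_kind != "EFA"],
        cfi_improvement=config.cfi_improvement, min_modeled=config.min_modeled,
    )

    for d, (subset, modeled) in enumerate(
        zip(sr.decision.subsets, sr.decision.modeled), start=1
    ):
        dim = DimensionReport(
            dim_label=f"{sr.set_id}_d{d}", indicator_ids=list(subset), modeled=modeled
        )
        sr.dimensions.append(dim)
        if not modeled:
            dim.status = "not_modeled"
            dim.error = "fewer indicators than required for IRT modeling"
            continue
        try:
            params = irt.fit_2pl(
                matrix, subset, D=config.D, n_nodes=config.n_nodes,
                min_items=config.min_modeled,
            )
            scores = irt.eap_scores(matrix, params, subset)
            result = sel.run_selection(scores, labels, params, k=config.k)
            result.sensitivity = sel.sensitivity_analysis(
                scores, labels, params, k=config.k,
                overlap_threshold=config.overlap_threshold,
            )
            result = sel.apply_fallback(
                result, params, scores, labels,
                floor=config.fallback_floor, k=config.k,
            )
            dim.params = params
            dim.theta_star = result.theta_star
            dim.percentile_used = result.percentile_used
            dim.fallback_triggered = result.fallback_triggered
            dim.selected = result.selected
            dim.ranking = result.ranking
            dim.info_at_star = result.info_at_star
            dim.sensitivity = result.sensitivity
            dim.reliability = irt.marginal_reliability(
                params, subset, result.theta_star
            )
        except Exception as exc:
            logger.exception("dimension %s failed", dim.dim_label)
            dim.status = "error"
            dim.error = f"{type(exc).__name__}: {exc}"


def report_render(report: PipelineReport, output_dir: str | Path) -> dict[str, Path]:
    """Write report.json plus the two summary CSV tables and a run log."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": out / "report.json",
        "table1": out / "table1.csv",
        "table3": out / "table3.csv",
        "log": out / "run.log",
    }
    paths["report"].write_text(report.to_json())
    report.summary_frame().to_csv(paths["table1"], index=False)
    report.selection_frame().to_csv(paths["table3"], index=False)
    lines = []
    for set_id, s in report.sets.items():
        lines.append(f"[{set_id}] status={s.status}")
        if s.screening:
            for ind, cnt in s.screening.dropped:
                lines.append(
                    f"  drop {ind}: {cnt} inestimable pairs (rule: most inestimable"
                    " pairs; ties by extreme margin, then id)"
                )
        if s.pa:
            lines.append(
                f"  parallel analysis: m_significant={s.pa.m_significant}"
                f" ({s.pa.n_permutations} permutations)"
            )
        if s.decision:
            lines.append(
                f"  retained {s.decision.m_retained} dimension(s);"
                f" evidence={s.decision.evidence}"
            )
        for dim in s.dimensions:
            if dim.status == "ok":
                lines.append(
                    f"  {dim.dim_label}: theta*={dim.theta_star:.3f}"
                    f" (pct {dim.percentile_used},"
                    f" fallback={dim.fallback_triggered})"
                    f" selected={dim.selected}"
                    f" reliability={dim.reliability:.3f}"
                )
            else:
                lines.append(f"  {dim.dim_label}: {dim.status} ({dim.error})")
    paths["log"].write_text("\n".join(lines) + "\n")
    return paths
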