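"""End-to-end orchestration of the five-stage validation pipeline.

Stages (in dependency order): ``item_selection`` (correlation network,
communities, centralities, four-strategy selection), ``efa`` (factorability,
parallel analysis, PAF + oblimin), ``invariance`` (configural/metric/scalar),
``validity`` (group test, ROC, Youden operating point), ``cfa`` (ordinal
confirmatory fit with omega), and ``extended`` (replication of validity and
CFA on a fresh replicate when the input is simulated).

All item-level analyses operate on recoded scores (reverse-coded items
mapped x -> 8 - x) so that every item discriminates in the same direction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from scalenet import classify, efa, network, stats
from scalenet.cfa import CfaSpec, fit_cfa, invariance_sequence
from scalenet.synthetic import (
    DEFAULT_REVERSE_ITEMS,
    Noninvariance,
    SimulationConfig,
    default_thresholds,
    generate_responses,
    induce_d_profile,
    two_factor_config,
)
from scalenet.types import CASE, ResponseMatrix

logger = logging.getLogger("scalenet")

SCHEMA_VERSION = 1
ALL_STAGES = ("item_selection", "efa", "invariance", "validity", "cfa", "extended")
FIXTURES = (
    "null_model",
    "two_factor_invariant",
    "metric_violation",
    "sample1_like",
    "sample3_like",
)


@dataclass
class PipelineConfig:
    """Run configuration: input data, stages, and per-stage parameters."""

    input: str | Path | SimulationConfig | ResponseMatrix
    stages: tuple[str, ...] = ("item_selection", "efa", "validity")
    network_threshold: float = 0.70
    walktrap_steps: int = 4
    selection: network.SelectionParams = field(default_factory=network.SelectionParams)
    n_factors: int | None = None  # None -> parallel analysis decides
    parallel_resamples: int = 1000
    cfa_spec: CfaSpec | str | Path | None = None  # "auto" builds it from the EFA
    reverse_items: frozenset[str] = DEFAULT_REVERSE_ITEMS
    roc_direction: str = "auto"
    seed: int = 0
    output_dir: str | Path | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if ("cfa" in self.stages or "invariance" in self.stages) and self.cfa_spec is None:
            raise ValueError(
                "stages 'cfa'/'invariance' need cfa_spec (a CfaSpec, a JSON path, "
                "or 'auto' together with the efa stage)"
            )
        if self.cfa_spec == "auto" and "efa" not in self.stages:
            raise ValueError("cfa_spec='auto' requires the efa stage")
        if "validity" in self.stages and "item_selection" not in self.stages:
            raise ValueError("the validity stage requires item_selection")
        if isinstance(self.input, (str, Path)) and not Path(self.input).exists():
            raise ValueError(f"input path does not exist: {self.input}")


@dataclass
class ReportBundle:
    stages: dict[str, dict]
    metadata: dict
    warnings: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return _jsonable(
            {
                "schema_version": SCHEMA_VERSION,
                "metadata": self.metadata,
                "warnings": self.warnings,
                "stages": self.stages,
            }
        )

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.to_json_dict(), indent=2))
        for name, payload in self.stages.items():
            (out / f"stage_{name}.json").write_text(
                json.dumps(_jsonable(payload), indent=2)
            )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _recoded(matrix: ResponseMatrix, reverse: frozenset[str]) -> ResponseMatrix:
    values = matrix.values.copy()
    for j, item in enumerate(matrix.item_ids):
        if item in reverse:
            values[:, j] = 8 - values[:, j]
    return ResponseMatrix(
        values=values,
        group=matrix.group.copy(),
        item_ids=list(matrix.item_ids),
        participant_ids=list(matrix.participant_ids),
    )


def _load_input(config: PipelineConfig) -> ResponseMatrix:
    if isinstance(config.input, ResponseMatrix):
        return config.input
    if isinstance(config.input, SimulationConfig):
        return generate_responses(config.input)
    return ResponseMatrix.from_csv(config.input)


def _load_cfa_spec(config: PipelineConfig, report: dict) -> CfaSpec:
    if isinstance(config.cfa_spec, CfaSpec):
        return config.cfa_spec
    if config.cfa_spec == "auto":
        sol = report["efa"]["_solution"]
        assign = np.argmax(np.abs(sol.loadings), axis=1)
        fmap = {
            f"F{f + 1}": [it for it, a in zip(sol.item_ids, assign) if a == f]
            for f in range(sol.loadings.shape[1])
        }
        fmap = {k: v for k, v in fmap.items() if v}
        return CfaSpec(factor_map=fmap)
    payload = json.loads(Path(config.cfa_spec).read_text())
    return CfaSpec(
        factor_map=payload["factor_map"],
        error_covariances=[tuple(p) for p in payload.get("error_covariances", [])],
        estimator=payload.get("estimator", "dwls"),
        identification=payload.get("identification", "variance_std"),
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the requested stages in dependency order; see module docstring."""
    config.validate()
    matrix = _load_input(config)
    recoded = _recoded(matrix, config.reverse_items)
    bundle = ReportBundle(
        stages={},
        metadata={
            "seed": config.seed,
            "n_participants": matrix.n_participants,
            "n_items": matrix.n_items,
            "stages": list(config.stages),
        },
    )
    report = bundle.stages
    selected: list[str] | None = None

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            if stage == "item_selection":
                report[stage] = _stage_item_selection(recoded, config)
                selected = report[stage]["selected"]
            elif stage == "efa":
                items = selected or list(recoded.item_ids)
                report[stage] = _stage_efa(recoded.subset(items), config)
            elif stage == "invariance":
                spec = _load_cfa_spec(config, report)
                rep = invariance_sequence(recoded, spec, seed=config.seed + 17)
                report[stage] = {
                    "levels": {
                        k: {kk: vv for kk, vv in v.items() if kk != "params"}
                        for k, v in rep.levels.items()
                    },
                    "deltas": rep.deltas,
                    "chi_square_diffs": rep.chi_square_diffs,
                    "decisions": rep.decisions,
                    "converged": rep.converged,
                    "note": rep.note,
                }
            elif stage == "validity":
                report[stage] = _stage_validity(recoded, selected, config)
            elif stage == "cfa":
                spec = _load_cfa_spec(config, report)
                fit = fit_cfa(recoded, spec, seed=config.seed + 23)
                report[stage] = {
                    "fit": fit.fit,
                    "omega": fit.omega,
                    "loadings": fit.loading_vector(),
                    "factor_correlation": fit.phi,
                    "error_covariances": {
                        "-".join(k): v for k, v in fit.error_covariances.items()
                    },
                    "note": fit.note,
                }
            elif stage == "extended":
                report[stage] = _stage_extended(config, selected)
        except Exception as exc:  # noqa: BLE001 - recorded, downstream skipped
            logger.warning("stage %s failed: %s", stage, exc)
            report[stage] = {"error": str(exc)}
            bundle.warnings.append(f"stage {stage} failed: {exc}")

    # drop private cross-stage handles
    for payload in report.values():
        payload.pop("_solution", None)
    if config.output_dir is not None:
        bundle.write(config.output_dir)
    return bundle


def _stage_item_selection(recoded: ResponseMatrix, config: PipelineConfig) -> dict:
    d_values = stats.item_level_d(recoded)
    corr = np.corrcoef(recoded.values.astype(float), rowvar=False)
    net = network.build_network(corr, config.network_threshold, list(recoded.item_ids))
    part = network.walktrap_communities(net, steps=config.walktrap_steps)
    cent = network.centralities(net)
    sel = network.select_items(d_values, net, part, cent, config.selection)
    alpha_full = stats.cronbach_alpha(recoded)
    alpha_sel = stats.cronbach_alpha(recoded, sel.selected)
    mean_d_sel = float(np.mean([d_values[i] for i in sel.selected]))
    mean_d_full = float(np.mean(list(d_values.values())))
    return {
        "d_values": d_values,
        "n_networked": len(net.nodes),
        "n_isolated": len(net.isolated_items),
        "n_communities": part.n_communities,
        "community_sizes": part.sizes,
        "selected": sel.selected,
        "provenance": {k: sorted(v) for k, v in sel.provenance.items()},
        "communities_covered": sel.communities_covered,
        "alpha_full": alpha_full,
        "alpha_selected": alpha_sel,
        "alpha_retention": alpha_sel / alpha_full,
        "mean_d_selected": mean_d_sel,
        "mean_d_full": mean_d_full,
        "d_improvement": mean_d_sel / mean_d_full - 1.0,
    }


def _stage_efa(sub: ResponseMatrix, config: PipelineConfig) -> dict:
    corr = np.corrcoef(sub.values.astype(float), rowvar=False)
    kmo_overall, _ = efa.kmo(corr)
    chi2_b, df_b, p_b = efa.bartlett_sphericity(corr, sub.n_participants)
    pa = efa.parallel_analysis(
        sub, n_resamples=config.parallel_resamples, seed=config.seed + 3
    )
    k = config.n_factors if config.n_factors is not None else max(pa.n_factors, 1)
    sol = efa.fit_efa(sub, n_factors=k)
    return {
        "kmo": kmo_overall,
        "bartlett": {"chi_square": chi2_b, "df": df_b, "p": p_b},
        "parallel_n_factors": pa.n_factors,
        "n_factors_used": k,
        "loadings": sol.loadings,
        "factor_correlation": sol.phi,
        "communalities": sol.communalities,
        "variance_explained": sol.variance_explained,
        "total_variance_explained": sol.total_variance_explained,
        "fit": sol.fit,
        "score_reliability": {
            k2: np.asarray(v) for k2, v in sol.score_reliability.items()
        },
        "item_ids": sol.item_ids,
        "_solution": sol,
    }


def _stage_validity(
    recoded: ResponseMatrix, selected: list[str] | None, config: PipelineConfig
) -> dict:
    items = selected or list(recoded.item_ids)
    # recoded matrix already reverse-corrected, so plain sums
    totals = stats.score_total(recoded, items)
    mask = recoded.group_mask(CASE)
    a = stats.GroupSummary.from_values(totals[mask])
    b = stats.GroupSummary.from_values(totals[~mask])
    t, df, p = stats.welch_t(a, b)
    d = stats.cohens_d(a, b)
    roc_res = classify.roc(totals, recoded.group, direction=config.roc_direction)
    thr, sens, spec_, _ = classify.youden_optimal(roc_res)
    counts = classify.classify_at(totals, recoded.group, thr, flipped=roc_res.flipped)
    sens_c, spec_c, acc_c = classify.confusion_metrics(counts)
    return {
        "items": items,
        "case_summary": {"mean": a.mean, "sd": a.sd, "n": a.n},
        "comparison_summary": {"mean": b.mean, "sd": b.sd, "n": b.n},
        "welch_t": t,
        "welch_df": df,
        "p": p,
        "cohens_d": d,
        "auc": roc_res.auc,
        "youden_threshold": thr,
        "sensitivity": sens_c,
        "specificity": spec_c,
        "accuracy": acc_c,
        "confusion": {
            "tp": counts.tp,
            "fp": counts.fp,
            "tn": counts.tn,
            "fn": counts.fn,
        },
    }


def _stage_extended(config: PipelineConfig, selected: list[str] | None) -> dict:
    if not isinstance(config.input, SimulationConfig):
        return {"skipped": "extended replication needs a simulated input"}
    replicate_cfg = SimulationConfig(
        n_per_group=config.input.n_per_group,
        loadings=config.input.loadings.copy(),
        factor_correlation=config.input.factor_correlation.copy(),
        group_shift=config.input.group_shift.copy(),
        thresholds=config.input.thresholds.copy(),
        item_ids=list(config.input.item_ids),
        reverse_items=config.input.reverse_items,
        seed=(config.seed * 1009 + 7919) % (2**31),
    )
    replicate = _recoded(generate_responses(replicate_cfg), config.reverse_items)
    return {
        "replicate_seed": replicate_cfg.seed,
        "validity": _stage_validity(replicate, selected, config),
    }


# ---------------------------------------------------------------------------
# fixtures


def _fixture_config(name: str, seed: int) -> tuple[SimulationConfig, dict]:
    if name == "null_model":
        cfg = two_factor_config(n_per_group=(196, 196), n_items=65, seed=seed)
        truth = {"d_profile": [0.0] * 65}
    elif name in {"two_factor_invariant", "metric_violation"}:
        lam = np.zeros((18, 2))
        lam[:12, 0] = 0.7
        lam[12:, 1] = 0.7
        cfg = SimulationConfig(
            n_per_group=(500, 500),
            loadings=lam,
            factor_correlation=np.array([[1.0, 0.58], [0.58, 1.0]]),
            group_shift=np.zeros(18),
            thresholds=default_thresholds(18),
            reverse_items=frozenset(),
            seed=seed,
        )
        truth = {"loading": 0.7, "factor_correlation": 0.58, "d_profile": [0.0] * 18}
        if name == "metric_violation":
            delta = np.zeros((18, 2))
            delta[:4, 0] = -0.3
            cfg.noninvariance = Noninvariance(loading_delta=delta)
            truth["violated_items"] = ["IP1", "IP2", "IP3", "IP4"]
            truth["loading_delta"] = -0.3
    elif name in {"sample1_like", "sample3_like"}:
        n = (196, 196) if name == "sample1_like" else (30, 30)
        base = two_factor_config(n_per_group=n, n_items=65, seed=seed)
        target = np.linspace(0.80, 2.44, 65)
        cfg = induce_d_profile(target, base)
        truth = {
            "d_profile": target.tolist(),
            "loading": 0.7,
            "factor_correlation": 0.58,
            "reverse_items": sorted(cfg.reverse_items),
        }
    else:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    truth.update(
        {
            "fixture": name,
            "seed": seed,
            "loadings": cfg.loadings.tolist(),
            "factor_correlation_matrix": cfg.factor_correlation.tolist(),
            "group_shift": cfg.group_shift.tolist(),
        }
    )
    return cfg, truth


def make_fixture(
    name: str, seed: int, output_dir: str | Path | None = None
) -> tuple[ResponseMatrix, dict]:
    """Generate a named test fixture and its ground-truth record.

    Fixtures: null_model (no group effect), two_factor_invariant (12+6
    items, no group differences), metric_violation (four case-group
    loadings lowered by 0.3), sample1_like (196/196, 65 items, d profile
    spanning 0.80-2.44), sample3_like (30/30 version of the same).
    """
    cfg, truth = _fixture_config(name, seed)
    matrix = generate_responses(cfg)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        matrix.to_csv(out / f"{name}.csv")
        (out / f"{name}_truth.json").write_text(json.dumps(truth, indent=2))
    return matrix, truth
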