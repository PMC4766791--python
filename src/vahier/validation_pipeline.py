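"""Orchestration of the resampling validation experiment.

One replicate = draw a target CSMF for the scenario, resample the harmonized
death pool to match it, classify the sampled records under each hierarchy,
collapse "possible" causes, and score all four agreement metrics. Replicates
use independent child RNG streams split from one master seed; within a
replicate every hierarchy scores the identical resample, so hierarchy
comparisons are paired.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError
from .metrics import (
    ConfusionMatrix,
    chance_corrected_concordance,
    cohens_kappa,
    csmf_abs_diff,
    csmf_accuracy,
)
from .reference_harmonizer import CauseMap, ReferenceLabel, collapse_groups, harmonize_comorbid
from .rules_engine import (
    Hierarchy,
    RuleSet,
    UNSPECIFIED,
    VARecord,
    assign_primary_cause,
    evaluate_record,
)
from .scenario_resampler import (
    CountryCsmfTable,
    ScenarioSpec,
    draw_target_csmf,
    resample_to_target,
)

__all__ = [
    "ReplicateResult",
    "MetricSummary",
    "ValidationSummary",
    "run_replicate",
    "run_replicates",
    "run_validation",
    "summarize",
    "replicates_to_frame",
]

METRIC_NAMES = ("csmf_accuracy", "kappa", "ccc", "unclassified_fraction")


@dataclass(frozen=True)
class ReplicateResult:
    scenario: str
    hierarchy: str
    replicate_id: int
    csmf_accuracy: float
    kappa: float
    ccc: float
    per_cause_abs_diff: Mapping[str, float]
    unclassified_fraction: float


@dataclass(frozen=True)
class MetricSummary:
    median: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if not (self.range_low <= self.median <= self.range_high):
            raise UsageError("summary must satisfy low <= median <= high")


@dataclass(frozen=True)
class ValidationSummary:
    """Median-and-range summaries per (scenario, hierarchy, metric) and cause."""

    metrics: Mapping[tuple[str, str, str], MetricSummary]
    per_cause: Mapping[tuple[str, str, str], MetricSummary]
    replicates: int
    range_mode: str = "minmax"


# ---------------------------------------------------------------------------
# Classification cache
# ---------------------------------------------------------------------------

def _predictions(
    records: Sequence[VARecord],
    ruleset: RuleSet,
    hierarchies: Sequence[Hierarchy],
    cause_map: CauseMap,
) -> dict[str, dict[str, str]]:
    """Primary cause per death per hierarchy, with grouped causes collapsed.

    Rule evaluation is hierarchy-independent, so fired sets are computed once.
    """
    fired_by_death: dict[str, set[str]] = {}
    for record in records:
        if record.death_id in fired_by_death:
            raise UsageError(f"duplicate death_id {record.death_id!r}")
        fired_by_death[record.death_id] = evaluate_record(record, ruleset)
    out: dict[str, dict[str, str]] = {}
    for hierarchy in hierarchies:
        if hierarchy.age_group != ruleset.age_group:
            raise UsageError(
                f"hierarchy {hierarchy.name!r} is {hierarchy.age_group}, rule set "
                f"is {ruleset.age_group}"
            )
        assigned = {
            death_id: assign_primary_cause(fired, hierarchy)
            for death_id, fired in fired_by_death.items()
        }
        out[hierarchy.name] = collapse_groups(assigned, cause_map)
    return out


def _score_sample(
    sample_ids: Sequence[str],
    truth: Mapping[str, str],
    predicted: Mapping[str, str],
    *,
    scenario: str,
    hierarchy: str,
    replicate_id: int,
    fallback_cause: str = UNSPECIFIED,
) -> ReplicateResult:
    truth_s = {}
    pred_s = {}
    for i, death_id in enumerate(sample_ids):
        key = f"{i}:{death_id}"  # with-replacement draws may repeat ids
        truth_s[key] = truth[death_id]
        pred_s[key] = predicted[death_id]
    cause_list = sorted(set(truth_s.values()) | set(pred_s.values()))
    cm = ConfusionMatrix.from_labels(truth_s, pred_s, cause_list)
    n = len(sample_ids)
    true_csmf = {c: 0.0 for c in cause_list}
    pred_csmf = {c: 0.0 for c in cause_list}
    for c in truth_s.values():
        true_csmf[c] += 1.0 / n
    for c in pred_s.values():
        pred_csmf[c] += 1.0 / n
    return ReplicateResult(
        scenario=scenario,
        hierarchy=hierarchy,
        replicate_id=replicate_id,
        csmf_accuracy=csmf_accuracy(pred_csmf, true_csmf),
        kappa=cohens_kappa(cm),
        ccc=chance_corrected_concordance(cm),
        per_cause_abs_diff=csmf_abs_diff(pred_csmf, true_csmf),
        unclassified_fraction=sum(
            1 for c in pred_s.values() if c == fallback_cause
        ) / n,
    )


def _pool_by_cause(truth: Mapping[str, str]) -> dict[str, list[str]]:
    pool: dict[str, list[str]] = {}
    for death_id, cause in truth.items():
        pool.setdefault(cause, []).append(death_id)
    return pool


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def run_replicate(
    records: Sequence[VARecord],
    labels: Sequence[ReferenceLabel],
    ruleset: RuleSet,
    hierarchy: Hierarchy,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    *,
    table: CountryCsmfTable | None = None,
    n: int | None = None,
    cause_map: CauseMap | None = None,
    replicate_id: int = 0,
) -> ReplicateResult:
    """Run one full replicate for a single hierarchy.

    ``n`` defaults to the pool size. ``cause_map`` defaults to the identity
    (labels must then be single-cause).
    """
    cause_map = cause_map or CauseMap()
    truth = collapse_groups(harmonize_comorbid(labels, cause_map), cause_map)
    predicted = _predictions(records, ruleset, [hierarchy], cause_map)[hierarchy.name]
    missing = set(truth) - set(predicted)
    if missing:
        raise UsageError(f"labels without records: {sorted(missing)[:5]}")
    pool = _pool_by_cause(truth)
    size = n if n is not None else len(truth)
    target = draw_target_csmf(
        scenario, rng, table=table,
        causes=sorted(pool), age_group=ruleset.age_group,
    )
    sample_ids = resample_to_target(pool, target, size, rng)
    return _score_sample(
        sample_ids, truth, predicted,
        scenario=scenario.name, hierarchy=hierarchy.name,
        replicate_id=replicate_id, fallback_cause=hierarchy.fallback_cause,
    )


def run_replicates(
    records: Sequence[VARecord],
    labels: Sequence[ReferenceLabel],
    ruleset: RuleSet,
    hierarchies: Sequence[Hierarchy],
    scenario: ScenarioSpec,
    *,
    table: CountryCsmfTable | None = None,
    n: int | None = None,
    replicates: int = 1000,
    seed: int = 0,
    cause_map: CauseMap | None = None,
) -> list[ReplicateResult]:
    """All replicate results for one scenario across several hierarchies.

    Each replicate draws its own target and resample from an independent
    child stream of ``seed``; the identical resample is scored under every
    hierarchy (paired comparison).
    """
    if replicates < 1:
        raise UsageError("replicates must be >= 1")
    cause_map = cause_map or CauseMap()
    truth = collapse_groups(harmonize_comorbid(labels, cause_map), cause_map)
    predicted = _predictions(records, ruleset, hierarchies, cause_map)
    missing = set(truth) - {r.death_id for r in records}
    if missing:
        raise UsageError(f"labels without records: {sorted(missing)[:5]}")
    pool = _pool_by_cause(truth)
    size = n if n is not None else len(truth)
    streams = np.random.SeedSequence(seed).spawn(replicates)
    results: list[ReplicateResult] = []
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        target = draw_target_csmf(
            scenario, rng, table=table,
            causes=sorted(pool), age_group=ruleset.age_group,
        )
        sample_ids = resample_to_target(pool, target, size, rng)
        for hierarchy in hierarchies:
            results.append(
                _score_sample(
                    sample_ids, truth, predicted[hierarchy.name],
                    scenario=scenario.name, hierarchy=hierarchy.name,
                    replicate_id=rep, fallback_cause=hierarchy.fallback_cause,
                )
            )
    return results


def summarize(
    results: Sequence[ReplicateResult], *, range_mode: str = "minmax"
) -> ValidationSummary:
    """Median and range per (scenario, hierarchy, metric) and per cause.

    ``range_mode`` is ``"minmax"`` (default) or ``"percentile"`` (2.5–97.5).
    """
    if not results:
        raise UsageError("summarize needs at least one replicate result")
    if range_mode not in ("minmax", "percentile"):
        raise UsageError(f"unknown range_mode {range_mode!r}")

    def _summary(values: list[float]) -> MetricSummary:
        arr = np.asarray(values, dtype=float)
        if range_mode == "minmax":
            low, high = float(arr.min()), float(arr.max())
        else:
            low, high = (float(v) for v in np.percentile(arr, [2.5, 97.5]))
        return MetricSummary(float(np.median(arr)), low, high)

    metric_values: dict[tuple[str, str, str], list[float]] = {}
    cause_values: dict[tuple[str, str, str], list[float]] = {}
    for result in results:
        key = (result.scenario, result.hierarchy)
        for name in METRIC_NAMES:
            metric_values.setdefault((*key, name), []).append(getattr(result, name))
        for cause, diff in result.per_cause_abs_diff.items():
            cause_values.setdefault((*key, cause), []).append(diff)
    replicate_count = len({(r.scenario, r.hierarchy, r.replicate_id) for r in results})
    return ValidationSummary(
        metrics={k: _summary(v) for k, v in metric_values.items()},
        per_cause={k: _summary(v) for k, v in cause_values.items()},
        replicates=replicate_count,
        range_mode=range_mode,
    )


def run_validation(
    records: Sequence[VARecord],
    labels: Sequence[ReferenceLabel],
    ruleset: RuleSet,
    hierarchies: Sequence[Hierarchy],
    scenario: ScenarioSpec,
    *,
    table: CountryCsmfTable | None = None,
    n: int | None = None,
    replicates: int = 1000,
    seed: int = 0,
    cause_map: CauseMap | None = None,
    range_mode: str = "minmax",
) -> ValidationSummary:
    """Run the full experiment for one scenario and summarize it."""
    results = run_replicates(
        records, labels, ruleset, hierarchies, scenario,
        table=table, n=n, replicates=replicates, seed=seed, cause_map=cause_map,
    )
    return summarize(results, range_mode=range_mode)


def replicates_to_frame(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    """Tidy frame: scenario, hierarchy, replicate, metric, cause, value."""
    rows = []
    for result in results:
        base = {
            "scenario": result.scenario,
            "hierarchy": result.hierarchy,
            "replicate": result.replicate_id,
        }
        for name in METRIC_NAMES:
            rows.append({**base, "metric": name, "cause": "", "value": getattr(result, name)})
        for cause, diff in result.per_cause_abs_diff.items():
            rows.append({**base, "metric": "csmf_abs_diff", "cause": cause, "value": diff})
    return pd.DataFrame(rows, columns=["scenario", "hierarchy", "replicate", "metric", "cause", "value"])


def summary_to_frame(summary: ValidationSummary) -> pd.DataFrame:
    rows = []
    for (scenario, hierarchy, metric), s in summary.metrics.items():
        rows.append(
            {"scenario": scenario, "hierarchy": hierarchy, "metric": metric,
             "cause": "", "median": s.median, "range_low": s.range_low,
             "range_high": s.range_high}
        )
    for (scenario, hierarchy, cause), s in summary.per_cause.items():
        rows.append(
            {"scenario": scenario, "hierarchy": hierarchy, "metric": "csmf_abs_diff",
             "cause": cause, "median": s.median, "range_low": s.range_low,
             "range_high": s.range_high}
        )
    return pd.DataFrame(rows)
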