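"""Population- and individual-level agreement metrics.

Population level:

* CSMF accuracy — one minus the total absolute error between estimated and
  true cause fractions, scaled by the maximum possible error given the
  smallest true fraction:  ``1 - sum_j |pred_j - true_j| / (2 (1 - min_j true_j))``.
* Per-cause absolute CSMF difference.

Individual level (both from a true-by-predicted confusion matrix):

* Cohen's kappa — ``(p_o - p_e) / (1 - p_e)``, ranging -1..1.
* Chance-corrected concordance (CCC) — per-cause
  ``(sens_j - 1/N) / (1 - 1/N)`` averaged (unweighted) over causes with at
  least one reference death, ranging ``1/(1-N)``..1 for N causes.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .errors import MetricUndefinedError, UsageError
from .scenario_resampler import CauseDistribution

__all__ = [
    "ConfusionMatrix",
    "csmf_from_labels",
    "csmf_accuracy",
    "csmf_abs_diff",
    "cohens_kappa",
    "chance_corrected_concordance",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of (true cause, predicted cause) pairs over one dataset.

    ``counts[i, j]`` is the number of deaths with true cause ``cause_list[i]``
    predicted as ``cause_list[j]``.
    """

    cause_list: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.cause_list)
        if self.counts.shape != (k, k):
            raise UsageError("counts must be square over cause_list")
        if (self.counts < 0).any():
            raise UsageError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(
        cls,
        truth: Mapping[str, str],
        predicted: Mapping[str, str],
        cause_list: Sequence[str] | None = None,
    ) -> "ConfusionMatrix":
        if set(truth) != set(predicted):
            raise UsageError("truth and predictions must cover the same deaths")
        if cause_list is None:
            cause_list = sorted(set(truth.values()) | set(predicted.values()))
        index = {c: i for i, c in enumerate(cause_list)}
        counts = np.zeros((len(cause_list), len(cause_list)), dtype=np.int64)
        for death_id, true_cause in truth.items():
            counts[index[true_cause], index[predicted[death_id]]] += 1
        return cls(tuple(cause_list), counts)


def csmf_from_labels(
    labels: Mapping[str, str], cause_list: Sequence[str] | None = None
) -> CauseDistribution:
    """Empirical cause-specific mortality fractions from single-cause labels."""
    if not labels:
        raise UsageError("labels must be non-empty")
    tally = Counter(labels.values())
    if cause_list is None:
        cause_list = sorted(tally)
    else:
        unknown = set(tally) - set(cause_list)
        if unknown:
            raise UsageError(f"labels outside cause list: {sorted(unknown)}")
    n = len(labels)
    return CauseDistribution({c: tally.get(c, 0) / n for c in cause_list})


def _aligned(
    pred: Mapping[str, float], true: Mapping[str, float]
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    if isinstance(pred, CauseDistribution):
        pred = pred.fractions
    if isinstance(true, CauseDistribution):
        true = true.fractions
    if set(pred) != set(true):
        raise UsageError("pred and true must share the same cause list")
    causes = tuple(true)
    return (
        causes,
        np.array([pred[c] for c in causes], dtype=float),
        np.array([true[c] for c in causes], dtype=float),
    )


def csmf_accuracy(pred: Mapping[str, float], true: Mapping[str, float]) -> float:
    """CSMF accuracy of an estimated cause distribution against the truth.

    Accepts plain cause->fraction mappings (the fractions need not sum to one,
    e.g. when scoring a subset of causes) as well as
    :class:`~vahier.scenario_resampler.CauseDistribution` objects. Returns a
    value in [0, 1]; exactly 1 iff the distributions are identical.
    """
    causes, p, t = _aligned(pred, true)
    if len(causes) < 2:
        raise MetricUndefinedError("CSMF accuracy needs at least two causes")
    min_true = float(t.min())
    if min_true >= 1.0:
        raise MetricUndefinedError("degenerate truth: smallest cause fraction is 1")
    return float(1.0 - np.abs(p - t).sum() / (2.0 * (1.0 - min_true)))


def csmf_abs_diff(
    pred: Mapping[str, float], true: Mapping[str, float]
) -> dict[str, float]:
    """Per-cause absolute difference between estimated and true fractions."""
    causes, p, t = _aligned(pred, true)
    return {c: float(abs(pi - ti)) for c, pi, ti in zip(causes, p, t)}


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa of a confusion matrix; undefined when both margins are
    concentrated on a single cause (expected agreement 1)."""
    n = cm.n
    if n < 1:
        raise MetricUndefinedError("empty confusion matrix")
    counts = cm.counts.astype(float)
    p_observed = counts.trace() / n
    p_expected = float(counts.sum(axis=1) @ counts.sum(axis=0)) / (n * n)
    if p_expected >= 1.0:
        raise MetricUndefinedError("kappa undefined: expected agreement is 1")
    return float((p_observed - p_expected) / (1.0 - p_expected))


def chance_corrected_concordance(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-cause chance-corrected concordance.

    Per cause, ``(sensitivity - 1/N) / (1 - 1/N)`` with ``N`` the number of
    causes in the matrix; causes with no reference deaths are skipped (their
    sensitivity is undefined). At least one averaged cause is required.
    """
    n_causes = len(cm.cause_list)
    if n_causes < 2:
        raise MetricUndefinedError("CCC needs at least two causes")
    row_totals = cm.counts.sum(axis=1)
    chance = 1.0 / n_causes
    values = []
    for i, total in enumerate(row_totals):
        if total == 0:
            continue
        sensitivity = cm.counts[i, i] / total
        values.append((sensitivity - chance) / (1.0 - chance))
    if not values:
        raise MetricUndefinedError("no cause has reference deaths")
    return float(np.mean(values))
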