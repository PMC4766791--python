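"""Synthetic labelled deaths and questionnaire records for pipeline testing.

The generator draws reference causes from a configurable CSMF (optionally
replacing single causes with co-morbid sets at configured rates), then emits
VA records whose symptom responses satisfy each true cause's rule signature
with probability ``sensitivity``, satisfy each foreign cause's signature with
probability ``1 - specificity``, and answer unrelated binary symptoms "yes"
at a background rate. Signatures are derived from the same
:class:`~vahier.rules_engine.RuleSet` the classifier uses, so generator and
classifier share predicate semantics by construction.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import ModelError, UsageError
from .reference_harmonizer import ReferenceLabel
from .rules_engine import (
    And,
    Not,
    NumericAtom,
    Or,
    Predicate,
    RuleSet,
    SymptomAtom,
    VARecord,
)
from .scenario_resampler import CauseDistribution

__all__ = [
    "SymptomModel",
    "GeneratorConfig",
    "build_symptom_model",
    "generate_reference_deaths",
    "generate_va_records",
    "make_disjoint_ruleset",
]

#: default fixture seed
DEFAULT_SEED = 20160601


# ---------------------------------------------------------------------------
# Satisfying assignments
# ---------------------------------------------------------------------------

Assignment = dict[str, object]  # symptom -> "yes"/"no" (binary) or float (numeric)


def _merge(a: Assignment, b: Assignment) -> Assignment | None:
    out = dict(a)
    for key, value in b.items():
        if key in out and out[key] != value:
            return None
        out[key] = value
    return out


def _satisfying(pred: Predicate) -> Iterator[Assignment]:
    """Yield partial assignments making ``pred`` true (lazy, may repeat)."""
    if isinstance(pred, SymptomAtom):
        yield {pred.symptom: pred.response}
    elif isinstance(pred, NumericAtom):
        yield {pred.symptom: float(pred.value)}
    elif isinstance(pred, Or):
        for term in pred.terms:
            yield from _satisfying(term)
    elif isinstance(pred, And):
        generators = [list(itertools.islice(_satisfying(t), 8)) for t in pred.terms]
        for combo in itertools.product(*generators):
            merged: Assignment | None = {}
            for part in combo:
                merged = _merge(merged, part)
                if merged is None:
                    break
            if merged is not None:
                yield merged
    elif isinstance(pred, Not):
        yield from _falsifying(pred.term)
    else:  # pragma: no cover
        raise TypeError(f"unknown predicate node {type(pred).__name__}")


def _falsifying(pred: Predicate) -> Iterator[Assignment]:
    if isinstance(pred, SymptomAtom):
        other = "no" if pred.response == "yes" else "yes"
        yield {pred.symptom: other}
    elif isinstance(pred, NumericAtom):
        if pred.op == "ge":
            if pred.value > 0:
                yield {pred.symptom: max(pred.value - 1.0, 0.0)}
        else:
            yield {pred.symptom: pred.value + 1.0}
    elif isinstance(pred, And):
        for term in pred.terms:
            yield from _falsifying(term)
    elif isinstance(pred, Or):
        generators = [list(itertools.islice(_falsifying(t), 8)) for t in pred.terms]
        for combo in itertools.product(*generators):
            merged: Assignment | None = {}
            for part in combo:
                merged = _merge(merged, part)
                if merged is None:
                    break
            if merged is not None:
                yield merged
    elif isinstance(pred, Not):
        yield from _satisfying(pred.term)
    else:  # pragma: no cover
        raise TypeError(f"unknown predicate node {type(pred).__name__}")


def find_signature(pred: Predicate) -> Assignment | None:
    """First satisfying assignment of a predicate, or None if unsatisfiable."""
    for candidate in itertools.islice(_satisfying(pred), 4096):
        # re-check: a merged candidate may violate a sibling Not() branch
        record = _assignment_to_record("probe", "neonate", candidate)
        if pred.evaluate(record):
            return candidate
    return None


def _assignment_to_record(
    death_id: str, age_group: str, assignment: Assignment
) -> VARecord:
    responses = {k: v for k, v in assignment.items() if isinstance(v, str)}
    numerics = {k: float(v) for k, v in assignment.items() if not isinstance(v, str)}
    return VARecord(death_id, age_group, responses, numerics)


# ---------------------------------------------------------------------------
# Model and config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymptomModel:
    """Per-cause rule signatures with generation probabilities."""

    ruleset: RuleSet
    signatures: Mapping[str, Assignment]
    sensitivity: float
    specificity: float
    background_yes_rate: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "background_yes_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ModelError(f"{name} must be in [0,1], got {value}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Recipe for one synthetic cohort."""

    age_group: str
    csmf: CauseDistribution
    n: int
    comorbid_rates: Mapping[frozenset[str], float] = field(default_factory=dict)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n < 1:
            raise UsageError("n must be >= 1")
        support = set(self.csmf.causes)
        for combo, rate in self.comorbid_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise UsageError(f"comorbid rate for {sorted(combo)} out of [0,1]")
            missing = set(combo) - support
            if missing:
                raise UsageError(
                    f"comorbid set {sorted(combo)} names causes absent from the "
                    f"CSMF: {sorted(missing)}"
                )


def build_symptom_model(
    ruleset: RuleSet,
    sensitivity: float = 1.0,
    specificity: float = 1.0,
    background_yes_rate: float = 0.0,
) -> SymptomModel:
    """Precompute one satisfying assignment (signature) per cause rule."""
    signatures: dict[str, Assignment] = {}
    for rule in ruleset.rules:
        signature = find_signature(rule.predicate)
        if signature is None:
            raise ModelError(f"rule {rule.cause_id!r} has an unsatisfiable predicate")
        signatures[rule.cause_id] = signature
    return SymptomModel(ruleset, signatures, sensitivity, specificity, background_yes_rate)


def generate_reference_deaths(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[ReferenceLabel]:
    """Draw ``config.n`` labelled deaths; co-morbid sets replace single draws.

    Each death first draws one cause from the CSMF. For every configured
    co-morbid set containing that cause (in sorted order), the single label is
    replaced by the full set with the configured probability; the first hit
    wins.
    """
    causes = list(config.csmf.causes)
    probs = np.array([config.csmf[c] for c in causes], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(causes), size=config.n, p=probs)
    combos = sorted(config.comorbid_rates, key=lambda s: tuple(sorted(s)))
    labels = []
    for i, idx in enumerate(draws):
        cause = causes[int(idx)]
        chosen: frozenset[str] = frozenset([cause])
        for combo in combos:
            if cause in combo and rng.random() < config.comorbid_rates[combo]:
                chosen = frozenset(combo)
                break
        labels.append(ReferenceLabel(f"d{i:05d}", chosen, config.age_group))
    return labels


def generate_va_records(
    labels: Sequence[ReferenceLabel],
    model: SymptomModel,
    rng: np.random.Generator,
) -> list[VARecord]:
    """Emit one VA record per label under the symptom model.

    With probability ``sensitivity`` the record satisfies the union of its
    true causes' signatures (one draw per death, shared by co-morbid causes);
    each foreign cause's signature is imposed with probability
    ``1 - specificity`` on symptoms not already set; remaining binary
    symptoms answer "yes" at the background rate.
    """
    dictionary = model.ruleset.symptom_dictionary
    binary_symptoms = [s for s, d in dictionary.items() if d.kind == "binary"]
    cause_order = model.ruleset.cause_ids
    records = []
    for label in labels:
        unknown = set(label.causes) - set(model.signatures)
        if unknown:
            raise ModelError(
                f"death {label.death_id!r}: no signature for causes {sorted(unknown)}"
            )
        assignment: Assignment = {}
        if rng.random() < model.sensitivity:
            for cause in sorted(label.causes):
                assignment.update(model.signatures[cause])
        for cause in cause_order:
            if cause in label.causes:
                continue
            if rng.random() < 1.0 - model.specificity:
                for symptom, value in model.signatures[cause].items():
                    assignment.setdefault(symptom, value)
        responses = {}
        numerics = {}
        for symptom in binary_symptoms:
            value = assignment.get(symptom)
            if value is None:
                value = "yes" if (
                    model.background_yes_rate > 0
                    and rng.random() < model.background_yes_rate
                ) else "no"
            responses[symptom] = value  # type: ignore[assignment]
        for symptom, value in assignment.items():
            if not isinstance(value, str):
                numerics[symptom] = float(value)
        records.append(
            VARecord(label.death_id, label.age_group, responses, numerics)
        )
    return records


def make_disjoint_ruleset(causes: Sequence[str], age_group: str) -> RuleSet:
    """One-symptom-per-cause rule set with pairwise disjoint signatures.

    Convenience for noiseless end-to-end fixtures: cause ``c`` fires iff the
    dedicated symptom ``sx_<c>`` is "yes".
    """
    from .rules_engine import CauseRule, SymptomDef

    symptoms = {f"sx_{c}": SymptomDef(kind="binary", label=c) for c in causes}
    rules = tuple(
        CauseRule(c, SymptomAtom(f"sx_{c}", "yes")) for c in causes
    )
    return RuleSet(age_group=age_group, rules=rules, symptom_dictionary=symptoms)
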