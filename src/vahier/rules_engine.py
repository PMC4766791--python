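"""Expert-algorithm rule evaluation and hierarchical primary-cause selection.

An *expert algorithm* is a boolean combination of close-ended questionnaire
responses (signs and symptoms) judged predictive of a particular cause of
death. Evaluating the full rule set on one verbal-autopsy (VA) record yields
the set of all causes whose predicate fires; a *hierarchy* — an ordered list
of causes — then selects the single primary cause, with an "unspecified"
fallback when no rule fires.

The whole chain is deterministic: identical responses always produce the
identical primary cause.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import yaml

from .errors import HierarchyError, RuleConfigError, UsageError

logger = logging.getLogger(__name__)

AGE_GROUPS = ("neonate", "child")
RESPONSES = ("yes", "no", "dont_know", "missing")

#: fallback cause emitted when no rule fires
UNSPECIFIED = "unspecified"


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VARecord:
    """One death's close-ended questionnaire responses.

    Parameters
    ----------
    death_id
        Opaque identifier, unique within a dataset.
    age_group
        ``"neonate"`` (0–27 days) or ``"child"`` (1–59 months).
    responses
        Map of binary symptom id to one of ``yes / no / dont_know / missing``.
    numerics
        Map of numeric symptom id to a non-negative value (days, counts, ...).
    """

    death_id: str
    age_group: str
    responses: Mapping[str, str] = field(default_factory=dict)
    numerics: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise UsageError(f"unknown age_group {self.age_group!r}")
        for sid, resp in self.responses.items():
            if resp not in RESPONSES:
                raise UsageError(
                    f"record {self.death_id!r}: symptom {sid!r} has invalid "
                    f"response {resp!r}"
                )
        for sid, value in self.numerics.items():
            if sid in self.responses:
                raise UsageError(
                    f"record {self.death_id!r}: symptom {sid!r} is both binary "
                    "and numeric"
                )
            if value < 0:
                raise UsageError(
                    f"record {self.death_id!r}: numeric symptom {sid!r} is "
                    f"negative ({value})"
                )


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------

class Predicate:
    """Base class for boolean expression-tree nodes."""

    def evaluate(self, record: VARecord, *, dont_know_is_no: bool = False) -> bool:
        raise NotImplementedError

    def atoms(self) -> Iterator["Predicate"]:
        raise NotImplementedError

    def to_obj(self):
        raise NotImplementedError


@dataclass(frozen=True)
class SymptomAtom(Predicate):
    """``symptom == yes`` or ``symptom == no`` on a binary symptom.

    ``missing`` responses always make the atom false. ``dont_know`` is false
    by default; under the ``dont_know_is_no`` policy it is treated as an
    explicit "no".
    """

    symptom: str
    response: str  # "yes" | "no"

    def evaluate(self, record: VARecord, *, dont_know_is_no: bool = False) -> bool:
        observed = record.responses.get(self.symptom, "missing")
        if observed == "missing":
            return False
        if observed == "dont_know":
            observed = "no" if dont_know_is_no else "dont_know"
        return observed == self.response

    def atoms(self) -> Iterator[Predicate]:
        yield self

    def to_obj(self):
        return {"symptom": self.symptom, "response": self.response}


@dataclass(frozen=True)
class NumericAtom(Predicate):
    """Threshold comparison on a numeric symptom (``ge`` or ``le``).

    A missing numeric value makes the atom false.
    """

    symptom: str
    op: str  # "ge" | "le"
    value: float

    def evaluate(self, record: VARecord, *, dont_know_is_no: bool = False) -> bool:
        observed = record.numerics.get(self.symptom)
        if observed is None:
            return False
        return observed >= self.value if self.op == "ge" else observed <= self.value

    def atoms(self) -> Iterator[Predicate]:
        yield self

    def to_obj(self):
        return {"symptom": self.symptom, "op": self.op, "value": self.value}


@dataclass(frozen=True)
class And(Predicate):
    terms: tuple[Predicate, ...]

    def evaluate(self, record: VARecord, *, dont_know_is_no: bool = False) -> bool:
        return all(t.evaluate(record, dont_know_is_no=dont_know_is_no) for t in self.terms)

    def atoms(self) -> Iterator[Predicate]:
        for t in self.terms:
            yield from t.atoms()

    def to_obj(self):
        return {"all": [t.to_obj() for t in self.terms]}


@dataclass(frozen=True)
class Or(Predicate):
    terms: tuple[Predicate, ...]

    def evaluate(self, record: VARecord, *, dont_know_is_no: bool = False) -> bool:
        return any(t.evaluate(record, dont_know_is_no=dont_know_is_no) for t in self.terms)

    def atoms(self) -> Iterator[Predicate]:
        for t in self.terms:
            yield from t.atoms()

    def to_obj(self):
        return {"any": [t.to_obj() for t in self.terms]}


@dataclass(frozen=True)
class Not(Predicate):
    term: Predicate

    def evaluate(self, record: VARecord, *, dont_know_is_no: bool = False) -> bool:
        return not self.term.evaluate(record, dont_know_is_no=dont_know_is_no)

    def atoms(self) -> Iterator[Predicate]:
        yield from self.term.atoms()

    def to_obj(self):
        return {"not": self.term.to_obj()}


def _normalize_response(value) -> str:
    # YAML 1.1 parses bare yes/no as booleans; accept both spellings.
    if value is True:
        return "yes"
    if value is False:
        return "no"
    if isinstance(value, str) and value in ("yes", "no"):
        return value
    raise RuleConfigError(f"atom response must be yes/no, got {value!r}")


def predicate_from_obj(obj, context: str = "predicate") -> Predicate:
    """Build a :class:`Predicate` tree from its plain-object (YAML/JSON) form."""
    if not isinstance(obj, Mapping):
        raise RuleConfigError(f"{context}: expected a mapping, got {type(obj).__name__}")
    keys = set(obj)
    if keys == {"all"} or keys == {"any"}:
        (kind,) = keys
        items = obj[kind]
        if not isinstance(items, Sequence) or isinstance(items, (str, bytes)) or not items:
            raise RuleConfigError(f"{context}: '{kind}' needs a non-empty list")
        terms = tuple(
            predicate_from_obj(item, f"{context}.{kind}[{i}]")
            for i, item in enumerate(items)
        )
        return And(terms) if kind == "all" else Or(terms)
    if keys == {"not"}:
        return Not(predicate_from_obj(obj["not"], f"{context}.not"))
    if keys == {"symptom", "response"}:
        return SymptomAtom(str(obj["symptom"]), _normalize_response(obj["response"]))
    if keys == {"symptom", "op", "value"}:
        op = obj["op"]
        if op not in ("ge", "le"):
            raise RuleConfigError(f"{context}: unknown operator {op!r} (use ge/le)")
        try:
            value = float(obj["value"])
        except (TypeError, ValueError):
            raise RuleConfigError(f"{context}: non-numeric threshold {obj['value']!r}")
        return NumericAtom(str(obj["symptom"]), op, value)
    raise RuleConfigError(f"{context}: unrecognized node with keys {sorted(keys)}")


# ---------------------------------------------------------------------------
# Rule sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CauseRule:
    """A single cause's predicate."""

    cause_id: str
    predicate: Predicate


@dataclass(frozen=True)
class SymptomDef:
    kind: str  # "binary" | "numeric"
    label: str = ""
    unit: str = ""


@dataclass(frozen=True)
class RuleSet:
    """An ordered collection of cause rules plus their symptom dictionary."""

    age_group: str
    rules: tuple[CauseRule, ...]
    symptom_dictionary: Mapping[str, SymptomDef]
    dont_know_is_no: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rule in self.rules:
            if rule.cause_id in seen:
                raise RuleConfigError(f"duplicate cause_id {rule.cause_id!r}")
            seen.add(rule.cause_id)
            for atom in rule.predicate.atoms():
                sid = atom.symptom  # type: ignore[attr-defined]
                decl = self.symptom_dictionary.get(sid)
                if decl is None:
                    raise RuleConfigError(
                        f"rule {rule.cause_id!r}: undeclared symptom {sid!r}"
                    )
                want = "numeric" if isinstance(atom, NumericAtom) else "binary"
                if decl.kind != want:
                    raise RuleConfigError(
                        f"rule {rule.cause_id!r}: symptom {sid!r} is declared "
                        f"{decl.kind} but used as {want}"
                    )

    @property
    def cause_ids(self) -> tuple[str, ...]:
        return tuple(r.cause_id for r in self.rules)


def parse_ruleset(config_text: str) -> RuleSet:
    """Parse a YAML (or JSON) rule-set config into a validated :class:`RuleSet`.

    Schema::

        age_group: neonate | child
        options: {dont_know_is_no: bool}        # optional
        symptoms:
          <symptom_id>: {type: binary|numeric, label: str, unit: str}
        rules:
          - cause: <cause_id>
            predicate: <expression tree>

    where an expression tree is an atom (``{symptom, response}`` or
    ``{symptom, op, value}``) or a combinator (``{all: [...]}}``,
    ``{any: [...]}}``, ``{not: ...}``).
    """
    try:
        obj = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise RuleConfigError(f"config is not valid YAML/JSON: {exc}") from exc
    return ruleset_from_obj(obj)


def ruleset_from_obj(obj) -> RuleSet:
    if not isinstance(obj, Mapping):
        raise RuleConfigError("rule-set config must be a mapping")
    age_group = obj.get("age_group")
    if age_group not in AGE_GROUPS:
        raise RuleConfigError(f"age_group must be one of {AGE_GROUPS}, got {age_group!r}")
    symptoms_obj = obj.get("symptoms")
    if not isinstance(symptoms_obj, Mapping) or not symptoms_obj:
        raise RuleConfigError("'symptoms' must be a non-empty mapping")
    dictionary: dict[str, SymptomDef] = {}
    for sid, spec in symptoms_obj.items():
        if not isinstance(spec, Mapping) or spec.get("type") not in ("binary", "numeric"):
            raise RuleConfigError(f"symptom {sid!r}: type must be binary or numeric")
        dictionary[str(sid)] = SymptomDef(
            kind=spec["type"], label=str(spec.get("label", "")), unit=str(spec.get("unit", ""))
        )
    rules_obj = obj.get("rules")
    if not isinstance(rules_obj, Sequence) or not rules_obj:
        raise RuleConfigError("'rules' must be a non-empty list")
    rules = []
    for i, rule_obj in enumerate(rules_obj):
        if not isinstance(rule_obj, Mapping) or "cause" not in rule_obj or "predicate" not in rule_obj:
            raise RuleConfigError(f"rules[{i}]: needs 'cause' and 'predicate'")
        cause = str(rule_obj["cause"])
        predicate = predicate_from_obj(rule_obj["predicate"], f"rule {cause!r}")
        rules.append(CauseRule(cause, predicate))
    options = obj.get("options") or {}
    return RuleSet(
        age_group=age_group,
        rules=tuple(rules),
        symptom_dictionary=dictionary,
        dont_know_is_no=bool(options.get("dont_know_is_no", False)),
    )


def serialize_ruleset(ruleset: RuleSet) -> str:
    """Serialize a rule set back to YAML; round-trips through parse_ruleset."""
    obj = {
        "age_group": ruleset.age_group,
        "options": {"dont_know_is_no": ruleset.dont_know_is_no},
        "symptoms": {
            sid: {"type": d.kind, "label": d.label, "unit": d.unit}
            for sid, d in ruleset.symptom_dictionary.items()
        },
        "rules": [
            {"cause": r.cause_id, "predicate": r.predicate.to_obj()} for r in ruleset.rules
        ],
    }
    return yaml.safe_dump(obj, sort_keys=False, default_flow_style=False)


def evaluate_record(record: VARecord, ruleset: RuleSet) -> set[str]:
    """Return the ids of every cause whose predicate fires on ``record``."""
    if record.age_group != ruleset.age_group:
        raise UsageError(
            f"record {record.death_id!r} is {record.age_group}, rule set is "
            f"{ruleset.age_group}"
        )
    dk = ruleset.dont_know_is_no
    return {
        rule.cause_id
        for rule in ruleset.rules
        if rule.predicate.evaluate(record, dont_know_is_no=dk)
    }


# ---------------------------------------------------------------------------
# Hierarchies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hierarchy:
    """An ordered cause list used to pick one primary cause among several.

    ``ranks`` is a tuple of rank levels; a level may hold several causes tied
    at that level (ties are broken by the listed left-to-right order, logged
    at warn level). Causes in ``fallback_causes`` are explicitly mapped to the
    fallback: they can fire but are only reported when nothing ranked fires,
    in which case ``fallback_cause`` is returned.
    """

    name: str
    age_group: str
    ranks: tuple[tuple[str, ...], ...]
    fallback_cause: str = UNSPECIFIED
    fallback_causes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise RuleConfigError(f"hierarchy {self.name!r}: bad age_group")
        seen: set[str] = set()
        for level in self.ranks:
            for cause in level:
                if cause in seen:
                    raise RuleConfigError(
                        f"hierarchy {self.name!r}: cause {cause!r} appears twice"
                    )
                seen.add(cause)
        overlap = seen & self.fallback_causes
        if overlap:
            raise RuleConfigError(
                f"hierarchy {self.name!r}: causes both ranked and fallback: "
                f"{sorted(overlap)}"
            )

    @property
    def ranked_causes(self) -> tuple[str, ...]:
        return tuple(c for level in self.ranks for c in level)

    def rank_of(self, cause_id: str) -> tuple[int, int] | None:
        """(rank level, within-level position) of a cause, or None if unranked."""
        for i, level in enumerate(self.ranks):
            for j, cause in enumerate(level):
                if cause == cause_id:
                    return (i, j)
        return None


def hierarchy_from_obj(name: str, age_group: str, obj) -> Hierarchy:
    if not isinstance(obj, Mapping) or "ranks" not in obj:
        raise RuleConfigError(f"hierarchy {name!r}: needs a 'ranks' list")
    ranks = []
    for i, level in enumerate(obj["ranks"]):
        if isinstance(level, str):
            level = [level]
        if not isinstance(level, Sequence) or not level:
            raise RuleConfigError(f"hierarchy {name!r}: ranks[{i}] must be a non-empty list")
        ranks.append(tuple(str(c) for c in level))
    return Hierarchy(
        name=name,
        age_group=age_group,
        ranks=tuple(ranks),
        fallback_cause=str(obj.get("fallback", UNSPECIFIED)),
        fallback_causes=frozenset(str(c) for c in obj.get("fallback_causes", [])),
    )


def assign_primary_cause(fired: Iterable[str], hierarchy: Hierarchy) -> str:
    """Select the primary cause: the earliest-ranked member of ``fired``.

    An empty fired set — or one containing only fallback-mapped causes —
    yields the hierarchy's fallback cause. Within-rank ties are broken by the
    listed order and logged.
    """
    ranked: list[tuple[int, int, str]] = []
    for cause in fired:
        pos = hierarchy.rank_of(cause)
        if pos is None:
            if cause in hierarchy.fallback_causes:
                continue
            raise HierarchyError(
                f"hierarchy {hierarchy.name!r} does not map fired cause {cause!r}"
            )
        ranked.append((pos[0], pos[1], cause))
    if not ranked:
        return hierarchy.fallback_cause
    ranked.sort()
    top_level = ranked[0][0]
    tied = [c for lvl, _, c in ranked if lvl == top_level]
    if len(tied) > 1:
        logger.warning(
            "hierarchy %s: tie at rank %d among %s; keeping %s",
            hierarchy.name, top_level + 1, tied, ranked[0][2],
        )
    return ranked[0][2]


def classify_dataset(
    records: Sequence[VARecord], ruleset: RuleSet, hierarchy: Hierarchy
) -> dict[str, str]:
    """Assign one primary cause per death. Deterministic."""
    if hierarchy.age_group != ruleset.age_group:
        raise UsageError(
            f"hierarchy is {hierarchy.age_group}, rule set is {ruleset.age_group}"
        )
    out: dict[str, str] = {}
    for record in records:
        if record.death_id in out:
            raise UsageError(f"duplicate death_id {record.death_id!r}")
        fired = evaluate_record(record, ruleset)
        out[record.death_id] = assign_primary_cause(fired, hierarchy)
    return out
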