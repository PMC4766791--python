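"""Harmonization of reference-standard and VA-assigned causes before scoring.

Two jobs:

* map co-morbid reference cause sets to a single underlying cause, following
  ICD-10-style rules (a mode-of-perinatal-death condition such as prematurity
  is not the main condition unless it is the only one known), including
  deterministic proportional reallocation for three-way co-morbid sets;
* collapse "possible" VA causes into their definite scoring counterparts
  (possible pneumonia -> pneumonia, etc.).
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import yaml

from ._util import largest_remainder
from .errors import AllocationError, MappingError, RuleConfigError

__all__ = [
    "ReferenceLabel",
    "ComorbidRule",
    "CauseMap",
    "harmonize_comorbid",
    "collapse_groups",
    "cause_map_from_obj",
    "parse_cause_map",
]


@dataclass(frozen=True)
class ReferenceLabel:
    """Reference-standard cause(s) for one death; co-morbid sets allowed."""

    death_id: str
    causes: frozenset[str]
    age_group: str

    def __post_init__(self) -> None:
        if not self.causes:
            raise MappingError(f"death {self.death_id!r}: empty reference cause set")


@dataclass(frozen=True)
class ComorbidRule:
    """Exact-match rule for one co-morbid cause set.

    Either ``target`` names the single underlying cause, or ``proportional``
    names >= 2 targets over which matching deaths are split in the ratio of
    deaths already singly assigned to those targets.
    """

    pattern: frozenset[str]
    target: str | None = None
    proportional: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.target is None) == (not self.proportional):
            raise RuleConfigError("comorbid rule needs exactly one of target/proportional")
        if self.proportional and len(self.proportional) < 2:
            raise RuleConfigError("proportional rule must name >= 2 targets")


@dataclass(frozen=True)
class CauseMap:
    """Reference-to-scoring cause correspondence."""

    direct: Mapping[str, str] = field(default_factory=dict)
    comorbid_rules: tuple[ComorbidRule, ...] = ()
    groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        for rule in self.comorbid_rules:
            if rule.pattern in seen:
                raise RuleConfigError(
                    f"duplicate comorbid pattern {sorted(rule.pattern)}"
                )
            seen.add(rule.pattern)


def cause_map_from_obj(obj) -> CauseMap:
    if not isinstance(obj, Mapping):
        raise RuleConfigError("cause map config must be a mapping")
    rules = []
    for i, rule_obj in enumerate(obj.get("comorbid", [])):
        pattern = frozenset(str(c) for c in rule_obj.get("pattern", []))
        if len(pattern) < 2:
            raise RuleConfigError(f"comorbid[{i}]: pattern must have >= 2 causes")
        if "proportional_over" in rule_obj:
            rules.append(
                ComorbidRule(
                    pattern,
                    proportional=tuple(str(c) for c in rule_obj["proportional_over"]),
                )
            )
        else:
            rules.append(ComorbidRule(pattern, target=str(rule_obj["target"])))
    return CauseMap(
        direct={str(k): str(v) for k, v in (obj.get("direct") or {}).items()},
        comorbid_rules=tuple(rules),
        groups={str(k): str(v) for k, v in (obj.get("groups") or {}).items()},
    )


def parse_cause_map(config_text: str) -> CauseMap:
    """Parse a YAML/JSON cause-map config."""
    return cause_map_from_obj(yaml.safe_load(config_text))


def harmonize_comorbid(
    labels: Sequence[ReferenceLabel], cause_map: CauseMap
) -> dict[str, str]:
    """Reduce each (possibly co-morbid) reference label to one cause.

    Single-cause labels go through the ``direct`` map (identity when absent).
    Multi-cause labels must exactly match one comorbid rule. Proportional
    rules split their matching deaths across targets in the ratio of deaths
    already singly assigned to those targets, rounded by the largest-remainder
    method and allocated in input order — fully deterministic, and the total
    death count is conserved.
    """
    assigned: dict[str, str] = {}
    deferred: dict[int, list[str]] = {}  # rule index -> death_ids, input order

    rule_index = {rule.pattern: i for i, rule in enumerate(cause_map.comorbid_rules)}
    for label in labels:
        if label.death_id in assigned or any(
            label.death_id in ids for ids in deferred.values()
        ):
            raise MappingError(f"duplicate death_id {label.death_id!r}")
        if len(label.causes) == 1:
            (cause,) = label.causes
            assigned[label.death_id] = cause_map.direct.get(cause, cause)
            continue
        idx = rule_index.get(label.causes)
        if idx is None:
            raise MappingError(
                f"death {label.death_id!r}: no harmonization rule for cause set "
                f"{sorted(label.causes)}"
            )
        rule = cause_map.comorbid_rules[idx]
        if rule.target is not None:
            assigned[label.death_id] = rule.target
        else:
            deferred.setdefault(idx, []).append(label.death_id)

    for idx, death_ids in deferred.items():
        rule = cause_map.comorbid_rules[idx]
        tallies = Counter(assigned.values())
        weights = {t: float(tallies.get(t, 0)) for t in rule.proportional}
        if sum(weights.values()) == 0:
            raise AllocationError(
                f"comorbid set {sorted(rule.pattern)}: no deaths singly assigned "
                f"to any of {list(rule.proportional)}"
            )
        counts = largest_remainder(weights, len(death_ids))
        cursor = 0
        for target in rule.proportional:
            for death_id in death_ids[cursor : cursor + counts[target]]:
                assigned[death_id] = target
            cursor += counts[target]

    return assigned


def collapse_groups(
    assignments: Mapping[str, str], cause_map: CauseMap
) -> dict[str, str]:
    """Replace every grouped cause with its scoring cause; idempotent."""
    return {d: cause_map.groups.get(c, c) for d, c in assignments.items()}
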