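"""Loaders for the bundled configuration files.

Bundled content: the published cause-assignment hierarchies (six neonatal,
three child), illustrative placeholder rule sets, reference-cause
harmonization maps, and a synthetic country CSMF table spanning all scenario
filters (real WHO-style tables are user-supplied).
"""

from __future__ import annotations

from importlib import resources

import yaml

from .errors import RuleConfigError
from .reference_harmonizer import CauseMap, parse_cause_map
from .rules_engine import Hierarchy, RuleSet, hierarchy_from_obj, parse_ruleset
from .scenario_resampler import CountryCsmfTable


def _data_text(name: str) -> str:
    return resources.files("vahier.data").joinpath(name).read_text()


def list_hierarchies(age_group: str) -> list[str]:
    obj = yaml.safe_load(_data_text("hierarchies.yaml"))
    if age_group not in obj:
        raise RuleConfigError(f"no bundled hierarchies for age group {age_group!r}")
    return list(obj[age_group])


def load_hierarchy(name: str, age_group: str) -> Hierarchy:
    obj = yaml.safe_load(_data_text("hierarchies.yaml"))
    try:
        spec = obj[age_group][name]
    except KeyError:
        raise RuleConfigError(
            f"no bundled hierarchy {name!r} for age group {age_group!r}; "
            f"available: {list_hierarchies(age_group)}"
        )
    return hierarchy_from_obj(name, age_group, spec)


def load_all_hierarchies(age_group: str) -> list[Hierarchy]:
    return [load_hierarchy(name, age_group) for name in list_hierarchies(age_group)]


def load_default_ruleset(age_group: str) -> RuleSet:
    """Illustrative placeholder rules; see the file headers for caveats."""
    return parse_ruleset(_data_text(f"rules_{age_group}.yaml"))


def load_cause_map(age_group: str) -> CauseMap:
    return parse_cause_map(_data_text(f"cause_map_{age_group}.yaml"))


def load_country_table(age_group: str) -> CountryCsmfTable:
    """Synthetic country CSMF table (fictional rows spanning every scenario)."""
    with resources.files("vahier.data").joinpath(
        f"country_csmf_{age_group}.csv"
    ).open("rb") as fh:
        return CountryCsmfTable.from_csv(fh)
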