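"""Mortality-scenario target distributions and pool resampling.

Four scenarios are supported. Three draw a country at random among those
matching a community profile in a country cause-of-death table:

* ``high_u5mr_malaria`` — under-five mortality rate (U5MR) above 35 deaths
  per 1000 live births and more than 5% of under-five deaths due to malaria;
* ``high_u5mr_no_malaria`` — U5MR above 35, malaria at or below 5%;
* ``moderate_u5mr`` — U5MR between 20 and 35 inclusive.

The fourth, ``general``, draws every cause fraction uniformly on
[0.05, 0.40] and normalizes the vector to sum to one.

The drawn target is then imposed on a labelled death pool by largest-
remainder apportionment and with-replacement sampling per cause; causes
absent from the pool are dropped and the target renormalized over the rest.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import largest_remainder
from .errors import ResamplingError, ScenarioError, UsageError

__all__ = [
    "CauseDistribution",
    "CountryRow",
    "CountryCsmfTable",
    "ScenarioSpec",
    "SCENARIO_NAMES",
    "eligible_rows",
    "draw_general_fractions",
    "draw_target_csmf",
    "renormalize_over_available",
    "apportion_counts",
    "resample_to_target",
]

SCENARIO_NAMES = (
    "high_u5mr_malaria",
    "high_u5mr_no_malaria",
    "moderate_u5mr",
    "general",
)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class CauseDistribution:
    """A cause-specific mortality fraction (CSMF) vector summing to one."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise UsageError("CauseDistribution needs at least one cause")
        for cause, value in self.fractions.items():
            if value < 0:
                raise UsageError(f"negative fraction for {cause!r}: {value}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise UsageError(f"fractions sum to {total!r}, not 1")

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(self.fractions)

    def __getitem__(self, cause: str) -> float:
        return self.fractions[cause]


@dataclass(frozen=True)
class CountryRow:
    country_id: str
    age_group: str
    u5mr: float  # deaths per 1000 live births
    malaria_fraction: float  # fraction of under-five deaths due to malaria
    distribution: CauseDistribution

    def __post_init__(self) -> None:
        if self.u5mr <= 0:
            raise UsageError(f"{self.country_id}: u5mr must be positive")
        if not 0 <= self.malaria_fraction <= 1:
            raise UsageError(f"{self.country_id}: malaria_fraction out of [0,1]")


@dataclass(frozen=True)
class CountryCsmfTable:
    rows: tuple[CountryRow, ...]

    @classmethod
    def from_csv(cls, path) -> "CountryCsmfTable":
        """Columns: country_id, age_group, u5mr, malaria_fraction, then one per cause."""
        df = pd.read_csv(path)
        meta = ["country_id", "age_group", "u5mr", "malaria_fraction"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise UsageError(f"country table missing columns {missing}")
        cause_cols = [c for c in df.columns if c not in meta]
        rows = []
        for rec in df.to_dict("records"):
            fractions = {
                c: float(rec[c]) for c in cause_cols if not pd.isna(rec[c]) and float(rec[c]) > 0
            }
            total = sum(fractions.values())
            fractions = {c: v / total for c, v in fractions.items()}
            rows.append(
                CountryRow(
                    country_id=str(rec["country_id"]),
                    age_group=str(rec["age_group"]),
                    u5mr=float(rec["u5mr"]),
                    malaria_fraction=float(rec["malaria_fraction"]),
                    distribution=CauseDistribution(fractions),
                )
            )
        return cls(tuple(rows))


@dataclass(frozen=True)
class ScenarioSpec:
    """One mortality scenario: either a country filter or uniform bounds."""

    name: str
    general_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ScenarioError(f"unknown scenario {self.name!r}")
        if (self.name == "general") != (self.general_bounds is not None):
            raise ScenarioError("general_bounds set iff scenario is 'general'")

    @classmethod
    def from_name(cls, name: str) -> "ScenarioSpec":
        if name == "general":
            return cls(name, general_bounds=(0.05, 0.40))
        return cls(name)

    @property
    def is_general(self) -> bool:
        return self.name == "general"

    def matches(self, u5mr: float, malaria_fraction: float) -> bool:
        if self.name == "high_u5mr_malaria":
            return u5mr > 35 and malaria_fraction > 0.05
        if self.name == "high_u5mr_no_malaria":
            return u5mr > 35 and malaria_fraction <= 0.05
        if self.name == "moderate_u5mr":
            return 20 <= u5mr <= 35
        raise ScenarioError("general scenario has no country filter")


def eligible_rows(
    table: CountryCsmfTable,
    scenario: ScenarioSpec,
    age_group: str | None = None,
) -> list[CountryRow]:
    """Country rows satisfying the scenario filter (and age group, if given)."""
    if not table.rows:
        raise ScenarioError("empty country table")
    if scenario.is_general:
        raise ScenarioError("general scenario does not filter country rows")
    rows = [
        row
        for row in table.rows
        if scenario.matches(row.u5mr, row.malaria_fraction)
        and (age_group is None or row.age_group == age_group)
    ]
    if not rows:
        raise ScenarioError(f"no rows eligible for scenario {scenario.name!r}")
    return rows


def draw_general_fractions(
    causes: Sequence[str],
    bounds: tuple[float, float],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Raw per-cause uniform draws on ``bounds``, before normalization."""
    low, high = bounds
    values = rng.uniform(low, high, size=len(causes))
    return dict(zip(causes, values.tolist()))


def draw_target_csmf(
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    *,
    table: CountryCsmfTable | None = None,
    causes: Sequence[str] | None = None,
    age_group: str | None = None,
) -> CauseDistribution:
    """Draw one target CSMF for a scenario; reproducible given ``rng`` state.

    Country scenarios pick uniformly among eligible rows' distributions;
    the general scenario draws each cause on its bounds and renormalizes.
    """
    if scenario.is_general:
        if not causes:
            raise ScenarioError("general scenario needs an explicit cause list")
        raw = draw_general_fractions(causes, scenario.general_bounds, rng)
        total = sum(raw.values())
        return CauseDistribution({c: v / total for c, v in raw.items()})
    if table is None:
        raise ScenarioError(f"scenario {scenario.name!r} needs a country table")
    rows = eligible_rows(table, scenario, age_group)
    row = rows[int(rng.integers(len(rows)))]
    return row.distribution


def renormalize_over_available(
    target: CauseDistribution, available: Iterable[str]
) -> CauseDistribution:
    """Restrict a target to the available causes and rescale to sum one."""
    available = set(available)
    kept = {c: f for c, f in target.fractions.items() if c in available and f > 0}
    if not kept:
        raise ScenarioError("no overlap between target causes and available pool")
    total = sum(kept.values())
    return CauseDistribution({c: f / total for c, f in kept.items()})


def apportion_counts(target: CauseDistribution, n: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` deaths to the target fractions."""
    if n < 1:
        raise UsageError("n must be >= 1")
    return largest_remainder(dict(target.fractions), n)


def resample_to_target(
    pool: Mapping[str, Sequence[str]],
    target: CauseDistribution,
    n: int,
    rng: np.random.Generator,
    *,
    with_replacement: bool = True,
) -> list[str]:
    """Draw a sample of ``n`` death ids whose empirical CSMF matches ``target``.

    Causes missing from the pool are dropped (target renormalized over the
    rest); per-cause counts come from :func:`apportion_counts`, so the
    empirical CSMF equals counts/n exactly.
    """
    available = {c for c, ids in pool.items() if len(ids) > 0}
    resolved = renormalize_over_available(target, available)
    counts = apportion_counts(resolved, n)
    sample: list[str] = []
    for cause in resolved.causes:
        ids = list(pool[cause])
        k = counts[cause]
        if k == 0:
            continue
        if with_replacement:
            picks = rng.integers(len(ids), size=k)
            sample.extend(ids[i] for i in picks)
        else:
            if k > len(ids):
                raise ResamplingError(
                    f"cause {cause!r}: need {k} deaths but pool has {len(ids)}"
                )
            picks = rng.choice(len(ids), size=k, replace=False)
            sample.extend(ids[i] for i in picks)
    return sample
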