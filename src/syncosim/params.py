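"""Model inputs for the syncope diagnostic-pathway budget-impact model.

This module houses every quantity that drives the cohort model as a validated
type: the clinical transition parameters (syncope recurrence rate, per-event
diagnostic yields, mortality hazard ratio), the unit costs of the implantable
loop recorder (ILR) pathway and of syncope admissions, the per-scenario
diagnostic-workup profiles, and the life table supplying baseline age-specific
mortality.  It also provides the two derived per-event cost quantities:

* the weighted diagnostic-workup cost of a syncope admission
  (sum of unit price x fraction of patients receiving each test), and
* the expected trauma cost per syncope episode
  (minor/major admission tariffs weighted by injury and severity probabilities).

Published scenario tables carry a printed total that does not always equal the
sum of their own weighted components (rounding in the source).  The printed
total is treated as canonical and is what the cost engine consumes; the
recomputed sum is always available for transparency and a warning is logged
when the two disagree by more than 1 EUR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ClinicalParameters",
    "CostParameters",
    "ScenarioProfile",
    "ScenarioItem",
    "LifeTable",
    "PopulationSource",
    "derive_cohort_size",
    "weighted_workup_cost",
    "expected_trauma_cost",
    "round_half_up",
]

log = logging.getLogger(__name__)

#: Tolerance (EUR) above which a printed scenario total triggers a warning
#: when it disagrees with the recomputed price x fraction sum.
CANONICAL_TOTAL_WARN_EUR = 1.0


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero toward +inf.

    The cohort is a continuous expectation internally; counts are rounded
    only for presentation, and 196.95 -> 197 style rounding must not use
    banker's rounding.
    """
    return int(math.floor(x + 0.5))


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if not (value >= 0.0):
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class ClinicalParameters:
    """Transition-driving quantities of the three-state cohort model.

    Defaults are the base case: a 197-patient cohort entering at age 61,
    0.6 syncope recurrences per person-year, per-event diagnostic yield of
    62.8% with an active ILR versus 12.5% on the conventional pathway, a
    3-year device battery, and all-cause mortality scaled by a hazard ratio
    of 1.32 relative to the general population.
    """

    start_age: float = 61.0
    cohort_size: float = 197.0
    annual_syncope_rate: float = 0.6
    diagnosis_prob_ilr: float = 0.628
    diagnosis_prob_cdp: float = 0.125
    battery_life_years: float = 3.0
    mortality_hazard_ratio: float = 1.32
    injury_prob_per_event: float = 0.522
    severe_injury_fraction: float = 0.1616
    horizon_years: float = 30.0
    cycle_length_years: float = 0.25

    def __post_init__(self) -> None:
        for name in ("diagnosis_prob_ilr", "diagnosis_prob_cdp",
                     "injury_prob_per_event", "severe_injury_fraction"):
            _check_prob(name, getattr(self, name))
        _check_nonneg("annual_syncope_rate", self.annual_syncope_rate)
        _check_nonneg("mortality_hazard_ratio", self.mortality_hazard_ratio)
        if self.cycle_length_years <= 0:
            raise ValueError("cycle_length_years must be positive")
        if self.annual_syncope_rate * self.cycle_length_years > 1.0 + 1e-12:
            raise ValueError(
                "annual_syncope_rate x cycle_length_years exceeds 1; the "
                "per-cycle event probability would not be a valid probability"
            )
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        n = self.horizon_years / self.cycle_length_years
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "horizon_years must be a whole number of cycles "
                f"(horizon {self.horizon_years} / cycle {self.cycle_length_years})"
            )
        if self.battery_life_years < 0:
            raise ValueError("battery_life_years must be >= 0")

    @property
    def n_cycles(self) -> int:
        return round(self.horizon_years / self.cycle_length_years)

    @property
    def battery_cycles(self) -> int:
        return round(self.battery_life_years / self.cycle_length_years)

    @property
    def cycles_per_year(self) -> int:
        return round(1.0 / self.cycle_length_years)

    def with_(self, **overrides) -> "ClinicalParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class CostParameters:
    """Unit costs of the ILR pathway and of syncope admissions (EUR).

    ``trauma_cost_per_event`` is the canonical expected cost of injury/trauma
    per syncope episode; ``expected_trauma_cost`` recomputes it from the
    minor/major admission tariffs for transparency.  ``explantation`` defaults
    to the implantation tariff.
    """

    device_acquisition: float = 2000.0
    implantation: float = 127.80
    explantation: float | None = None
    followup_visit: float = 31.0
    followup_visits_per_year: float = 2.0
    minor_trauma_tariff: float = 2684.83
    major_trauma_tariff: float = 6058.25
    trauma_cost_per_event: float = 1687.57
    annual_discount_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.explantation is None:
            object.__setattr__(self, "explantation", self.implantation)
        for name in ("device_acquisition", "implantation", "explantation",
                     "followup_visit", "followup_visits_per_year",
                     "minor_trauma_tariff", "major_trauma_tariff",
                     "trauma_cost_per_event"):
            _check_nonneg(name, getattr(self, name))
        if not (0.0 <= self.annual_discount_rate < 1.0):
            raise ValueError("annual_discount_rate must be in [0, 1)")

    def with_(self, **overrides) -> "CostParameters":
        return replace(self, **overrides)


@dataclass(frozen=True)
class ScenarioItem:
    """One diagnostic test of a workup scenario."""

    test_name: str
    unit_price: float
    fraction_of_patients: float

    def __post_init__(self) -> None:
        _check_nonneg(f"unit_price[{self.test_name}]", self.unit_price)
        _check_prob(f"fraction_of_patients[{self.test_name}]",
                    self.fraction_of_patients)


@dataclass(frozen=True)
class ScenarioProfile:
    """Per-scenario diagnostic-test frequency table.

    Each scenario describes, for one source study, the fraction of syncope
    patients receiving each diagnostic test together with its national unit
    price.  ``printed_total`` is the total published with the table; when
    present it is the canonical per-event workup cost used by the engine.
    """

    name: str
    items: tuple[ScenarioItem, ...] = ()
    printed_total: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(
            it if isinstance(it, ScenarioItem) else ScenarioItem(*it)
            for it in self.items
        ))
        if self.printed_total is not None:
            _check_nonneg("printed_total", self.printed_total)

    def weighted_workup_cost(self) -> float:
        """Recomputed workup cost: sum of unit_price x fraction over items."""
        return float(sum(it.unit_price * it.fraction_of_patients
                         for it in self.items))

    @property
    def canonical_workup_cost(self) -> float:
        """Workup cost the engine uses: printed total if available.

        Falls back to the recomputed sum when no printed total is stored.
        Logs a warning when the two disagree by more than 1 EUR.
        """
        recomputed = self.weighted_workup_cost()
        if self.printed_total is None:
            return recomputed
        if abs(recomputed - self.printed_total) > CANONICAL_TOTAL_WARN_EUR:
            log.warning(
                "scenario %r: printed workup total %.2f EUR differs from the "
                "recomputed price x fraction sum %.2f EUR; using the printed "
                "total", self.name, self.printed_total, recomputed)
        return self.printed_total


def weighted_workup_cost(profile: ScenarioProfile) -> float:
    """Recompute a scenario's per-event diagnostic-workup cost (EUR)."""
    return profile.weighted_workup_cost()


def expected_trauma_cost(minor: float, major: float, p_injury: float,
                         severe_frac: float) -> float:
    """Expected injury/trauma cost per syncope episode (EUR).

    A fraction ``p_injury`` of episodes lead to a trauma admission; of those,
    ``severe_frac`` are billed at the major tariff and the rest at the minor
    tariff.
    """
    _check_nonneg("minor", minor)
    _check_nonneg("major", major)
    _check_prob("p_injury", p_injury)
    _check_prob("severe_frac", severe_frac)
    return minor * p_injury * (1.0 - severe_frac) + major * p_injury * severe_frac


@dataclass(frozen=True)
class PopulationSource:
    """National admission statistics from which the cohort is sized."""

    annual_syncope_admissions: float = 1010.0
    unexplained_recurrent_fraction: float = 0.195

    def __post_init__(self) -> None:
        _check_nonneg("annual_syncope_admissions", self.annual_syncope_admissions)
        _check_prob("unexplained_recurrent_fraction",
                    self.unexplained_recurrent_fraction)


def derive_cohort_size(src: PopulationSource) -> int:
    """Cohort size: admissions x unexplained-recurrent fraction, rounded half-up."""
    return round_half_up(src.annual_syncope_admissions
                         * src.unexplained_recurrent_fraction)


class LifeTable:
    """Age-indexed annual death probabilities with linear interpolation.

    Parameters
    ----------
    ages, probs:
        Strictly increasing ages (years) and the corresponding annual
        probability of death q(age), each in [0, 1].
    """

    def __init__(self, ages: Sequence[float], probs: Sequence[float]) -> None:
        ages_arr = np.asarray(ages, dtype=float)
        probs_arr = np.asarray(probs, dtype=float)
        if ages_arr.ndim != 1 or ages_arr.shape != probs_arr.shape:
            raise ValueError("ages and probs must be 1-D and of equal length")
        if ages_arr.size < 2:
            raise ValueError("life table needs at least two ages")
        if not np.all(np.diff(ages_arr) > 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(probs_arr < 0) or np.any(probs_arr > 1):
            raise ValueError("annual death probabilities must lie in [0, 1]")
        self.ages = ages_arr
        self.probs = probs_arr

    @property
    def min_age(self) -> float:
        return float(self.ages[0])

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])

    def covers(self, lo: float, hi: float) -> bool:
        return self.min_age <= lo and hi <= self.max_age

    def annual_death_prob(self, age) -> np.ndarray | float:
        """q(age) with linear interpolation; errors outside the table range."""
        a = np.asarray(age, dtype=float)
        if np.any(a < self.min_age - 1e-9) or np.any(a > self.max_age + 1e-9):
            raise ValueError(
                f"age outside life-table range [{self.min_age}, {self.max_age}]")
        q = np.interp(a, self.ages, self.probs)
        return float(q) if np.isscalar(age) else q

    # -- file interface: two-column delimited text, header required --------

    @classmethod
    def from_file(cls, path) -> "LifeTable":
        """Read a two-column delimited text file (age, annual_death_prob)."""
        import pandas as pd

        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"life-table file {path} needs two columns")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))

    def to_file(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "age": self.ages.astype(int) if np.allclose(self.ages, np.round(self.ages)) else self.ages,
            "annual_death_prob": self.probs,
        }).to_csv(path, index=False, float_format="%.8f")

    def __eq__(self, other) -> bool:
        return (isinstance(other, LifeTable)
                and np.array_equal(self.ages, other.ages)
                and np.array_equal(self.probs, other.probs))

    def __repr__(self) -> str:
        return (f"LifeTable(ages [{self.min_age:g}, {self.max_age:g}], "
                f"{self.ages.size} rows)")
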