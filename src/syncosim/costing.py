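"""Cost accrual and discounting over a cohort trace.

Booking rules per arm:

* ILR — device acquisition and implantation for the whole cohort at cycle 0;
  follow-up visits (2 x 31 EUR/yr, apportioned per cycle) for every
  alive-undiagnosed patient while the battery lasts; explantation at the
  cycle of diagnosis, or at the battery-expiry boundary for survivors still
  undiagnosed (never for patients who died with the device); trauma cost for
  every expected episode at every cycle; diagnostic-workup cost only for
  episodes after battery expiry, when the arm has reverted to the
  conventional pathway.
* CDP — no device components; trauma and workup costs for every expected
  episode at every cycle, whether or not the episode yields a diagnosis.

All streams are discounted at the annual rate with per-cycle compounding,
(1 + r)^(-t x cycle_length), costs booked at cycle start (an annual-boundary
convention is available as a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Arm, ArmSpec, CohortTrace
from .params import ClinicalParameters, CostParameters, ScenarioProfile

__all__ = [
    "COMPONENTS",
    "CostLedger",
    "ArmComparison",
    "discount_factor",
    "accrue",
    "compare",
    "average_event_cost_range",
]

COMPONENTS = ("device_acquisition", "implantation", "followup",
              "explantation", "trauma", "workup")


def discount_factor(cycle, annual_rate: float, cycle_length: float = 0.25,
                    convention: str = "per-cycle"):
    """Present-value factor for a cost booked at the start of ``cycle``.

    ``'per-cycle'`` compounds continuously across cycles,
    (1 + r)^(-cycle x cycle_length); ``'annual'`` discounts in whole-year
    steps, (1 + r)^(-floor(cycle x cycle_length)).
    """
    t = np.asarray(cycle, dtype=float)
    if np.any(t < 0):
        raise ValueError("cycle index must be >= 0")
    years = t * cycle_length
    if convention == "annual":
        years = np.floor(years)
    elif convention != "per-cycle":
        raise ValueError(f"unknown discount convention {convention!r}")
    out = (1.0 + annual_rate) ** (-years)
    return float(out) if np.isscalar(cycle) else out


@dataclass(frozen=True)
class CostLedger:
    """Per-cycle cost streams of one arm, undiscounted and discounted.

    Component arrays have length n_cycles + 1 so that the explantation of
    battery-expiry survivors can be booked at the cycle-boundary following
    the last battery cycle.
    """

    arm_id: Arm
    annual_discount_rate: float
    cycle_length_years: float
    convention: str
    undiscounted: dict[str, np.ndarray]
    discount: np.ndarray

    @property
    def discounted(self) -> dict[str, np.ndarray]:
        return {c: v * self.discount for c, v in self.undiscounted.items()}

    def component_totals(self, discounted: bool = True) -> dict[str, float]:
        streams = self.discounted if discounted else self.undiscounted
        return {c: float(v.sum()) for c, v in streams.items()}

    def total(self, discounted: bool = True) -> float:
        return float(sum(self.component_totals(discounted).values()))

    @property
    def device_related(self) -> float:
        """Discounted implantation + follow-up + explantation total."""
        t = self.component_totals()
        return t["implantation"] + t["followup"] + t["explantation"]

    def to_frame(self) -> pd.DataFrame:
        """Component x cycle table (undiscounted and discounted columns)."""
        n = self.discount.size
        data = {"cycle": np.arange(n), "discount_factor": self.discount}
        for c in COMPONENTS:
            data[c] = self.undiscounted[c]
            data[f"{c}_discounted"] = self.undiscounted[c] * self.discount
        return pd.DataFrame(data)


def accrue(trace: CohortTrace, arm: ArmSpec, clin: ClinicalParameters,
           costs: CostParameters, workup_cost_per_event: float, *,
           discount_convention: str = "per-cycle") -> CostLedger:
    """Convert a cohort trace into the arm's cost ledger (see module docstring)."""
    if trace.arm_id != arm.arm_id:
        raise ValueError(f"trace arm {trace.arm_id} != arm spec {arm.arm_id}")
    if workup_cost_per_event < 0:
        raise ValueError("workup_cost_per_event must be >= 0")
    T = trace.n_cycles
    zeros = lambda: np.zeros(T + 1)
    led = {c: zeros() for c in COMPONENTS}

    led["trauma"][:T] = trace.episodes * costs.trauma_cost_per_event

    if arm.arm_id is Arm.ILR:
        B = min(clin.battery_cycles, T)
        led["device_acquisition"][0] = trace.cohort_size * costs.device_acquisition
        led["implantation"][0] = trace.cohort_size * costs.implantation
        per_cycle_followup = (costs.followup_visit * costs.followup_visits_per_year
                              * clin.cycle_length_years)
        led["followup"][:B] = trace.undiagnosed[:B] * per_cycle_followup
        # explantation: at diagnosis during battery life, at the battery
        # boundary for undiagnosed survivors; the dead keep the device.
        led["explantation"][:B] = trace.new_diagnosed[:B] * costs.explantation
        led["explantation"][B] += trace.undiagnosed[B] * costs.explantation
        led["workup"][B:T] = trace.episodes[B:] * workup_cost_per_event
    else:
        led["workup"][:T] = trace.episodes * workup_cost_per_event

    disc = discount_factor(np.arange(T + 1), costs.annual_discount_rate,
                           clin.cycle_length_years, discount_convention)
    for c, v in led.items():
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError(f"non-finite or negative cost stream in {c!r}")
    return CostLedger(
        arm_id=arm.arm_id,
        annual_discount_rate=costs.annual_discount_rate,
        cycle_length_years=clin.cycle_length_years,
        convention=discount_convention,
        undiscounted=led,
        discount=disc,
    )


@dataclass(frozen=True)
class ArmComparison:
    """Discounted cost totals of the two arms and the resulting savings."""

    ilr_total: float
    cdp_total: float
    savings: float
    pct_reduction: float
    per_patient_savings: float
    cohort_size: float


def compare(ilr: CostLedger, cdp: CostLedger, cohort_size: float) -> ArmComparison:
    """Savings of the ILR arm over the conventional pathway.

    savings = CDP total - ILR total (discounted); the percentage reduction is
    relative to the CDP total (0 when the CDP total is 0).
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    ilr_total = ilr.total()
    cdp_total = cdp.total()
    savings = cdp_total - ilr_total
    pct = 100.0 * savings / cdp_total if cdp_total != 0 else 0.0
    return ArmComparison(ilr_total, cdp_total, savings, pct,
                         savings / cohort_size, cohort_size)


def average_event_cost_range(profiles, trauma_cost: float) -> tuple[float, float]:
    """(min, max) total cost of one syncope event across workup scenarios.

    Each scenario's canonical workup total plus the expected trauma cost,
    rounded to the nearest 10 EUR.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one scenario profile is required")
    totals = [p.canonical_workup_cost + trauma_cost for p in profiles]
    to10 = lambda x: 10.0 * math.floor(x / 10.0 + 0.5)
    return (to10(min(totals)), to10(max(totals)))
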