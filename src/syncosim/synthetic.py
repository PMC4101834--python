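"""Synthetic-data stage: patient-level microsimulation and fixture generators.

The cohort engine propagates *expected* occupancies; this module realises the
same stochastic process patient by patient, so the deterministic recursion can
be validated against Monte-Carlo means.  The engine's simultaneous convention
books the diagnosing-syncope fraction (sigma_c delta) and the death fraction
(q_c) out of the same start-of-cycle pool, which makes the two exits mutually
exclusive within a cycle.  The microsimulation realises exactly that
convention: per cycle, one uniform draw partitions each alive-undiagnosed
patient into death (mass q_c), syncope-with-diagnosis (mass sigma_c delta_t)
or neither; a second draw gives the remaining patients (including those dying
this cycle, whose episode the engine still counts) a non-diagnosing syncope
with conditional probability sigma_c (1 - delta_t) / (1 - sigma_c delta_t);
a third marks injuries among syncope cycles.  Under this construction every
engine quantity — new diagnoses, deaths, episodes, injuries, occupancy — is
the exact per-cycle expectation of the simulation.

Also here: a Gompertz-Makeham life-table generator (the bundled default
mortality fixture is synthetic — see :mod:`syncosim.datasets`) and a fuzzer
producing random valid parameter sets for property tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ArmSpec, cycle_death_prob, cycle_syncope_prob
from .params import ClinicalParameters, CostParameters, LifeTable

__all__ = [
    "PatientHistories",
    "PatientHistory",
    "simulate_patients",
    "patient_cost_totals",
    "synthetic_life_table",
    "random_parameter_set",
]

EXIT_DIAGNOSED = "diagnosed"
EXIT_DIED = "died"
EXIT_HORIZON = "horizon"


@dataclass(frozen=True)
class PatientHistory:
    """One simulated patient's event history."""

    patient_id: int
    syncope: np.ndarray   # bool per cycle
    injury: np.ndarray
    diagnosis: np.ndarray
    death: np.ndarray
    exit_cycle: int
    exit_reason: str


@dataclass(frozen=True)
class PatientHistories:
    """Event flags of ``n`` simulated patients over ``n_cycles`` cycles.

    Flag arrays are boolean with shape (n, n_cycles); no flags are set after
    a patient's exit cycle.
    """

    arm_id: str
    cycle_length_years: float
    syncope: np.ndarray
    injury: np.ndarray
    diagnosis: np.ndarray
    death: np.ndarray
    exit_cycle: np.ndarray   # int, == n_cycles for horizon exits
    exit_reason: np.ndarray  # unicode array

    @property
    def n(self) -> int:
        return self.syncope.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.syncope.shape[1]

    def patient(self, i: int) -> PatientHistory:
        return PatientHistory(i, self.syncope[i], self.injury[i],
                              self.diagnosis[i], self.death[i],
                              int(self.exit_cycle[i]), str(self.exit_reason[i]))

    def counts_per_cycle(self) -> pd.DataFrame:
        """Observed per-cycle event counts (the microsim analogue of a trace)."""
        return pd.DataFrame({
            "cycle": np.arange(self.n_cycles),
            "episodes": self.syncope.sum(axis=0),
            "new_diagnosed": self.diagnosis.sum(axis=0),
            "new_dead": self.death.sum(axis=0),
            "injuries": self.injury.sum(axis=0),
        })

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per patient x cycle with any event."""
        pid, cyc = np.nonzero(self.syncope | self.diagnosis
                              | self.death | self.injury)
        return pd.DataFrame({
            "patient": pid,
            "cycle": cyc,
            "syncope": self.syncope[pid, cyc].astype(int),
            "injury": self.injury[pid, cyc].astype(int),
            "diagnosis": self.diagnosis[pid, cyc].astype(int),
            "death": self.death[pid, cyc].astype(int),
        })


def simulate_patients(params: ClinicalParameters, arm: ArmSpec, lt: LifeTable,
                      n: int, seed: int | np.random.Generator,
                      *, rate_conversion: str = "linear") -> PatientHistories:
    """Simulate ``n`` patient histories over the parameter horizon.

    Reproducible: the same seed yields identical histories.  Draw order is
    fixed — per cycle, (exit, non-diagnosing syncope, injury) uniforms for
    all patients in index order.  See the module docstring for the exact
    correspondence with the cohort engine's competing-risk convention.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = params.n_cycles
    sigma_c = cycle_syncope_prob(params.annual_syncope_rate,
                                 params.cycle_length_years, rate_conversion)
    ages = params.start_age + params.cycle_length_years * np.arange(T)
    q_c = cycle_death_prob(ages, lt, params.mortality_hazard_ratio,
                           params.cycle_length_years)
    delta = arm.yields(T)
    if np.any(q_c + sigma_c * delta > 1.0 + 1e-12):
        raise ValueError("per-cycle exit probabilities exceed 1")

    syncope = np.zeros((n, T), dtype=bool)
    injury = np.zeros((n, T), dtype=bool)
    diagnosis = np.zeros((n, T), dtype=bool)
    death = np.zeros((n, T), dtype=bool)
    exit_cycle = np.full(n, T, dtype=np.int64)
    exit_reason = np.full(n, EXIT_HORIZON, dtype="U9")
    active = np.ones(n, dtype=bool)

    for t in range(T):
        if not active.any():
            break
        u = rng.random((3, n))
        sd = sigma_c * delta[t]
        # single-uniform partition: death and diagnosing syncope exclusive
        died = active & (u[0] < q_c[t])
        diag = active & (u[0] >= q_c[t]) & (u[0] < q_c[t] + sd)
        # non-diagnosing syncope among the rest (the dying included), at the
        # conditional rate that restores a total syncope probability sigma_c
        p_other = sigma_c * (1.0 - delta[t]) / (1.0 - sd) if sd < 1.0 else 0.0
        sync = diag | (active & ~diag & (u[1] < p_other))
        inj = sync & (u[2] < params.injury_prob_per_event)
        death[died, t] = True
        syncope[sync, t] = True
        diagnosis[diag, t] = True
        injury[inj, t] = True
        exit_cycle[died | diag] = t
        exit_reason[diag] = EXIT_DIAGNOSED
        exit_reason[died] = EXIT_DIED
        active &= ~(died | diag)
    return PatientHistories(
        arm_id=str(arm.arm_id.value),
        cycle_length_years=params.cycle_length_years,
        syncope=syncope, injury=injury, diagnosis=diagnosis, death=death,
        exit_cycle=exit_cycle, exit_reason=exit_reason,
    )


def patient_cost_totals(histories: PatientHistories, clin: ClinicalParameters,
                        costs: CostParameters, workup_cost_per_event: float,
                        *, discount_convention: str = "per-cycle") -> np.ndarray:
    """Discounted total cost per simulated patient, same booking rules as
    the cohort ledger; the mean converges to the ledger total per patient."""
    from .costing import discount_factor

    n, T = histories.n, histories.n_cycles
    disc = discount_factor(np.arange(T + 1), costs.annual_discount_rate,
                           clin.cycle_length_years, discount_convention)
    total = np.zeros(n)
    trauma = costs.trauma_cost_per_event
    is_ilr = histories.arm_id == "ILR"
    B = min(clin.battery_cycles, T)

    total += histories.syncope @ (disc[:T] * trauma)
    if is_ilr:
        total += costs.device_acquisition + costs.implantation
        # alive-undiagnosed at start of cycle t  <=>  exit_cycle >= t, except
        # that events are booked in the exit cycle itself, so occupancy at t
        # means exit_cycle >= t.
        per_cycle_fu = (costs.followup_visit * costs.followup_visits_per_year
                        * clin.cycle_length_years)
        ec = histories.exit_cycle
        for t in range(B):
            total[ec >= t] += per_cycle_fu * disc[t]
        # explantation: at diagnosis within battery life; at the battery
        # boundary for everyone still undiagnosed and alive there.
        diag_in_batt = histories.diagnosis[:, :B]
        dcycle = np.where(diag_in_batt.any(axis=1),
                          diag_in_batt.argmax(axis=1), -1)
        died_in_batt = histories.death[:, :B].any(axis=1)
        mask = (dcycle >= 0) & ~died_in_batt
        total[mask] += costs.explantation * disc[dcycle[mask]]
        survivors = ec >= B
        total[survivors] += costs.explantation * disc[B]
        if B < T:
            total += histories.syncope[:, B:] @ (disc[B:T] * workup_cost_per_event)
    else:
        total += histories.syncope @ (disc[:T] * workup_cost_per_event)
    return total


def synthetic_life_table(a: float, b: float, c: float,
                         age_range: tuple[float, float] = (50, 100),
                         step: float = 1.0) -> LifeTable:
    """Gompertz-Makeham life table: q(age) = 1 - exp(-(a + b e^(c age))).

    ``a`` is the age-independent (Makeham) hazard level, ``b`` and ``c`` the
    Gompertz scale and slope.  Parameters that drive q to 1 before the top
    age are rejected.
    """
    if a < 0 or b < 0 or c <= 0:
        raise ValueError("require a >= 0, b >= 0, c > 0")
    lo, hi = age_range
    if hi <= lo:
        raise ValueError("age range must be increasing")
    ages = np.arange(lo, hi + step / 2, step, dtype=float)
    with np.errstate(over="raise"):
        try:
            hazard = a + b * np.exp(c * ages)
        except FloatingPointError:
            raise ValueError("Gompertz term overflows over the age range") from None
    q = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    if np.any(q[:-1] >= 1.0):
        raise ValueError("parameters drive q(age) to 1 before the top age")
    return LifeTable(ages, q)


def random_parameter_set(seed: int | np.random.Generator,
                         life_table: LifeTable | None = None,
                         **fixed) -> tuple[ClinicalParameters, CostParameters]:
    """Random valid parameter set for property-test fuzzing.

    Draws span the supported space while guaranteeing the engine's
    feasibility constraint (per-cycle exit probability <= 1 over the covered
    ages).  Keyword arguments pin individual fields.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if life_table is None:
        from .datasets import default_life_table

        life_table = default_life_table()

    horizon = fixed.pop("horizon_years", float(rng.choice([1.0, 3.0, 30.0])))
    start_age = fixed.pop("start_age", float(rng.uniform(
        life_table.min_age, life_table.max_age - horizon)))
    hr = fixed.pop("mortality_hazard_ratio", float(rng.uniform(0.5, 2.0)))
    # cap the per-cycle exit probability: sigma_c * delta + q_c <= 1
    ages = np.arange(start_age, start_age + horizon + 0.25, 0.25)
    ages = ages[ages <= life_table.max_age]
    q_max = float(np.max(1.0 - (1.0 - np.minimum(
        1.0, life_table.annual_death_prob(ages) * hr)) ** 0.25))
    rate_cap = min(2.0, 4.0 * (1.0 - q_max) / max(1e-9, 1.0))
    clin = ClinicalParameters(
        start_age=start_age,
        cohort_size=fixed.pop("cohort_size", float(rng.integers(1, 1000))),
        annual_syncope_rate=fixed.pop("annual_syncope_rate",
                                      float(rng.uniform(0.0, rate_cap))),
        diagnosis_prob_ilr=fixed.pop("diagnosis_prob_ilr", float(rng.uniform(0, 1))),
        diagnosis_prob_cdp=fixed.pop("diagnosis_prob_cdp", float(rng.uniform(0, 1))),
        battery_life_years=fixed.pop("battery_life_years",
                                     min(3.0, horizon)),
        mortality_hazard_ratio=hr,
        injury_prob_per_event=fixed.pop("injury_prob_per_event",
                                        float(rng.uniform(0, 1))),
        severe_injury_fraction=fixed.pop("severe_injury_fraction",
                                         float(rng.uniform(0, 1))),
        horizon_years=horizon,
        cycle_length_years=0.25,
    )
    costs = CostParameters(
        device_acquisition=fixed.pop("device_acquisition", float(rng.uniform(0, 5000))),
        implantation=fixed.pop("implantation", float(rng.uniform(0, 500))),
        followup_visit=fixed.pop("followup_visit", float(rng.uniform(0, 100))),
        minor_trauma_tariff=fixed.pop("minor_trauma_tariff", float(rng.uniform(0, 5000))),
        major_trauma_tariff=fixed.pop("major_trauma_tariff", float(rng.uniform(0, 10000))),
        trauma_cost_per_event=fixed.pop("trauma_cost_per_event", float(rng.uniform(0, 3000))),
        annual_discount_rate=fixed.pop("annual_discount_rate", float(rng.uniform(0, 0.1))),
    )
    if fixed:
        raise KeyError(f"unknown fixed field(s): {sorted(fixed)}")
    return clin, costs
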