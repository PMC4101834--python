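"""One-call model evaluation: traces, ledgers and arm comparison.

`ModelContext` bundles everything a single deterministic evaluation needs —
clinical parameters, unit costs, the active workup scenario, the life table
and the convention flags — and `run` applies named parameter overrides and
returns both arms' traces, ledgers and the cost comparison.  The sensitivity
module drives thousands of these evaluations.

Override names accepted by :meth:`ModelContext.run`: any field of
``ClinicalParameters`` or ``CostParameters``, plus ``workup_cost`` (per-event
diagnostic workup cost, overriding the scenario's canonical total).

Trauma-cost convention: when ``recompute_trauma`` is set (the default for
sensitivity analyses), the per-event trauma cost is recomputed from the
minor/major tariffs and the injury/severity probabilities so that overrides
of those components propagate; otherwise the canonical
``trauma_cost_per_event`` is used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .costing import ArmComparison, CostLedger, accrue, compare
from .engine import ArmSpec, CohortTrace, run_cohort
from .params import (ClinicalParameters, CostParameters, LifeTable,
                     ScenarioProfile, expected_trauma_cost)

__all__ = ["ModelContext", "ModelResult"]

_CLINICAL_FIELDS = frozenset(ClinicalParameters.__dataclass_fields__)
_COST_FIELDS = frozenset(CostParameters.__dataclass_fields__)


@dataclass(frozen=True)
class ModelResult:
    ilr_trace: CohortTrace
    cdp_trace: CohortTrace
    ilr_ledger: CostLedger
    cdp_ledger: CostLedger
    comparison: ArmComparison
    workup_cost_per_event: float
    trauma_cost_per_event: float


@dataclass(frozen=True)
class ModelContext:
    clinical: ClinicalParameters
    costs: CostParameters
    profile: ScenarioProfile
    life_table: LifeTable
    rate_conversion: str = "linear"
    event_order: str = "simultaneous"
    discount_convention: str = "per-cycle"
    recompute_trauma: bool = False

    @classmethod
    def base_case(cls, horizon_years: float = 30.0, scenario: str = "Sousa Pedro",
                  **flags) -> "ModelContext":
        """Base-case context on the bundled fixtures."""
        from . import datasets

        return cls(
            clinical=datasets.base_clinical(horizon_years),
            costs=datasets.base_costs(),
            profile=datasets.scenario_profiles()[scenario],
            life_table=datasets.default_life_table(),
            **flags,
        )

    def run(self, overrides: dict | None = None) -> ModelResult:
        """Evaluate both arms under the context, with optional overrides."""
        overrides = dict(overrides or {})
        workup = overrides.pop("workup_cost", None)
        clin_over = {k: overrides.pop(k) for k in list(overrides)
                     if k in _CLINICAL_FIELDS}
        cost_over = {k: overrides.pop(k) for k in list(overrides)
                     if k in _COST_FIELDS}
        if overrides:
            raise KeyError(f"unknown override(s): {sorted(overrides)}")
        clin = self.clinical.with_(**clin_over) if clin_over else self.clinical
        costs = self.costs.with_(**cost_over) if cost_over else self.costs
        if self.recompute_trauma:
            costs = costs.with_(trauma_cost_per_event=expected_trauma_cost(
                costs.minor_trauma_tariff, costs.major_trauma_tariff,
                clin.injury_prob_per_event, clin.severe_injury_fraction))
        if workup is None:
            workup = self.profile.canonical_workup_cost

        results = {}
        for spec in (ArmSpec.ilr(clin), ArmSpec.cdp(clin)):
            trace = run_cohort(clin, spec, self.life_table,
                               rate_conversion=self.rate_conversion,
                               event_order=self.event_order)
            ledger = accrue(trace, spec, clin, costs, workup,
                            discount_convention=self.discount_convention)
            results[spec.arm_id.value] = (trace, ledger)
        ilr_trace, ilr_ledger = results["ILR"]
        cdp_trace, cdp_ledger = results["CDP"]
        return ModelResult(
            ilr_trace=ilr_trace, cdp_trace=cdp_trace,
            ilr_ledger=ilr_ledger, cdp_ledger=cdp_ledger,
            comparison=compare(ilr_ledger, cdp_ledger, clin.cohort_size),
            workup_cost_per_event=workup,
            trauma_cost_per_event=costs.trauma_cost_per_event,
        )

    def with_(self, **changes) -> "ModelContext":
        return replace(self, **changes)
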