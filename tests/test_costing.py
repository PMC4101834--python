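"""Cost accrual, discounting and the ILR-vs-CDP comparison."""

import numpy as np
import pytest

from syncosim.costing import (accrue, average_event_cost_range, compare,
                              discount_factor)
from syncosim.engine import ArmSpec, run_cohort
from syncosim.params import (ClinicalParameters, CostParameters, LifeTable,
                             ScenarioProfile)


class TestDiscountFactor:
    def test_time_zero_undiscounted(self):
        assert discount_factor(0, 0.05) == 1.0

    def test_zero_rate_never_discounts(self):
        assert np.all(discount_factor(np.arange(50), 0.0) == 1.0)

    def test_one_year_at_five_percent(self):
        assert discount_factor(4, 0.05) == pytest.approx(1 / 1.05)

    def test_annual_convention_steps_at_year_boundaries(self):
        d = discount_factor(np.arange(8), 0.05, convention="annual")
        assert np.all(d[:4] == 1.0)
        assert np.all(d[4:] == pytest.approx(1 / 1.05))

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.05)


def _run_and_accrue(clin, costs, lt, arm_name="ilr", workup=164.32, **kw):
    arm = getattr(ArmSpec, arm_name)(clin)
    trace = run_cohort(clin, arm, lt)
    return trace, accrue(trace, arm, clin, costs, workup, **kw)


class TestAccrue:
    def test_device_acquisition_base_case(self, clinical30, costs, life_table):
        _, ledger = _run_and_accrue(clinical30, costs, life_table)
        assert ledger.component_totals(discounted=False)["device_acquisition"] \
            == pytest.approx(394_000.0)
        # spent entirely at cycle 0, so discounting does not touch it
        assert ledger.component_totals()["device_acquisition"] \
            == pytest.approx(394_000.0)

    def test_all_zero_unit_costs_zero_ledger(self, clinical30, life_table):
        zero = CostParameters(device_acquisition=0, implantation=0,
                              followup_visit=0, minor_trauma_tariff=0,
                              major_trauma_tariff=0, trauma_cost_per_event=0,
                              annual_discount_rate=0.05)
        _, ledger = _run_and_accrue(clinical30, zero, life_table, workup=0.0)
        assert ledger.total() == 0.0

    def test_single_cycle_toy_cdp_arithmetic(self, flat_life_table):
        clin = ClinicalParameters(cohort_size=100, annual_syncope_rate=0.4,
                                  horizon_years=0.25, battery_life_years=0.0)
        costs = CostParameters(trauma_cost_per_event=1000.0,
                               annual_discount_rate=0.0)
        _, ledger = _run_and_accrue(clin, costs, flat_life_table,
                                    arm_name="cdp", workup=100.0)
        totals = ledger.component_totals()
        assert totals["trauma"] == pytest.approx(10_000.0)   # 100 x 0.1 x 1000
        assert totals["workup"] == pytest.approx(1_000.0)

    def test_zero_rate_discounted_equals_undiscounted(self, clinical30,
                                                      life_table):
        costs = CostParameters(annual_discount_rate=0.0)
        _, ledger = _run_and_accrue(clinical30, costs, life_table)
        assert ledger.total(discounted=True) == ledger.total(discounted=False)

    def test_cdp_ledger_ignores_device_costs(self, clinical30, life_table):
        a = CostParameters()
        b = CostParameters(device_acquisition=9999.0, implantation=500.0,
                           followup_visit=77.0)
        _, la = _run_and_accrue(clinical30, a, life_table, arm_name="cdp")
        _, lb = _run_and_accrue(clinical30, b, life_table, arm_name="cdp")
        assert la.total() == pytest.approx(lb.total(), rel=1e-14)

    def test_ilr_workup_only_after_battery_exhaustion(self, clinical30, costs,
                                                      life_table):
        _, ledger = _run_and_accrue(clinical30, costs, life_table)
        workup = ledger.undiscounted["workup"]
        assert np.all(workup[:12] == 0.0)
        assert np.any(workup[12:] > 0.0)

    def test_explantation_conservation(self, clinical30, costs, life_table):
        """Explanted devices (at diagnosis or battery expiry) plus deaths
        with the device in situ account for the whole cohort."""
        trace, ledger = _run_and_accrue(clinical30, costs, life_table)
        explanted = ledger.component_totals(discounted=False)["explantation"] \
            / costs.explantation
        died_with_device = trace.cumulative_dead[11]
        assert explanted + died_with_device == pytest.approx(
            clinical30.cohort_size, abs=1e-9)

    def test_grand_total_is_sum_of_components(self, base_result30):
        ledger = base_result30.ilr_ledger
        assert ledger.total() == pytest.approx(
            sum(ledger.component_totals().values()), abs=1e-6)

    def test_ilr_variable_costs_decrease_with_yield(self, costs, life_table):
        """Beyond the fixed device costs, a better yield means fewer episodes
        and earlier explantation, hence a cheaper ILR arm."""
        totals = []
        for d in (0.4, 0.628, 0.8):
            clin = ClinicalParameters(diagnosis_prob_ilr=d, horizon_years=30.0)
            _, ledger = _run_and_accrue(clin, costs, life_table)
            t = ledger.component_totals()
            totals.append(ledger.total() - t["device_acquisition"]
                          - t["implantation"])
        assert totals[0] > totals[1] > totals[2]


class TestCompare:
    def test_identical_ledgers_no_savings(self, base_result30):
        c = compare(base_result30.cdp_ledger, base_result30.cdp_ledger, 197)
        assert c.savings == 0.0 and c.pct_reduction == 0.0

    def test_per_patient_savings_is_definitional(self, base_result30):
        c = base_result30.comparison
        assert c.per_patient_savings == pytest.approx(c.savings / 197.0)

    def test_zero_cdp_total_guarded(self, clinical30, life_table):
        zero = CostParameters(device_acquisition=0, implantation=0,
                              followup_visit=0, trauma_cost_per_event=0)
        _, ledger = _run_and_accrue(clinical30, zero, life_table,
                                    arm_name="cdp", workup=0.0)
        c = compare(ledger, ledger, 197)
        assert c.pct_reduction == 0.0


class TestEventCostRange:
    def test_published_scenarios_bracket(self, profiles):
        lo, hi = average_event_cost_range(profiles.values(), 1687.57)
        assert (lo, hi) == (1760.0, 2800.0)

    def test_single_profile_degenerate_range(self):
        p = ScenarioProfile("only", items=[("t", 100.0, 1.0)])
        assert average_event_cost_range([p], 0.0) == (100.0, 100.0)

    def test_requires_at_least_one_profile(self):
        with pytest.raises(ValueError):
            average_event_cost_range([], 1000.0)
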