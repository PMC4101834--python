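"""Cohort engine: per-cycle probabilities, the recursion and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syncosim.engine import (ArmSpec, CohortTrace, cycle_death_prob,
                             cycle_syncope_prob, run_cohort, step, summarize)
from syncosim.params import ClinicalParameters, LifeTable


class TestCycleSyncopeProb:
    @pytest.mark.parametrize("rate, expected", [
        (0.6, 0.15),       # base case: 0.6/yr over a quarter
        (0.0, 0.0),
        (0.81, 0.2025),    # one-way upper bound of the recurrence rate
    ])
    def test_linear_apportioning(self, rate, expected):
        assert cycle_syncope_prob(rate, 0.25) == pytest.approx(expected)

    def test_rejects_rates_exceeding_one_per_cycle(self):
        with pytest.raises(ValueError, match="not a probability"):
            cycle_syncope_prob(5.0, 0.25)

    def test_exponential_alternative(self):
        got = cycle_syncope_prob(0.6, 0.25, conversion="exponential")
        assert got == pytest.approx(1.0 - np.exp(-0.15))
        assert got < 0.15  # convexity: exponential is below linear


class TestCycleDeathProb:
    def test_zero_table_gives_zero(self, flat_life_table):
        assert cycle_death_prob(61.0, flat_life_table, 1.32, 0.25) == 0.0

    def test_unit_hazard_ratio_reproduces_table_conversion(self):
        lt = LifeTable([60, 70], [0.02, 0.02])
        got = cycle_death_prob(65.0, lt, 1.0, 0.25)
        assert got == pytest.approx(1.0 - 0.98 ** 0.25, rel=1e-12)

    def test_adjusted_quarterly_probability(self):
        lt = LifeTable([60, 62], [0.010, 0.010])
        got = cycle_death_prob(61.0, lt, 1.32, 0.25)
        assert got == pytest.approx(1.0 - 0.9868 ** 0.25, rel=1e-12)
        assert got == pytest.approx(0.003316, abs=5e-7)

    def test_hazard_cap_at_certain_death(self):
        lt = LifeTable([60, 62], [0.9, 0.9])
        assert cycle_death_prob(61.0, lt, 2.0, 0.25) == pytest.approx(1.0)


class TestStep:
    def test_no_syncope_rate_means_only_deaths(self, life_table):
        clin = ClinicalParameters(annual_syncope_rate=0.0, horizon_years=3.0)
        res = step(197.0, 0, ArmSpec.ilr(clin), clin, life_table)
        assert res.episodes == 0.0 and res.new_diagnosed == 0.0
        assert res.new_dead > 0.0

    def test_direct_arithmetic(self, flat_life_table):
        clin = ClinicalParameters(horizon_years=3.0)
        res = step(197.0, 0, ArmSpec.ilr(clin), clin, flat_life_table)
        assert res.episodes == pytest.approx(197 * 0.15)         # 29.55
        assert res.new_diagnosed == pytest.approx(197 * 0.15 * 0.628)

    def test_absorbing_limit_everyone_diagnosed_in_one_cycle(self, flat_life_table):
        clin = ClinicalParameters(annual_syncope_rate=4.0, diagnosis_prob_ilr=1.0,
                                  horizon_years=3.0)
        res = step(100.0, 0, ArmSpec.ilr(clin), clin, flat_life_table)
        assert res.new_diagnosed == pytest.approx(100.0)
        assert res.undiagnosed_next == pytest.approx(0.0)

    def test_iterated_step_matches_vectorised_trace(self, clinical3, life_table):
        arm = ArmSpec.ilr(clinical3)
        trace = run_cohort(clinical3, arm, life_table)
        u = clinical3.cohort_size
        for t in range(clinical3.n_cycles):
            res = step(u, t, arm, clinical3, life_table)
            assert res.new_diagnosed == pytest.approx(trace.new_diagnosed[t], rel=1e-12)
            assert res.new_dead == pytest.approx(trace.new_dead[t], rel=1e-12)
            u = res.undiagnosed_next
        assert u == pytest.approx(trace.undiagnosed[-1], rel=1e-12)


class TestRunCohort:
    def test_zero_mortality_matches_geometric_closed_form(self, clinical3,
                                                          flat_life_table):
        trace = run_cohort(clinical3, ArmSpec.cdp(clinical3), flat_life_table)
        T = clinical3.n_cycles
        p = 0.15 * clinical3.diagnosis_prob_cdp
        closed = clinical3.cohort_size * (1 - (1 - p) ** np.arange(1, T + 1))
        np.testing.assert_allclose(trace.cumulative_diagnosed, closed, rtol=1e-13)

    @pytest.mark.parametrize("horizon", [3.0, 30.0])
    @pytest.mark.parametrize("arm_name", ["ilr", "cdp"])
    def test_state_occupancy_conservation(self, life_table, horizon, arm_name):
        clin = ClinicalParameters(horizon_years=horizon)
        arm = getattr(ArmSpec, arm_name)(clin)
        trace = run_cohort(clin, arm, life_table)
        occupancy = (trace.undiagnosed[1:] + trace.cumulative_diagnosed
                     + trace.cumulative_dead)
        np.testing.assert_allclose(occupancy, clin.cohort_size, atol=1e-9)
        assert np.all(trace.undiagnosed >= 0)
        assert np.all(np.diff(trace.cumulative_diagnosed) >= 0)

    def test_diagnosed_monotone_in_yield_episodes_antitone(self, life_table):
        lo = ClinicalParameters(diagnosis_prob_ilr=0.3, horizon_years=30.0)
        hi = ClinicalParameters(diagnosis_prob_ilr=0.7, horizon_years=30.0)
        t_lo = run_cohort(lo, ArmSpec.ilr(lo), life_table)
        t_hi = run_cohort(hi, ArmSpec.ilr(hi), life_table)
        assert np.all(t_hi.cumulative_diagnosed >= t_lo.cumulative_diagnosed - 1e-12)
        assert np.all(t_hi.cumulative_episodes <= t_lo.cumulative_episodes + 1e-12)

    def test_arm_symmetry_with_equal_yields(self, life_table):
        clin = ClinicalParameters(diagnosis_prob_ilr=0.125, horizon_years=30.0)
        t_ilr = run_cohort(clin, ArmSpec.ilr(clin), life_table)
        t_cdp = run_cohort(clin, ArmSpec.cdp(clin), life_table)
        np.testing.assert_allclose(t_ilr.undiagnosed, t_cdp.undiagnosed, rtol=1e-14)
        np.testing.assert_allclose(t_ilr.new_diagnosed, t_cdp.new_diagnosed,
                                   rtol=1e-14)

    def test_ilr_yield_reverts_after_battery_life(self, clinical30):
        delta = ArmSpec.ilr(clinical30).yields(clinical30.n_cycles)
        assert np.all(delta[:12] == 0.628)
        assert np.all(delta[12:] == 0.125)

    def test_life_table_must_cover_cohort_ages(self, clinical30):
        short = LifeTable([61, 70], [0.01, 0.02])
        with pytest.raises(ValueError, match="does not cover"):
            run_cohort(clinical30, ArmSpec.ilr(clinical30), short)

    def test_death_first_ordering_reduces_events(self, clinical30, life_table):
        sim = run_cohort(clinical30, ArmSpec.ilr(clinical30), life_table)
        df = run_cohort(clinical30, ArmSpec.ilr(clinical30), life_table,
                        event_order="death_first")
        assert df.episodes.sum() < sim.episodes.sum()

    @given(delta=st.floats(0.0, 1.0), rate=st.floats(0.0, 2.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_conservation_fuzzed(self, delta, rate, life_table):
        clin = ClinicalParameters(diagnosis_prob_cdp=delta,
                                  annual_syncope_rate=rate, horizon_years=3.0)
        trace = run_cohort(clin, ArmSpec.cdp(clin), life_table)
        occupancy = (trace.undiagnosed[1:] + trace.cumulative_diagnosed
                     + trace.cumulative_dead)
        np.testing.assert_allclose(occupancy, clin.cohort_size, atol=1e-9)


class TestSummarize:
    def test_empty_cohort_summarises_to_zeros(self):
        from syncosim.engine import Arm

        T = 12
        trace = CohortTrace(
            arm_id=Arm.CDP, cohort_size=0.0, start_age=61.0,
            cycle_length_years=0.25, injury_prob_per_event=0.522,
            undiagnosed=np.zeros(T + 1), episodes=np.zeros(T),
            new_diagnosed=np.zeros(T), new_dead=np.zeros(T),
            injuries=np.zeros(T))
        s = summarize(trace)
        assert (s.diagnosed_total, s.episodes, s.injuries, s.deaths) == (0, 0, 0, 0)

    def test_year_boundaries(self, clinical30, life_table):
        trace = run_cohort(clinical30, ArmSpec.ilr(clinical30), life_table)
        s = summarize(trace)
        assert s.diagnosed_year1 <= s.diagnosed_year3 <= s.diagnosed_total
        assert s.horizon_years == 30.0
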