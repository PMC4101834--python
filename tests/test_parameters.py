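"""Parameter types, derived per-event costs and the config file interface."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syncosim import datasets
from syncosim.config import default_bundle, load_config, save_config
from syncosim.params import (ClinicalParameters, CostParameters, LifeTable,
                             PopulationSource, ScenarioProfile,
                             derive_cohort_size, expected_trauma_cost,
                             weighted_workup_cost)


@pytest.mark.parametrize("admissions, fraction, expected", [
    (1010, 0.195, 197),   # base-case national admission statistics
    (100, 0.0, 0),
    (1000, 0.5, 500),
])
def test_cohort_size_from_admission_statistics(admissions, fraction, expected):
    src = PopulationSource(annual_syncope_admissions=admissions,
                           unexplained_recurrent_fraction=fraction)
    assert derive_cohort_size(src) == expected


class TestWorkupCost:
    def test_empty_profile_costs_nothing(self):
        assert weighted_workup_cost(ScenarioProfile("empty")) == 0.0

    def test_single_item_identity_weighting(self):
        p = ScenarioProfile("one", items=[("ECG", 6.50, 1.0)])
        assert weighted_workup_cost(p) == pytest.approx(6.50)

    def test_recomputed_sum_of_published_items(self, profiles):
        # hand-summed unit_price x fraction over the ten published rows
        p = profiles["Baron-Esquivias"]
        assert weighted_workup_cost(p) == pytest.approx(88.5996, abs=1e-3)
        # the engine nevertheless uses the published total
        assert p.canonical_workup_cost == pytest.approx(88.51)

    @pytest.mark.parametrize("name, printed", [
        ("Sousa Pedro", 164.32), ("Edvardsson", 1112.02),
        ("Baron-Esquivias", 88.51), ("Brignole", 173.31), ("Farwell", 72.41),
    ])
    def test_canonical_totals_are_the_published_ones(self, profiles, name,
                                                     printed):
        assert profiles[name].canonical_workup_cost == pytest.approx(printed)

    def test_divergent_printed_total_logs_warning(self, profiles, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="syncosim.params"):
            profiles["Farwell"].canonical_workup_cost
        assert "printed workup total" in caplog.text

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linear_in_unit_prices(self, scale):
        items = [("a", 10.0, 0.5), ("b", 200.0, 0.25)]
        base = weighted_workup_cost(ScenarioProfile("p", items=items))
        scaled = weighted_workup_cost(ScenarioProfile("p", items=[
            (n, price * scale, f) for n, price, f in items]))
        assert scaled == pytest.approx(scale * base)

    @given(f=st.floats(0.0, 1.0), bump=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_fractions(self, f, bump):
        hi = min(1.0, f + bump)
        lo_cost = weighted_workup_cost(
            ScenarioProfile("p", items=[("t", 50.0, f)]))
        hi_cost = weighted_workup_cost(
            ScenarioProfile("p", items=[("t", 50.0, hi)]))
        assert hi_cost >= lo_cost - 1e-12


class TestTraumaCost:
    def test_base_tariff_weighting(self):
        # 2,684.83 x 0.522 x (1 - 0.1616) + 6,058.25 x 0.522 x 0.1616
        got = expected_trauma_cost(2684.83, 6058.25, 0.522, 0.1616)
        assert got == pytest.approx(1686.05, abs=0.01)
        # close to, but not exactly, the canonical published 1,687.57
        assert abs(got - 1687.57) < 2.0

    def test_no_injuries_no_cost(self):
        assert expected_trauma_cost(2684.83, 6058.25, 0.0, 0.1616) == 0.0

    def test_all_severe_all_injured_is_major_tariff(self):
        assert expected_trauma_cost(100.0, 900.0, 1.0, 1.0) == pytest.approx(900.0)

    @given(minor=st.floats(0, 1e4), major=st.floats(0, 1e4),
           p=st.floats(0, 1), s=st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_two_outcome_enumeration_and_bounds(self, minor, major, p, s):
        got = expected_trauma_cost(minor, major, p, s)
        # brute-force enumeration over the two injury outcomes
        enumerated = sum(prob * tariff for prob, tariff in
                         [(p * (1 - s), minor), (p * s, major)])
        assert got == pytest.approx(enumerated, rel=1e-12, abs=1e-9)
        assert 0.0 <= got <= max(minor, major) + 1e-9


class TestValidation:
    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            ClinicalParameters(diagnosis_prob_ilr=1.2)

    def test_event_probability_per_cycle_must_be_valid(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            ClinicalParameters(annual_syncope_rate=5.0)

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            CostParameters(device_acquisition=-1.0)

    def test_discount_rate_support(self):
        with pytest.raises(ValueError):
            CostParameters(annual_discount_rate=1.0)

    def test_explantation_defaults_to_implantation_tariff(self):
        c = CostParameters(implantation=99.0)
        assert c.explantation == 99.0

    def test_fractional_cycle_horizon_rejected(self):
        with pytest.raises(ValueError, match="whole number of cycles"):
            ClinicalParameters(horizon_years=3.1)


class TestLifeTable:
    def test_interpolates_between_table_ages(self):
        lt = LifeTable([60, 62], [0.01, 0.03])
        assert lt.annual_death_prob(61) == pytest.approx(0.02)

    def test_age_outside_range_rejected(self):
        lt = LifeTable([60, 62], [0.01, 0.03])
        with pytest.raises(ValueError, match="outside"):
            lt.annual_death_prob(59.0)

    def test_nonmonotone_ages_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            LifeTable([60, 60], [0.01, 0.02])

    def test_file_round_trip(self, tmp_path, life_table):
        path = tmp_path / "lt.csv"
        life_table.to_file(path)
        again = LifeTable.from_file(path)
        assert np.allclose(again.ages, life_table.ages)
        assert np.allclose(again.probs, life_table.probs, atol=1e-8)


class TestConfigFile:
    def test_round_trips_bit_identically(self, tmp_path):
        p1, p2 = tmp_path / "a.yaml", tmp_path / "b.yaml"
        save_config(default_bundle(), p1)
        save_config(load_config(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_loaded_values_match_base_case(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        save_config(default_bundle(), path)
        bundle = load_config(path)
        assert bundle.clinical == datasets.base_clinical()
        assert bundle.costs == datasets.base_costs()
        assert set(bundle.scenarios) == set(datasets.SCENARIO_NAMES)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("clinical:\n  not_a_field: 1\n")
        with pytest.raises(ValueError, match="unknown key"):
            load_config(path)

    def test_missing_life_table_file_is_a_clean_error(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("life_table_path: does/not/exist.csv\n")
        with pytest.raises(FileNotFoundError):
            load_config(path)
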