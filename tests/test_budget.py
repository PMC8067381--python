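"""Partial-budget components, the ledger identity and its structural
properties."""
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from herdbudget import (
    EconomicInputs,
    ScenarioConfig,
    calf_income_difference,
    extra_feed_cost,
    extra_treatment_cost,
    insemination_cost_saving,
    milk_income,
    net_benefit,
    replacement_cost_saving,
    scenario_from_letter,
)

FIXED_YES = ScenarioConfig("fixed", True)
FIXED_NO = ScenarioConfig("fixed", False)
VAR_YES = ScenarioConfig("variable", True)
VAR_NO = ScenarioConfig("variable", False)


def econ_strategy():
    money = st.floats(0, 2000, allow_nan=False)
    prop = st.floats(0, 0.5, allow_nan=False)
    return st.builds(
        EconomicInputs,
        days_gain=st.floats(0, 30),
        daily_yield_l=st.floats(0, 50),
        milk_price_gbp_per_l=st.floats(0, 1),
        feed_cost_gbp_per_l=st.floats(0, 0.5),
        barren_reduction=prop,
        heifer_cost_gbp=money,
        cull_value_gbp=money,
        treatment_extra_cost_gbp=st.floats(0, 100),
        ai_cost_gbp=st.floats(0, 60),
        services_per_conception_pgod=st.floats(1, 4),
        services_per_conception_moft=st.floats(1, 4),
        conc_first42_pgod=prop, conc_first42_moft=prop,
        conc_second42_pgod=prop, conc_second42_moft=prop,
        calf_value_dairy_male=money, calf_value_dairy_female=money,
        calf_value_beefx_male=money, calf_value_beefx_female=money,
        male_fraction=st.floats(0, 1),
    )


class TestComponents:
    def test_milk_income_fixed_dry_off(self, default_inputs):
        assert milk_income(default_inputs, FIXED_YES) == pytest.approx(26.88)

    def test_milk_income_omitted_under_variable_dry_off(self, default_inputs):
        assert milk_income(default_inputs, VAR_YES) == 0.0

    def test_milk_income_no_gain_no_income(self, default_inputs):
        assert milk_income(replace(default_inputs, days_gain=0.0), FIXED_YES) == 0.0

    def test_calf_income_worked_example(self):
        """Sex-flattened calf values GBP 110 (dairy) and 165 (beef-cross)."""
        inputs = EconomicInputs(
            conc_first42_pgod=0.70, conc_second42_pgod=0.10,
            conc_first42_moft=0.77, conc_second42_moft=0.09,
            calf_value_dairy_male=110, calf_value_dairy_female=110,
            calf_value_beefx_male=165, calf_value_beefx_female=165,
        )
        assert calf_income_difference(inputs, FIXED_YES) == pytest.approx(6.05)

    def test_identical_mixes_give_zero_calf_income(self):
        inputs = EconomicInputs(
            conc_first42_moft=0.70, conc_second42_moft=0.10,
        )
        assert calf_income_difference(inputs, FIXED_YES) == pytest.approx(0.0)
        assert calf_income_difference(inputs, FIXED_NO) == pytest.approx(0.0)

    def test_beef_shift_sign_follows_value_gap(self):
        """With equal totals, shifting the mix toward beef pays exactly
        when a beef-cross calf is worth more than a dairy calf."""
        inputs = EconomicInputs(
            conc_first42_pgod=0.40, conc_second42_pgod=0.40,
            conc_first42_moft=0.10, conc_second42_moft=0.70,
        )
        assert calf_income_difference(inputs, FIXED_NO) > 0
        flipped = replace(
            inputs,
            calf_value_dairy_male=300, calf_value_dairy_female=300,
            calf_value_beefx_male=100, calf_value_beefx_female=100,
        )
        assert calf_income_difference(flipped, FIXED_NO) < 0

    def test_ai_saving(self, default_inputs):
        assert insemination_cost_saving(default_inputs) == pytest.approx(1.40)
        equal = replace(default_inputs, services_per_conception_moft=1.72)
        assert insemination_cost_saving(equal) == 0.0
        free = replace(default_inputs, ai_cost_gbp=0.0)
        assert insemination_cost_saving(free) == 0.0

    def test_replacement_saving(self, default_inputs):
        assert replacement_cost_saving(default_inputs, FIXED_YES) == pytest.approx(51.84)
        assert replacement_cost_saving(default_inputs, FIXED_NO) == 0.0
        zero = replace(default_inputs, barren_reduction=0.0)
        assert replacement_cost_saving(zero, FIXED_YES) == 0.0

    def test_extra_feed_cost(self, default_inputs):
        nine_p = replace(default_inputs, feed_cost_gbp_per_l=0.09)
        assert extra_feed_cost(nine_p) == pytest.approx(8.64)
        assert extra_feed_cost(replace(default_inputs, feed_cost_gbp_per_l=0.0)) == 0.0
        assert extra_feed_cost(replace(default_inputs, days_gain=0.0)) == 0.0

    def test_feed_charged_under_both_dry_off_policies(self, default_inputs):
        for sc in (FIXED_YES, VAR_YES):
            assert net_benefit(default_inputs, sc).feed_cost == pytest.approx(11.424)

    def test_extra_treatment_cost(self, default_inputs):
        assert extra_treatment_cost(default_inputs) == 18.0
        assert extra_treatment_cost(
            replace(default_inputs, treatment_extra_cost_gbp=24.0)) == 24.0

    def test_only_treatment_cost_survives_null_comparison(self):
        inputs = EconomicInputs(
            days_gain=0.0, services_per_conception_moft=1.72,
            conc_first42_moft=0.70, conc_second42_moft=0.10,
            barren_reduction=0.0,
        )
        assert net_benefit(inputs, FIXED_YES).net_benefit == pytest.approx(-18.0)


class TestNetBenefit:
    def test_reproduces_published_scenarios(self, default_inputs):
        assert round(net_benefit(default_inputs, FIXED_YES).net_benefit, 2) == 53.42
        assert round(net_benefit(default_inputs, VAR_YES).net_benefit, 2) == 26.54

    @settings(max_examples=100, deadline=None)
    @given(inputs=econ_strategy(), letter=st.sampled_from("abcd"))
    def test_ledger_identity(self, inputs, letter):
        r = net_benefit(inputs, scenario_from_letter(letter))
        assert r.net_benefit == pytest.approx(
            r.milk_income + r.calf_income + r.ai_saving + r.replacement_saving
            - r.treatment_cost - r.feed_cost - r.returns_foregone, abs=1e-9,
        )
        assert r.returns_foregone == 0.0

    @settings(max_examples=100, deadline=None)
    @given(inputs=econ_strategy(), improve=st.booleans())
    def test_dry_off_difference_is_gross_milk_revenue(self, inputs, improve):
        fixed = net_benefit(inputs, ScenarioConfig("fixed", improve)).net_benefit
        variable = net_benefit(inputs, ScenarioConfig("variable", improve)).net_benefit
        milk = inputs.days_gain * inputs.daily_yield_l * inputs.milk_price_gbp_per_l
        assert fixed - variable == pytest.approx(milk, abs=1e-9)

    @pytest.mark.parametrize("field,points", [
        ("heifer_cost_gbp", (1000.0, 1400.0, 1800.0)),
        ("milk_price_gbp_per_l", (0.1, 0.2, 0.3)),
        ("barren_reduction", (0.0, 0.05, 0.10)),
        ("treatment_extra_cost_gbp", (0.0, 20.0, 40.0)),
        ("conc_second42_moft", (0.02, 0.06, 0.10)),
    ])
    def test_affine_in_each_input(self, default_inputs, field, points):
        """Three-point collinearity: the mid net benefit is the mean of
        the extremes for an evenly spaced sweep of any single input."""
        lo, mid, hi = (
            net_benefit(replace(default_inputs, **{field: v}), FIXED_YES).net_benefit
            for v in points
        )
        assert mid == pytest.approx((lo + hi) / 2, abs=1e-9)

    def test_monotonicity_in_costs(self, default_inputs):
        cheaper, dearer = (
            net_benefit(replace(default_inputs, heifer_cost_gbp=v), FIXED_YES).net_benefit
            for v in (1200.0, 1800.0)
        )
        assert dearer >= cheaper
        low_tc, high_tc = (
            net_benefit(replace(default_inputs, treatment_extra_cost_gbp=v),
                        FIXED_YES).net_benefit
            for v in (12.0, 24.0)
        )
        assert high_tc <= low_tc

    def test_scenario_letters_map_to_the_four_combinations(self):
        seen = {(s.dry_off, s.barren_improvement)
                for s in map(scenario_from_letter, "abcd")}
        assert seen == {("fixed", True), ("fixed", False),
                        ("variable", True), ("variable", False)}
        with pytest.raises(ValueError):
            scenario_from_letter("e")

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            EconomicInputs(milk_price_gbp_per_l=-0.1)
        with pytest.raises(ValueError):
            EconomicInputs(conc_first42_moft=0.8, conc_second42_moft=0.3)
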