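"""Vial arithmetic, supportive care, toxicity costs and aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sarcoma_cea.costing import (
    CATEGORIES,
    aggregate_costs,
    cheapest_vial_combination,
    cost_structure,
    cycle_cost,
    drug_acquisition_cost,
    expected_toxicity_cost,
    supportive_medication_cost,
    treatment_cycle_cost,
)
from sarcoma_cea.engine import build_state_space, run_cohort
from sarcoma_cea.reference import load_published_results


class TestVialArithmetic:
    def test_trabectedin_italy_worked_example(self, italy):
        # 1.3 mg/m2 x 1.8 m2 = 2.34 mg -> three 1-mg vials
        cost, orders = drug_acquisition_cost(
            italy.regimens["trabectedin"], italy.costs, bsa_m2=1.8
        )
        assert cost == pytest.approx(3 * 2970.1)
        (order,) = orders
        assert order.required_mg == pytest.approx(2.34)
        assert order.vials == ((1.0, 3),)

    def test_doxorubicin_component_italy_worked_example(self, italy):
        # 66 mg/m2 x 1.8 = 118.8 mg -> three 50-mg vials at EUR 119.5
        combo, cost = cheapest_vial_combination(118.8, italy.costs.vials["doxorubicin"])
        assert combo == ((50.0, 3),)
        assert cost == pytest.approx(358.5)

    def test_mesna_added_at_ifosfamide_dose(self, italy):
        cost, orders = drug_acquisition_cost(
            italy.regimens["doxorubicin_ifosfamide"], italy.costs, bsa_m2=1.8
        )
        by_drug = {o.drug: o for o in orders}
        assert by_drug["mesna"].required_mg == by_drug["ifosfamide"].required_mg
        # dox 3 x 119.5 + ifosfamide 16 x 30.7 + mesna 3 x 25.7
        assert cost == pytest.approx(358.5 + 16 * 30.7 + 3 * 25.7)

    def test_zero_dose_component_costs_nothing(self):
        combo, cost = cheapest_vial_combination(0.0, [(50.0, 100.0)])
        assert combo == () and cost == 0.0

    def test_multi_strength_picks_cheapest_combination(self):
        # one 80-mg vial is cheaper than four 20-mg vials for a 75-mg dose
        combo, cost = cheapest_vial_combination(75.0, [(20.0, 30.0), (80.0, 100.0)])
        assert cost == 100.0
        # but 20-mg vials win when the large vial is overpriced
        combo, cost = cheapest_vial_combination(75.0, [(20.0, 30.0), (80.0, 200.0)])
        assert combo == ((20.0, 4),) and cost == 120.0

    @given(
        dose=st.floats(min_value=0.1, max_value=5000.0),
        strength=st.floats(min_value=0.5, max_value=1000.0),
        price=st.floats(min_value=0.1, max_value=5000.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_single_strength_count_is_minimal_cover(self, dose, strength, price):
        combo, cost = cheapest_vial_combination(dose, [(strength, price)])
        ((s, count),) = combo
        assert count == math.ceil(dose / strength - 1e-12)
        assert count * strength >= dose - 1e-9
        assert cost == pytest.approx(count * price)


class TestSupportiveMedication:
    def test_sweden_doxifos_premeds_worked_example(self, sweden):
        cost = supportive_medication_cost(
            sweden.regimens["doxorubicin_ifosfamide"],
            sweden.costs,
            sweden.resource,
            include_gcsf=False,
        )
        assert cost == pytest.approx(3.2 + 20.5)  # betamethasone + tropisetron

    def test_gcsf_italy_expected_cost(self, italy):
        reg = italy.regimens["doxorubicin_ifosfamide"]
        with_g = supportive_medication_cost(reg, italy.costs, italy.resource)
        without = supportive_medication_cost(
            reg, italy.costs, italy.resource, include_gcsf=False
        )
        assert with_g - without == pytest.approx(0.65 * 149.8)

    def test_regimen_without_matching_entries_costs_nothing(self, sweden):
        # trabectedin in Sweden receives only its own premedication entry
        cost = supportive_medication_cost(
            sweden.regimens["trabectedin"], sweden.costs, sweden.resource,
            include_gcsf=False,
        )
        assert cost == pytest.approx(2 * 6.4)
        # and no G-CSF prophylaxis applies
        assert sweden.resource.gcsf.proportion_for(sweden.regimens["trabectedin"]) == 0.0


class TestToxicityCost:
    def test_first_line_doxifos_italy_dot_product(self, italy):
        cost = expected_toxicity_cost(
            italy.toxicity[("doxorubicin_ifosfamide", "first")], italy.costs
        )
        expected = 0.82 * 523.3 + 0.12 * 3305.0 + 0.23 * 1354.8 + 0.35 * 1354.8
        assert cost == pytest.approx(expected)
        assert cost == pytest.approx(1611.5, abs=0.05)

    def test_first_line_trabectedin_italy_dot_product(self, italy):
        cost = expected_toxicity_cost(
            italy.toxicity[("trabectedin", "first")], italy.costs
        )
        assert cost == pytest.approx(0.33 * 523.3 + 0.03 * 1354.8)
        assert cost == pytest.approx(213.3, abs=0.05)

    def test_zero_probabilities_cost_nothing(self, italy):
        from sarcoma_cea.parameters import ToxicityProfile

        assert expected_toxicity_cost(ToxicityProfile(0, 0, 0, 0), italy.costs) == 0.0

    def test_sweden_has_no_neutropenia_management_price(self, sweden):
        # mirrors the Swedish tariff list: plain neutropenia costs zero
        from sarcoma_cea.parameters import ToxicityProfile

        only_neutropenia = ToxicityProfile(1.0, 0.0, 0.0, 0.0)
        assert expected_toxicity_cost(only_neutropenia, sweden.costs) == 0.0


class TestCycleCost:
    def test_dead_compartment_costs_nothing(self, italy):
        space = build_state_space(italy, "doxorubicin_ifosfamide")
        bd = cycle_cost(space.dead, space, italy)
        assert bd.total == 0.0
        assert all(v == 0.0 for v in bd.amounts.values())

    def test_hospitalisation_uses_admission_days(self, italy, spain):
        bd = treatment_cycle_cost(
            italy.regimens["doxorubicin_ifosfamide"], italy, "first_line_cytotoxics"
        )
        assert bd.amounts["hospitalisation"] == pytest.approx(3.0 * 238.3)
        bd = treatment_cycle_cost(
            spain.regimens["doxorubicin_ifosfamide"], spain, "first_line_cytotoxics"
        )
        assert bd.amounts["hospitalisation"] == pytest.approx(4.0 * 212.9)

    def test_followup_cycle_contributes_only_evaluation_costs(self, italy):
        space = build_state_space(italy, "doxorubicin_ifosfamide")
        # a CR tunnel position beyond the treatment course is follow-up
        idx = space.index["CR1_t5"]
        assert not space.compartments[idx].on_treatment
        bd = cycle_cost(idx, space, italy)
        assert bd.amounts["evaluations"] > 0
        assert bd.total == pytest.approx(bd.amounts["evaluations"])

    def test_dose_reduction_lowers_late_course_acquisition(self, italy):
        pre = treatment_cycle_cost(
            italy.regimens["trabectedin"], italy, "first_line_cytotoxics", reduced=False
        )
        post = treatment_cycle_cost(
            italy.regimens["trabectedin"], italy, "first_line_cytotoxics", reduced=True
        )
        mult = italy.resource.dose_reduction.multiplier
        assert mult == pytest.approx(1 - 0.18 * 0.23)
        assert post.amounts["first_line_cytotoxics"] == pytest.approx(
            pre.amounts["first_line_cytotoxics"] * mult
        )


class TestAggregation:
    def test_published_italy_trabectedin_categories_sum_to_total(self):
        published = load_published_results()
        r = published[("italy", "trabectedin")]
        assert r.breakdown.total == pytest.approx(40631.7, abs=0.05)

    def test_published_spain_doxifos_categories_sum_to_total(self):
        published = load_published_results()
        r = published[("spain", "doxorubicin_ifosfamide")]
        assert r.breakdown.total == pytest.approx(30699.4, abs=0.05)

    def test_total_is_exact_category_sum(self, all_countries):
        for params in all_countries.values():
            for strategy in ("doxorubicin_ifosfamide", "trabectedin"):
                traj = run_cohort(params, strategy)
                bd = aggregate_costs(traj, params)
                assert bd.total == sum(bd.amounts.values())
                assert all(v >= 0 for v in bd.amounts.values())

    def test_costs_increase_with_any_unit_cost(self, italy):
        from sarcoma_cea.sensitivity import _resolve

        traj = run_cohort(italy, "doxorubicin_ifosfamide")
        base = aggregate_costs(traj, italy).total
        # +20% on any unit cost never lowers the total
        for path in ("cost.palliative_care", "cost.hospitalisation_day",
                     "vial.trabectedin", "cost.manage_anaemia"):
            value, setter = _resolve(italy, path)
            up = setter(value * 1.2)
            traj_up = run_cohort(up, "doxorubicin_ifosfamide")
            assert aggregate_costs(traj_up, up).total >= base

    def test_cost_contribution_is_linear_in_occupancy(self, italy):
        space = build_state_space(italy, "doxorubicin_ifosfamide")
        traj = run_cohort(italy, "doxorubicin_ifosfamide", space=space)
        bd = aggregate_costs(traj, italy)
        doubled = run_cohort(italy, "doxorubicin_ifosfamide", space=space)
        doubled.occupancy = traj.occupancy * 2.0
        doubled.palliative_entries = traj.palliative_entries * 2.0
        bd2 = aggregate_costs(doubled, italy)
        for cat in CATEGORIES:
            assert bd2.amounts[cat] == pytest.approx(2 * bd.amounts[cat])

    def test_empty_trajectory_costs_nothing(self, italy):
        space = build_state_space(italy, "doxorubicin_ifosfamide")
        traj = run_cohort(italy, "doxorubicin_ifosfamide", space=space)
        traj.occupancy = np.zeros_like(traj.occupancy)
        traj.palliative_entries = np.zeros_like(traj.palliative_entries)
        bd = aggregate_costs(traj, italy)
        assert bd.total == 0.0

    def test_diagnosis_charged_once_at_entry(self, italy):
        structure = cost_structure(
            build_state_space(italy, "doxorubicin_ifosfamide"), italy
        )
        diag_row = structure.per_cycle[CATEGORIES.index("diagnosis")]
        assert np.count_nonzero(diag_row) == 1
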