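"""Cohort engine: discounting, transition/accrual logic, conservation laws."""
import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from silatro_cea import CohortState, discount_factor, run_arm, step_cycle
from silatro_cea.cohort import COST_CATEGORIES
from silatro_cea.parameters import ValidationError


def _no_decrement(params):
    """Switch off mortality and discounting for closed-form checks."""
    return (
        params.with_value("p_death_cycle", 0.0)
        .with_value("discount_costs", 0.0)
        .with_value("discount_outcomes", 0.0)
    )


def _trace_states(params, arm, settings):
    state = CohortState()
    states = [dataclasses.replace(state)]
    for _ in range(settings.horizon_cycles):
        state, _ledger = step_cycle(state, params, arm, settings)
        states.append(state)
    return states


class TestDiscounting:
    @pytest.mark.parametrize("convention", ["per_cycle", "annual_step"])
    def test_first_cycle_undiscounted(self, convention):
        assert discount_factor(1, 0.03, convention) == 1.0

    def test_annual_step_year_two(self):
        assert discount_factor(4, 0.03, "annual_step") == pytest.approx(1 / 1.03)
        assert discount_factor(3, 0.03, "annual_step") == 1.0

    def test_per_cycle_geometric(self):
        assert discount_factor(2, 0.03, "per_cycle") == pytest.approx(1.03 ** (-1 / 3))

    def test_cycle_index_is_one_based(self):
        with pytest.raises(ValidationError):
            discount_factor(0, 0.03)


class TestStepCycle:
    def test_first_cycle_expected_events(self, adult_params, settings):
        _, ledger = step_cycle(CohortState(), adult_params, "usual_care", settings)
        # 0.21 * 0.66 on the (barely decremented) at-risk cohort
        assert ledger.expected_atis == pytest.approx(0.1386, rel=1e-3)

    def test_zero_ati_limit(self, adult_params, settings):
        params = adult_params.with_value("p_ati_int", 0.0).with_value("p_ati_uc", 0.0)
        for arm in ("intervention", "usual_care"):
            res = run_arm(params, arm, settings)
            assert res.total_atis == 0.0
            assert res.categories["antibiotics"] == 0.0
            assert res.categories["productivity_loss"] == 0.0
            assert res.categories["gp_consultations"] > 0.0  # baseline presentations
        res_int = run_arm(params, "intervention", settings)
        assert res_int.categories["adjuvant_therapy"] > 0.0

    def test_invalid_arm_rejected(self, adult_params, settings):
        with pytest.raises(ValidationError):
            step_cycle(CohortState(), adult_params, "placebo", settings)


class TestRunArm:
    def test_base_case_never_triggers_surgery(self, adult_params, child_params, settings):
        # 2.5 prior ATIs + at most ~0.83 expected in-model events stays below 4
        for params in (adult_params, child_params):
            for arm in ("intervention", "usual_care"):
                res = run_arm(params, arm, settings)
                assert res.surgeries == 0.0
                assert res.categories["tonsillectomy_surgery"] == 0.0

    def test_total_atis_closed_form_without_decrements(self, adult_params, settings):
        res = run_arm(_no_decrement(adult_params), "usual_care", settings)
        assert res.total_atis == pytest.approx(6 * 0.21 * 0.66, abs=1e-10)
        assert res.total_atis == res.total_atis_undiscounted

    def test_discounted_never_exceeds_undiscounted(self, adult_params, settings):
        res = run_arm(adult_params, "usual_care", settings)
        assert res.total_atis <= res.total_atis_undiscounted
        for ledger in res.trace:
            for cat in COST_CATEGORIES:
                assert ledger.discounted[cat] <= ledger.undiscounted[cat] + 1e-15

    def test_total_cost_is_sum_of_categories(self, adult_params, settings):
        res = run_arm(adult_params, "intervention", settings)
        assert res.total_cost == pytest.approx(sum(res.categories.values()), abs=1e-9)

    def test_productivity_component_linear_in_unit_cost(self, adult_params, settings):
        base = run_arm(adult_params, "usual_care", settings)
        doubled = run_arm(
            adult_params.with_value(
                "daily_productivity_cost", 2 * adult_params.value("daily_productivity_cost")
            ),
            "usual_care",
            settings,
        )
        assert doubled.categories["productivity_loss"] == pytest.approx(
            2 * base.categories["productivity_loss"], rel=1e-12
        )

    def test_atis_and_cost_monotone_in_ati_probability(self, adult_params, settings):
        grid = [0.105, 0.15, 0.21, 0.27, 0.315]
        atis = []
        costs = []
        for p in grid:
            res = run_arm(adult_params.with_value("p_ati_uc", p), "usual_care", settings)
            atis.append(res.total_atis)
            costs.append(res.total_cost)
        assert all(a < b for a, b in zip(atis, atis[1:]))
        assert all(a < b for a, b in zip(costs, costs[1:]))

    def test_dead_state_matches_survival_closed_form(self, adult_params, settings):
        p = adult_params.value("p_death_cycle")
        states = _trace_states(adult_params, "usual_care", settings)
        assert states[-1].occ_dead == pytest.approx(1 - (1 - p) ** 6, rel=1e-9)

    def test_surgery_pathway_accrues_costs(self, adult_params, settings):
        # high baseline history puts the usual-care cohort over the 4-ATI bar
        params = adult_params.with_value("prior_atis", 3.5)
        res = run_arm(params, "usual_care", settings)
        assert res.surgeries > 0.0
        assert res.categories["tonsillectomy_surgery"] > 0.0
        assert res.categories["tonsillectomy_travel_time"] > 0.0


class TestConservation:
    @given(
        p_ati=st.floats(0.0, 1.0),
        n_given=st.floats(0.0, 2.0),
        p_death=st.floats(0.0, 0.2),
        prior=st.floats(0.0, 6.0),
        p_surg=st.floats(0.0, 1.0),
    )
    def test_occupancies_conserved_and_absorbing(
        self, config, p_ati, n_given, p_death, prior, p_surg
    ):
        """Occupancy mass is conserved each cycle; dead and post-surgery
        occupancies and the cumulative expected event count never decrease."""
        settings, sets = config
        params = (
            sets["adults_adolescents"]
            .with_value("p_ati_uc", p_ati)
            .with_value("n_ati_given_ati_uc", n_given)
            .with_value("p_death_cycle", p_death)
            .with_value("prior_atis", prior)
            .with_value("p_surgery_if_eligible", p_surg)
        )
        states = _trace_states(params, "usual_care", settings)
        for s in states:
            total = s.occ_well + s.occ_post_surgery + s.occ_dead
            assert total == pytest.approx(1.0, abs=1e-12)
        for a, b in zip(states, states[1:]):
            assert b.occ_dead >= a.occ_dead - 1e-15
            assert b.occ_post_surgery >= a.occ_post_surgery - 1e-15
            assert b.cum_expected_atis >= a.cum_expected_atis - 1e-15
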