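"""Markov cohort engine: tunnel structure, transitions, accruals."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from renalcea import (
    DIALYSIS_STATES,
    ExpandedState,
    HealthState,
    Perspective,
    RateConversion,
    baseline_config,
    build_transition_model,
    rate_to_probability,
    run_cohort,
)
from renalcea.engine import (
    DEATH_STATE,
    StateSpace,
    cycle_distribution,
    entry_event_cost,
    state_annual_cost,
    transition_event_cost,
)
from renalcea.states import HomeHDMortalityMode
from renalcea.cea import discount_sum
from renalcea.synthetic import edge_config

S = HealthState


class TestRateConversion:
    def test_zero_rate(self):
        assert rate_to_probability(0.0, RateConversion.EXPONENTIAL) == 0.0
        assert rate_to_probability(0.0, RateConversion.LINEAR) == 0.0

    def test_exponential_closed_form(self):
        # constant-hazard conversion of the PD mortality rate
        assert rate_to_probability(15.21) == pytest.approx(1 - math.exp(-0.1521))
        assert rate_to_probability(15.21) == pytest.approx(0.14110, abs=5e-6)

    def test_linear_is_direct_division_capped(self):
        assert rate_to_probability(19.45, RateConversion.LINEAR) == 0.1945
        assert rate_to_probability(250.0, RateConversion.LINEAR) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-1.0)

    @given(st.floats(min_value=0, max_value=500))
    def test_exponential_below_linear_and_in_unit_interval(self, rate):
        p_exp = rate_to_probability(rate, RateConversion.EXPONENTIAL)
        p_lin = rate_to_probability(rate, RateConversion.LINEAR)
        assert 0.0 <= p_exp <= 1.0
        assert p_exp <= p_lin + 1e-12


class TestCycleDistribution:
    def test_transplant_only_stays_or_dies(self, baseline):
        space = StateSpace(10, 5)
        dist = cycle_distribution(ExpandedState(S.TRANSPLANT, 3), baseline, space)
        assert set(dist) == {ExpandedState(S.TRANSPLANT, 4), DEATH_STATE}
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_home_hd_never_reaches_pd(self, baseline):
        space = StateSpace(10, 5)
        dist = cycle_distribution(ExpandedState(S.HOME_HD, 2), baseline, space)
        assert not any(s.health == S.PD for s in dist)

    def test_competing_risk_product(self, baseline):
        """Death, transplant and switching compose multiplicatively."""
        baseline.conventions.rate_conversion = RateConversion.LINEAR
        baseline.clinical.mortality_rates[S.PD] = 10.0  # p_d = 0.1
        baseline.clinical.transplant_rate = 0.1
        space = StateSpace(10, 5)
        dist = cycle_distribution(ExpandedState(S.PD, 1), baseline, space)
        assert dist[ExpandedState(S.PD, 2)] == pytest.approx(0.9 * 0.9 * 0.888)
        assert dist[DEATH_STATE] == pytest.approx(0.1)
        assert dist[ExpandedState(S.TRANSPLANT, 1)] == pytest.approx(0.9 * 0.1)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_death_is_terminal_origin(self, baseline):
        with pytest.raises(ValueError):
            cycle_distribution(DEATH_STATE, baseline, StateSpace(10, 5))

    def test_zero_routed_mode_diverts_death_mass_to_hospital(self, baseline):
        baseline.conventions.home_hd_mortality_mode = (
            HomeHDMortalityMode.ZERO_ROUTED_VIA_HOSP
        )
        space = StateSpace(10, 5)
        dist = cycle_distribution(ExpandedState(S.HOME_HD, 1), baseline, space)
        assert DEATH_STATE not in dist
        assert sum(dist.values()) == pytest.approx(1.0)


class TestEventCosts:
    def test_death_transitions_are_free(self, baseline_with_events):
        assert (
            transition_event_cost(
                ExpandedState(S.PD, 4), DEATH_STATE, baseline_with_events
            )
            == 0.0
        )

    def test_hd_to_hd_switch_charges_training_only(self, baseline_with_events):
        # shared vascular access: no removal, no new access surgery
        cost = transition_event_cost(
            ExpandedState(S.HOSP_HD, 2),
            ExpandedState(S.HOME_HD, 1),
            baseline_with_events,
        )
        assert cost == 12184.6

    def test_pd_retraining_every_interval(self, baseline_with_events):
        c5 = transition_event_cost(
            ExpandedState(S.PD, 5), ExpandedState(S.PD, 6), baseline_with_events
        )
        c4 = transition_event_cost(
            ExpandedState(S.PD, 4), ExpandedState(S.PD, 5), baseline_with_events
        )
        assert c5 == 1692.3 and c4 == 0.0

    def test_transplant_charges_removal_plus_operation(self, baseline_with_events):
        cost = transition_event_cost(
            ExpandedState(S.PD, 2), ExpandedState(S.TRANSPLANT, 1), baseline_with_events
        )
        assert cost == pytest.approx(3192.3 + 10278.8)

    def test_pd_to_hd_switch_charges_removal_access_training(self, baseline_with_events):
        cost = transition_event_cost(
            ExpandedState(S.PD, 1), ExpandedState(S.HOSP_HD, 1), baseline_with_events
        )
        blended = 0.3 * 2057.7 + 0.7 * 6384.6
        assert cost == pytest.approx(3192.3 + blended + 0.0)

    def test_flag_disables_all_event_costs(self, baseline):
        assert not baseline.conventions.include_event_costs
        assert (
            transition_event_cost(
                ExpandedState(S.PD, 5), ExpandedState(S.PD, 6), baseline
            )
            == 0.0
        )
        assert entry_event_cost(S.HOME_HD, baseline) == 0.0

    def test_entry_event_is_access_plus_training(self, baseline_with_events):
        blended = 0.3 * 2057.7 + 0.7 * 6384.6
        assert entry_event_cost(S.HOME_HD, baseline_with_events) == pytest.approx(
            blended + 12184.6
        )
        assert entry_event_cost(S.PD, baseline_with_events) == pytest.approx(
            3192.3 + 1692.3
        )


class TestStateAnnualCost:
    @pytest.mark.parametrize(
        "state, years, perspective, expected",
        [
            (S.PD, 1, Perspective.PROVIDER, 15188.1),
            (S.PD, 3, Perspective.PROVIDER, 10358.5),
            (S.HOSP_HD, 2, Perspective.SOCIETAL, 52950.9),
            (S.TRANSPLANT, 1, Perspective.PROVIDER, 1678.2),
            (S.TRANSPLANT, 7, Perspective.SOCIETAL, 610.3),
        ],
    )
    def test_initial_vs_subsequent_year(self, baseline, state, years, perspective, expected):
        assert state_annual_cost(ExpandedState(state, years), baseline, perspective) == expected

    def test_death_costs_nothing(self, baseline):
        assert state_annual_cost(DEATH_STATE, baseline) == 0.0


class TestTransitionModel:
    def test_rows_are_stochastic_and_death_absorbing(self, baseline_with_events):
        model = build_transition_model(baseline_with_events)
        np.testing.assert_allclose(model.matrix.sum(axis=1), 1.0, atol=1e-9)
        i = model.space.death_index
        assert model.matrix[i, i] == 1.0

    def test_modality_entries_land_in_year_one(self, baseline):
        model = build_transition_model(baseline)
        for i, origin in enumerate(model.space.states):
            for j in np.nonzero(model.matrix[i])[0]:
                dest = model.space.states[j]
                if dest.health != origin.health and dest.health != S.DEATH:
                    assert dest.years_in_state == 1


class TestCohortTrace:
    def test_conservation_and_monotone_death(self, baseline):
        for strategy in DIALYSIS_STATES:
            trace = run_cohort(strategy, baseline)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            dead = trace.occupancy[:, trace.space.death_index]
            assert (np.diff(dead) >= -1e-12).all()
            # most of the cohort dies within the horizon; the residual is the
            # transplanted fraction surviving on the low 2/100 py rate
            assert dead[-1] > 0.8

    def test_no_mortality_means_no_absorption(self):
        config = edge_config("IMMORTAL")
        trace = run_cohort(S.PD, config)
        assert trace.occupancy[:, trace.space.death_index].max() == 0.0

    def test_maximal_disutility_zeroes_qalys(self, baseline):
        from renalcea import apply_parameter

        for s in (S.PD, S.HOSP_HD, S.HOME_HD, S.TRANSPLANT):
            baseline = apply_parameter(baseline, f"disutility.{s.value}", 1.0)
        trace = run_cohort(S.HOSP_HD, baseline)
        assert trace.cycle_qalys.sum() == 0.0

    def test_certain_death_leaves_one_cycle_of_utility(self):
        """With annual death probability 1, only cycle 0 accrues anything."""
        config = edge_config("INSTANT_DEATH")
        trace = run_cohort(S.PD, config)
        assert trace.cycle_qalys[0] == pytest.approx(1 - 0.222)
        assert trace.cycle_qalys[1:].sum() == 0.0
        assert trace.cycle_costs[0] == pytest.approx(15188.1)

    def test_tunnel_cap_preserves_results_and_retraining_periodicity(self, baseline_with_events):
        """Lifetime outcomes are insensitive to the tracked years-in-state cap
        as long as the wrap keeps the retraining phase (modular counting)."""
        results = {}
        for depth in (10, 20, None):
            cfg = baseline_with_events.copy()
            cfg.conventions.tunnel_depth = depth
            trace = run_cohort(S.PD, cfg)
            results[depth] = (trace.cycle_costs.sum(), trace.cycle_qalys.sum())
        for depth in (10, 20):
            assert results[depth][0] == pytest.approx(results[None][0], rel=1e-3)
            assert results[depth][1] == pytest.approx(results[None][1], rel=1e-3)

    def test_half_cycle_correction_halves_terminal_cycles(self, baseline):
        full = run_cohort(S.PD, baseline)
        baseline.conventions.half_cycle_correction = True
        half = run_cohort(S.PD, baseline)
        assert half.cycle_qalys[0] == pytest.approx(full.cycle_qalys[0] / 2)
        assert half.cycle_qalys[1] == pytest.approx(full.cycle_qalys[1])

    def test_trace_frame_is_plot_ready(self, baseline):
        df = run_cohort(S.HOME_HD, baseline).to_frame()
        assert list(df.columns[:1]) == ["cycle"]
        assert {"PD", "HOSP_HD", "HOME_HD", "TRANSPLANT", "DEATH", "cycle_cost", "cycle_qalys"} <= set(df.columns)
        assert len(df) == baseline.conventions.horizon_years

    def test_invalid_strategy_rejected(self, baseline):
        with pytest.raises(ValueError):
            run_cohort(S.TRANSPLANT, baseline)
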