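"""Signal schedules, nutrition scaling, and the two MAPK interfaces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import yeastcycle as yc
from yeastcycle.perturbation import (
    SignalSchedule,
    apply_nutrition,
    hog1_terms,
    pheromone_terms,
    signal_at,
)


class TestSignalAt:
    def test_half_open_interval_convention(self):
        schedule = SignalSchedule(pheromone_intervals=((10.0, 140.0),))
        assert signal_at(schedule, 10.0).pheromone_on is True
        assert signal_at(schedule, 139.999).pheromone_on is True
        assert signal_at(schedule, 140.0).pheromone_on is False
        assert signal_at(schedule, 9.999).pheromone_on is False

    def test_empty_schedule_gives_default_state(self):
        schedule = SignalSchedule(nutrition_factor=1.3)
        state = signal_at(schedule, 42.0)
        assert (state.pheromone_on, state.osmostress_on) == (False, False)
        assert state.nutrition_factor == 1.3

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            signal_at(SignalSchedule(), -1.0)

    @pytest.mark.parametrize("intervals", [
        (((-5.0, 10.0),)),            # negative start
        (((20.0, 10.0),)),            # reversed
        (((0.0, 10.0), (5.0, 15.0))), # overlap
    ])
    def test_invalid_intervals_rejected(self, intervals):
        with pytest.raises(ValueError):
            SignalSchedule(pheromone_intervals=intervals)

    @given(st.lists(st.tuples(st.floats(0, 500), st.floats(1, 100)),
                    min_size=1, max_size=4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_signal_matches_interval_membership(self, raw):
        # build disjoint sorted intervals from random (start, width) pairs
        intervals, cursor = [], 0.0
        for start, width in raw:
            t_on = cursor + start
            intervals.append((t_on, t_on + width))
            cursor = t_on + width + 1.0
        schedule = SignalSchedule(osmostress_intervals=tuple(intervals))
        for t_on, t_off in intervals:
            assert signal_at(schedule, t_on).osmostress_on
            assert signal_at(schedule, 0.5 * (t_on + t_off)).osmostress_on
            assert not signal_at(schedule, t_off).osmostress_on


class TestApplyNutrition:
    def test_identity_at_factor_one(self, model):
        scaled = apply_nutrition(model.parameters, 1.0)
        assert scaled.values == model.parameters.values

    def test_pure_function_and_subset_scaling(self, model):
        before = dict(model.parameters.values)
        scaled = apply_nutrition(model.parameters, 1.7)
        assert model.parameters.values == before  # input untouched
        for name, value in before.items():
            if name in model.parameters.production_subset:
                assert scaled[name] == pytest.approx(1.7 * value)
            else:
                assert scaled[name] == value

    @pytest.mark.parametrize("factor", [0.0, -1.0, np.inf, np.nan])
    def test_invalid_factor_rejected(self, model, factor):
        with pytest.raises(ValueError):
            apply_nutrition(model.parameters, factor)

    def test_rhs_production_equivalence(self, model):
        """Scaling parameters equals passing the factor through the signal."""
        state = model.initial_state
        via_params = model.with_parameters(
            apply_nutrition(model.parameters, 1.4)).rhs_unchecked(
                state, yc.SignalState())
        via_signal = model.rhs_unchecked(
            state, yc.SignalState(nutrition_factor=1.4))
        np.testing.assert_allclose(via_params, via_signal, rtol=1e-12)


class TestPheromoneTerms:
    def test_zero_contribution_when_off(self, model, random_states):
        for state in random_states[:5]:
            delta = pheromone_terms(model, state, pheromone_on=False)
            assert np.abs(delta).max() == 0.0

    def test_on_contribution_zero_without_far1_pathway_species(self, model):
        # with Far1 and Far1_p absent, only the transcription induction and
        # Far1 phosphorylation terms could act; both need Far1 mass except
        # the zeroth-order induction
        state = np.zeros(model.n_species)
        delta = pheromone_terms(model, state, pheromone_on=True)
        names = model.inventory.names
        nonzero = {names[i] for i in np.nonzero(delta)[0]}
        assert nonzero == {"Far1"}  # pure transcriptional induction

    def test_far1_induction_and_stabilization_signs(self, model):
        names = model.inventory.names
        state = model.initial_state.copy()
        state[names.index("Far1")] = 100.0
        delta = pheromone_terms(model, state, pheromone_on=True)
        assert delta[names.index("Far1_p")] > 0    # stabilising phosphorylation
        # induction minus conversion on Far1 itself; its phosphoform gains

    def test_cln_degradation_active_regardless_of_signal(self, model):
        # Cln2-dependent Far1 turnover is not pheromone-gated: with the
        # signal off the Far1 derivative still reflects Cln2-driven loss
        names = model.inventory.names
        state = np.zeros(model.n_species)
        state[names.index("Far1")] = 500.0
        state[names.index("Cln2")] = 1000.0
        deriv = yc.rhs(model, state)
        basal = model.parameters["ks_far1"] - (
            model.parameters["kd_far1"]
            + model.parameters["kd_far1_cln2"] * 1000.0) * 500.0
        assert deriv[names.index("Far1")] == pytest.approx(basal, rel=1e-9)


class TestHog1Terms:
    def test_zero_contribution_when_off(self, model, random_states):
        for state in random_states[:5]:
            delta = hog1_terms(model, state, osmostress_on=False)
            assert np.abs(delta).max() == 0.0

    def test_stress_effects_signs(self, model):
        names = model.inventory.names
        state = model.initial_state.copy()
        state[names.index("Sic1")] = 500.0
        state[names.index("SBF")] = 300.0
        state[names.index("MBF_a")] = 250.0
        state[names.index("Swe1")] = 400.0
        state[names.index("Clb2")] = 1000.0
        delta = hog1_terms(model, state, osmostress_on=True)
        assert delta[names.index("Sic1_Hp")] > 0      # Thr173 stabilisation
        assert delta[names.index("Cln2")] < 0         # expression downregulated
        assert delta[names.index("Clb5")] < 0
        assert delta[names.index("Swe1")] > 0         # phosphorylation blocked
        assert delta[names.index("Swe1_p")] < 0

    def test_sic1_hp_exempt_from_cdk_degradation(self, model):
        names = model.inventory.names
        state = np.zeros(model.n_species)
        state[names.index("Sic1_Hp")] = 300.0
        state[names.index("Cln2")] = 2000.0
        deriv = yc.rhs(model, state)
        # only basal turnover and slow dephosphorylation act on Sic1_Hp
        expected = -(model.parameters["kd_sic1"]
                     + model.parameters["kdp_sic1_hp"]) * 300.0
        assert deriv[names.index("Sic1_Hp")] == pytest.approx(expected, rel=1e-9)
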