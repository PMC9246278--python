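"""Structure and right-hand-side contracts of the core ODE model."""

import numpy as np
import pytest

import yeastcycle as yc
from yeastcycle.model_core import (
    ModelDefinitionError,
    ParameterSet,
    SignalState,
    conserved_totals,
    derived_observables,
    rhs,
)

SIC1_TOTAL_MEMBERS = ("Sic1", "Sic1_p", "Sic1_Hp", "Clb5_Sic1",
                      "Clb5_Sic1_Hp", "Clb3_Sic1", "Clb2_Sic1")


class TestStructure:
    def test_state_and_parameter_counts(self, model):
        assert model.n_species == 33
        assert model.n_parameters == 111

    def test_species_names_unique_and_complexes_resolved(self, model):
        names = model.inventory.names
        assert len(set(names)) == len(names)
        for entry in model.inventory.entries:
            for part in entry.constituents:
                assert part in names

    def test_sic1_total_member_species_present(self, model):
        for name in SIC1_TOTAL_MEMBERS:
            assert name in model.inventory.names

    def test_production_subset_strict_nonempty(self, model):
        subset = model.parameters.production_subset
        assert subset
        assert subset < set(model.parameters.values)

    def test_required_pools_exist(self, model):
        pools = model.conservation_pools
        assert set(pools["SBF"]) >= {"SBF", "SBF_Whi5"}
        assert set(pools["Cdc14"]) == {"Cdc14", "Cdc14_p"}

    @pytest.mark.parametrize("kinase, target", [
        ("Cln3", "Whi5"),          # Cln3 phosphorylates Whi5
        ("Cln2", "Whi5"),          # Cln1/2 feedback on Whi5
        ("Cln2", "Sic1"),          # Cln2-mediated Sic1 phosphorylation
        ("Clb5", "Sic1"),          # Clb5-mediated Sic1 phosphorylation
        ("Clb2", "SBF"),           # Clb2 inactivates SBF
        ("Clb2", "Net1"),          # Clb2 phosphorylates Net1
        ("Swe1", "Clb2"),          # Swe1 inhibits Clb2
        ("Clb2", "Swe1"),          # Clb2 phosphorylates Swe1
    ])
    def test_kinase_couplings_present(self, model, kinase, target):
        """Each named regulatory interaction appears in some rate law."""
        assert any(kinase in r.rate and target in r.stoichiometry
                   for r in model.rate_laws)

    @pytest.mark.parametrize("factor, product", [
        ("SBF", "Cln2"),           # SBF drives CLN1/2 expression
        ("MBF_a", "Clb5"),         # MBF drives CLB5/6 expression
        ("Clb5", "Clb3"),          # Clb5 -> Clb3 cascade step
        ("Mcm1_a", "Clb2"),        # Mcm1 drives CLB1/2 expression
        ("Swi5_a", "Sic1"),        # Swi5 drives SIC1 expression
    ])
    def test_expression_couplings_present(self, model, factor, product):
        assert any(factor in r.rate and r.stoichiometry.get(product) == 1
                   for r in model.rate_laws)

    def test_feedback_and_exit_couplings_present(self, model):
        rates = " | ".join(r.rate for r in model.rate_laws)
        named = {r.name: r for r in model.rate_laws}
        # Cln2 activates MBF; Clb2 feeds back on Mcm1; Mcm1 activates APC
        assert "Cln2" in named["act_mbf"].rate
        assert "Clb2" in named["act_mcm1"].rate
        assert "Mcm1_a" in named["act_apc"].rate
        # Cdc14 self-activation and APC->Cdc14
        assert "Cdc14_p" in named["act_cdc14"].rate
        assert "APC_a" in named["act_cdc14"].rate
        # APC-mediated Clb degradation
        for cyclin in ("clb5", "clb3", "clb2"):
            assert f"kd_{cyclin}_apc" in rates
        # Far1 hooks: Fus3 induction/stabilisation, Cln binding
        assert "FUS3" in named["syn_far1"].rate
        assert "FUS3" in named["pho_far1"].rate
        assert named["bind_cln2_far1"].stoichiometry["Cln2_Far1_p"] == 1
        assert named["bind_cln3_far1"].stoichiometry["Cln3_Far1_p"] == 1
        # Hog1 hooks
        assert "HOG1" in named["syn_cln2"].rate
        assert "HOG1" in named["syn_clb5"].rate
        assert "HOG1" in named["hog_pho_sic1"].rate
        assert "HOG1" in named["pho_swe1"].rate

    def test_pools_conserved_by_stoichiometry(self, model):
        for pool, members in model.conservation_pools.items():
            for reaction in model.rate_laws:
                net = sum(reaction.stoichiometry.get(m, 0) for m in members)
                assert net == 0, (pool, reaction.name)

    def test_parameter_set_validation(self):
        with pytest.raises(ModelDefinitionError):
            ParameterSet({"a": 1.0}, frozenset({"a"}))  # not strict subset
        with pytest.raises(ModelDefinitionError):
            ParameterSet({"a": -1.0, "b": 1.0}, frozenset({"b"}))

    def test_unknown_species_in_rate_law_rejected(self, model):
        from dataclasses import replace
        from yeastcycle.model_core import ModelDefinition, Reaction
        bad = model.rate_laws + (Reaction("bogus", {"NotASpecies": 1}, "1.0"),)
        with pytest.raises(ModelDefinitionError, match="NotASpecies"):
            ModelDefinition(model.inventory, model.parameters, bad,
                            model.conservation_pools, model.initial_state)


class TestRHS:
    def test_pool_derivatives_vanish_at_random_states(self, model, random_states):
        names = model.inventory.names
        for state in random_states[:20]:
            deriv = rhs(model, state)
            scale = np.abs(deriv).max() + 1.0
            for pool, members in model.conservation_pools.items():
                total = sum(deriv[names.index(m)] for m in members)
                assert abs(total) < 1e-10 * scale, pool

    def test_zero_state_only_constant_production(self, model):
        deriv = rhs(model, np.zeros(model.n_species))
        names = model.inventory.names
        nonzero = {names[i] for i in np.nonzero(deriv)[0]}
        # species with zeroth-order inflow at the empty state: constitutive
        # synthesis plus the basal activation of the complement pools
        assert nonzero == {"Cln3", "Sic1", "Swe1", "Far1", "Mcm1_a", "APC_a"}
        for entry in model.inventory.entries:
            if entry.constituents:
                assert deriv[names.index(entry.name)] == 0.0

    def test_production_scales_with_nutrition_factor(self, model):
        state = model.initial_state
        base = rhs(model, state, SignalState())
        doubled = rhs(model, state, SignalState(nutrition_factor=2.0))
        # the difference is exactly the production fluxes once more
        names = model.inventory.names
        extra = doubled - base
        # Cln3 production is purely constitutive
        i = names.index("Cln3")
        ks = model.parameters["ks_cln3"]
        assert np.isclose(extra[i], ks)

    def test_finite_difference_consistency(self, model):
        """RHS matches the numerical slope of an integrated trajectory.

        A fine output grid keeps the central-difference truncation error well
        below the comparison tolerance of 1e-4 relative to the flux scale.
        """
        tr = yc.integrate(model, t_end=30.0, output_step=0.01,
                          settings=yc.IntegratorSettings(rtol=1e-10,
                                                         atol=1e-12))
        idx = np.linspace(5, tr.times.size - 5, 50).astype(int)
        h = tr.times[1] - tr.times[0]
        for i in idx:
            slope = (tr.states[i + 1] - tr.states[i - 1]) / (2 * h)
            deriv = rhs(model, np.maximum(tr.states[i], 0.0))
            scale = np.abs(deriv).max()
            assert np.abs(slope - deriv).max() < 1e-4 * scale

    def test_rejects_negative_state(self, model):
        state = model.initial_state.copy()
        state[0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            rhs(model, state)

    def test_rejects_nonfinite_state(self, model):
        state = model.initial_state.copy()
        state[3] = np.nan
        with pytest.raises(ValueError):
            rhs(model, state)


class TestConservedTotals:
    def test_initial_state_totals_match_direct_sums(self, model):
        totals = conserved_totals(model, model.initial_state)
        names = model.inventory.names
        for pool, members in model.conservation_pools.items():
            expected = sum(model.initial_state[names.index(m)] for m in members)
            assert totals[pool] == pytest.approx(expected)

    def test_doubling_pool_members_doubles_total(self, model):
        names = model.inventory.names
        state = model.initial_state.copy()
        before = conserved_totals(model, state)["Cdc14"]
        for m in model.conservation_pools["Cdc14"]:
            state[names.index(m)] *= 2.0
        assert conserved_totals(model, state)["Cdc14"] == pytest.approx(2 * before)

    def test_totals_constant_along_trajectory(self, model, tight_trajectory):
        tr = tight_trajectory
        t0 = conserved_totals(model, tr.states[0])
        for pool, total0 in t0.items():
            totals = np.array([conserved_totals(model, s)[pool]
                               for s in tr.states[::50]])
            assert np.abs(totals - total0).max() / total0 < 1e-6, pool

    def test_unknown_pool_raises(self, model):
        with pytest.raises(KeyError):
            conserved_totals(model, model.initial_state, pools=["NotAPool"])


class TestDerivedObservables:
    def test_sic1_total_sum_definition(self, model):
        names = model.inventory.names
        state = np.zeros(model.n_species)
        state[names.index("Sic1")] = 10.0
        state[names.index("Sic1_p")] = 5.0
        obs = derived_observables(model, state)
        assert obs["Sic1_total"] == pytest.approx(15.0)

    def test_zero_state_all_observables_zero(self, model):
        obs = derived_observables(model, np.zeros(model.n_species))
        assert all(v == 0.0 for v in obs.values())

    def test_totals_dominate_constituents(self, model, random_states):
        names = model.inventory.names
        state = random_states[0]
        obs = derived_observables(model, state)
        assert obs["Clb5_total"] >= state[names.index("Clb5")]
        assert obs["Clb2_total"] >= state[names.index("Clb2")]
        assert obs["Whi5_nuclear"] >= state[names.index("Whi5")]

    def test_trajectory_observables_equal_columnwise_sums(self, model,
                                                          reference_trajectory):
        tr = reference_trajectory
        manual = np.zeros(tr.times.size)
        for member in SIC1_TOTAL_MEMBERS:
            manual += tr.states[:, model.inventory.index(member)]
        np.testing.assert_allclose(tr.column("Sic1_total"), manual, rtol=1e-12)
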