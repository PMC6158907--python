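"""Session semantics: bound overrides, knockouts, objectives, resets."""

import pytest

from fluxlens import SessionState
from fluxlens.fixtures import enumerate_vertex_optimum, make_branch, make_chain
from fluxlens.lp_core import OPTIMAL, ObjectiveSpec, build_stoichiometric_matrix
from fluxlens.model_io import MetabolicModel, Metabolite, Reaction


class TestBounds:
    def test_fixed_bounds_pin_the_flux(self, chain3_state):
        state = chain3_state.set_bounds("CONV_1", 4.0, 4.0)
        solution = state.evaluate()
        assert solution.flux("CONV_1") == pytest.approx(4.0, abs=1e-9)
        assert solution.objective_value == pytest.approx(4.0, abs=1e-9)

    def test_other_reactions_unchanged(self, chain3_state):
        state = chain3_state.set_bounds("CONV_1", 0.0, 5.0)
        assert state.effective_bounds("CONV_2") == chain3_state.effective_bounds("CONV_2")

    def test_unknown_reaction_raises(self, chain3_state):
        with pytest.raises(KeyError, match="nonexistent"):
            chain3_state.set_bounds("nonexistent", 0.0, 1.0)

    def test_inverted_bounds_rejected(self, chain3_state):
        with pytest.raises(ValueError, match="exceeds"):
            chain3_state.set_bounds("CONV_1", 5.0, 1.0)

    def test_original_state_untouched(self, chain3_state):
        chain3_state.set_bounds("CONV_1", 0.0, 0.0)
        assert chain3_state.bound_overrides == {}


class TestKnockout:
    @pytest.mark.parametrize("reaction", ["EX_A0", "CONV_1", "CONV_2", "SINK"])
    def test_knockout_equals_zero_bounds(self, chain3_state, reaction):
        by_ko = chain3_state.knockout(reaction).evaluate()
        by_bounds = chain3_state.set_bounds(reaction, 0.0, 0.0).evaluate()
        assert by_ko.status == by_bounds.status
        assert by_ko.objective_value == pytest.approx(by_bounds.objective_value, abs=1e-9)

    def test_interior_knockout_kills_the_single_pathway(self, chain3_state):
        solution = chain3_state.knockout("CONV_2").evaluate()
        assert solution.status == OPTIMAL
        assert solution.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_knockout_dominates_bound_override(self, chain3_state):
        state = chain3_state.knockout("CONV_1").set_bounds("CONV_1", 1.0, 5.0)
        assert state.effective_bounds("CONV_1") == (0.0, 0.0)

    def test_unknown_reaction_raises(self, chain3_state):
        with pytest.raises(KeyError):
            chain3_state.knockout("nonexistent")


class TestReset:
    def test_knockout_then_reset_restores_base(self, chain3_state):
        base = chain3_state.evaluate()
        restored = chain3_state.knockout("CONV_1").reset_reaction("CONV_1").evaluate()
        assert restored.status == base.status
        assert restored.objective_value == pytest.approx(base.objective_value, abs=1e-12)

    def test_reset_of_untouched_reaction_is_noop(self, chain3_state):
        assert chain3_state.reset_reaction("CONV_1") == chain3_state

    def test_reset_all_clears_everything(self, chain3_state):
        perturbed = (
            chain3_state.set_bounds("EX_A0", -2.0, 0.0)
            .knockout("CONV_2")
            .set_objective("CONV_1", "minimize")
        )
        restored = perturbed.reset_all()
        base = chain3_state.evaluate()
        again = restored.evaluate()
        assert (again.status, again.objective_value) == (base.status, base.objective_value)
        assert restored.objective == chain3_state.objective

    def test_reset_all_is_idempotent(self, chain3_state):
        once = chain3_state.knockout("SINK").reset_all()
        assert once.reset_all() == once

    def test_reset_all_restores_base_objective_after_retarget(self, chain3_state):
        state = chain3_state.set_objective("CONV_1", "maximize").reset_all()
        assert state.objective.reaction_ids == ("SINK",)


class TestObjective:
    def test_single_mode_always_one_entry(self, chain3_state):
        state = chain3_state
        for rid, direction in [("CONV_1", "maximize"), ("CONV_2", "minimize"),
                               ("SINK", "maximize")]:
            state = state.set_objective(rid, direction)
            assert len(state.objective.entries) == 1
        assert state.objective.entries == (("SINK", 1.0),)

    def test_minimize_uses_negative_unit_coefficient(self, chain3_state):
        state = chain3_state.set_objective("CONV_1", "minimize")
        assert state.objective.entries == (("CONV_1", -1.0),)

    def test_invalid_direction_rejected(self, chain3_state):
        with pytest.raises(ValueError, match="direction"):
            chain3_state.set_objective("CONV_1", "sideways")

    def test_compound_mode_accumulates(self, chain3_state):
        state = (
            chain3_state.set_compound_mode(True)
            .set_objective("SINK", "maximize")
            .set_objective("CONV_1", "minimize")
        )
        assert dict(state.objective.entries) == {"SINK": 1.0, "CONV_1": -1.0}

    def test_compound_retarget_replaces_not_duplicates(self, chain3_state):
        state = (
            chain3_state.set_compound_mode(True)
            .set_objective("CONV_1", "maximize")
            .set_objective("CONV_1", "minimize")
        )
        assert state.objective.entries.count(("CONV_1", -1.0)) == 1
        assert len([e for e in state.objective.entries if e[0] == "CONV_1"]) == 1

    def test_leaving_compound_collapses_to_most_recent(self, chain3_state):
        state = (
            chain3_state.set_compound_mode(True)
            .set_objective("SINK", "maximize")
            .set_objective("CONV_1", "minimize")
            .set_compound_mode(False)
        )
        assert state.objective.entries == (("CONV_1", -1.0),)
        assert not state.compound_mode

    def test_compound_objective_matches_vertex_oracle(self):
        # maximize the favoured sink while minimizing the alternative branch
        model = make_branch(10.0)
        state = (
            SessionState.from_model(model)
            .set_compound_mode(True)
            .set_objective("SINK_B", "maximize")
            .set_objective("SINK_C", "minimize")
        )
        solution = state.evaluate()
        oracle = enumerate_vertex_optimum(
            build_stoichiometric_matrix(model),
            [(r.lower_bound, r.upper_bound) for r in model.reactions],
            state.objective,
        )
        assert solution.objective_value == pytest.approx(oracle, abs=1e-6)
        assert solution.objective_value == pytest.approx(10.0, abs=1e-6)


class TestEvaluate:
    def test_referentially_transparent(self, chain3_state):
        state = chain3_state.set_bounds("EX_A0", -7.0, 0.0)
        first = state.evaluate()
        second = state.evaluate()
        assert first.status == second.status
        assert first.objective_value == second.objective_value
        assert first.fluxes == second.fluxes

    def test_empty_objective_is_a_configuration_error(self):
        model = make_chain(2, 10.0)
        objective_less = MetabolicModel(
            id=model.id,
            metabolites=model.metabolites,
            reactions=tuple(
                Reaction(**{**r.__dict__, "objective_coefficient": 0.0})
                for r in model.reactions
            ),
        )
        state = SessionState.from_model(objective_less)
        with pytest.raises(ValueError, match="objective"):
            state.evaluate()

    def test_all_exchanges_knocked_out_gives_zero_flux_optimum(self, chain3_state):
        state = chain3_state.knockout("EX_A0")
        solution = state.evaluate()
        assert solution.status == OPTIMAL
        assert solution.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_forced_flux_without_supply_is_infeasible(self):
        model = make_chain(2, 10.0)
        state = SessionState.from_model(model)
        # an ATPM-like forced drain: sink must run, but supply is cut
        state = state.set_bounds("SINK", 1.0, 1000.0).knockout("EX_A0")
        assert state.evaluate().status == "infeasible"
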