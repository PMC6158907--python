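"""Stoichiometric matrix construction and LP solving.

The simplex backend is cross-checked two independent ways: against the
brute-force vertex-enumeration oracle on small random networks, and against
COBRApy's own FBA on the E. coli core model.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxlens.fixtures import enumerate_vertex_optimum, make_chain, make_random_feasible
from fluxlens.lp_core import (
    INFEASIBLE,
    OPTIMAL,
    UNBOUNDED,
    ObjectiveSpec,
    build_stoichiometric_matrix,
    solve_lp,
)
from fluxlens.model_io import MetabolicModel, Metabolite, Reaction


def _bounds(model):
    return [(r.lower_bound, r.upper_bound) for r in model.reactions]


def _objective(model):
    return ObjectiveSpec(
        tuple(
            (r.id, 1.0 if r.objective_coefficient > 0 else -1.0)
            for r in model.objective_reactions()
        )
    )


class TestMatrix:
    def test_conversion_column_signs(self):
        model = make_chain(2, 10.0)  # EX_A0, CONV_1 (A0->A1), SINK
        matrix = build_stoichiometric_matrix(model)
        assert matrix.coefficient("A0_c", "CONV_1") == -1.0
        assert matrix.coefficient("A1_c", "CONV_1") == 1.0

    def test_exchange_column_single_entry(self):
        matrix = build_stoichiometric_matrix(make_chain(2, 10.0))
        column = matrix.matrix[:, matrix.column_index("EX_A0")].toarray().ravel()
        assert np.count_nonzero(column) == 1

    def test_chain2_matches_hand_written_matrix(self):
        matrix = build_stoichiometric_matrix(make_chain(2, 10.0))
        expected = np.array([[-1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        assert matrix.dense() == pytest.approx(expected)
        assert matrix.column_ids == ("EX_A0", "CONV_1", "SINK")

    def test_untouched_pairs_are_zero(self):
        matrix = build_stoichiometric_matrix(make_chain(4, 10.0))
        assert matrix.coefficient("A0_c", "SINK") == 0.0


class TestSolve:
    def test_bound_limited_chain(self):
        model = make_chain(2, 10.0)
        solution = solve_lp(build_stoichiometric_matrix(model), _bounds(model), _objective(model))
        assert solution.status == OPTIMAL
        assert solution.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_unknown_objective_reaction_raises(self):
        model = make_chain(2, 10.0)
        with pytest.raises(KeyError, match="NOPE"):
            solve_lp(
                build_stoichiometric_matrix(model),
                _bounds(model),
                ObjectiveSpec.maximize("NOPE"),
            )

    def test_empty_objective_raises(self):
        model = make_chain(2, 10.0)
        with pytest.raises(ValueError, match="objective"):
            solve_lp(build_stoichiometric_matrix(model), _bounds(model), ObjectiveSpec())

    def test_bounds_length_mismatch_raises(self):
        model = make_chain(2, 10.0)
        with pytest.raises(ValueError, match="bound"):
            solve_lp(build_stoichiometric_matrix(model), [(0, 1)], _objective(model))

    def test_infeasible_status(self):
        model = make_chain(2, 10.0)
        bounds = _bounds(model)
        bounds[-1] = (20.0, 30.0)  # sink forced beyond achievable supply
        solution = solve_lp(build_stoichiometric_matrix(model), bounds, _objective(model))
        assert solution.status == INFEASIBLE
        assert solution.objective_value is None
        assert solution.fluxes is None

    def test_unbounded_status(self):
        model = MetabolicModel(
            id="unbounded",
            metabolites=(Metabolite(id="A_c"),),
            reactions=(
                Reaction(id="IN", stoichiometry={"A_c": 1.0}, lower_bound=0,
                         upper_bound=float("inf")),
                Reaction(id="OUT", stoichiometry={"A_c": -1.0}, lower_bound=0,
                         upper_bound=float("inf"), objective_coefficient=1.0),
            ),
        )
        solution = solve_lp(
            build_stoichiometric_matrix(model), _bounds(model), _objective(model)
        )
        assert solution.status == UNBOUNDED

    def test_objective_coefficients_restricted_to_unit(self):
        with pytest.raises(ValueError, match=r"\+1 or -1"):
            ObjectiveSpec((("R1", 2.0),))


class TestInvariantsAndOracle:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n=st.integers(3, 6), seed=st.integers(0, 5_000))
    def test_optimal_vectors_satisfy_steady_state_and_bounds(self, n, seed):
        model = make_random_feasible(n, seed)
        matrix = build_stoichiometric_matrix(model)
        solution = solve_lp(matrix, _bounds(model), _objective(model))
        assert solution.status == OPTIMAL
        v = np.array([solution.fluxes[rid] for rid in matrix.column_ids])
        assert np.abs(matrix.dense() @ v).max() <= 1e-6
        for (lb, ub), flux in zip(_bounds(model), v):
            assert lb - 1e-6 <= flux <= ub + 1e-6

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(3, 6), seed=st.integers(0, 5_000))
    def test_maximize_negated_equals_negated_minimum(self, n, seed):
        model = make_random_feasible(n, seed)
        matrix = build_stoichiometric_matrix(model)
        objective = _objective(model)
        forward = solve_lp(matrix, _bounds(model), objective)
        backward = solve_lp(matrix, _bounds(model), objective.negated())
        # max(c) >= -max(-c) always; equality iff the flux is pinned, so only
        # the ordering is asserted here plus consistency on a pinned fixture.
        assert forward.objective_value >= -backward.objective_value - 1e-9

    def test_max_equals_negated_min_on_pinned_flux(self):
        model = make_chain(3, 10.0)
        matrix = build_stoichiometric_matrix(model)
        bounds = _bounds(model)
        bounds[0] = (-10.0, -10.0)  # pin the exchange: every flux unique
        hi = solve_lp(matrix, bounds, ObjectiveSpec.maximize("CONV_1"))
        lo = solve_lp(matrix, bounds, ObjectiveSpec.minimize("CONV_1"))
        # minimize reports max(-v), so min v = -objective_value
        assert hi.objective_value == pytest.approx(-lo.objective_value, abs=1e-9)
        assert hi.objective_value == pytest.approx(10.0, abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(3, 6), seed=st.integers(0, 5_000),
           which=st.integers(0, 5), widen=st.floats(0.1, 5.0))
    def test_widening_bounds_never_decreases_optimum(self, n, seed, which, widen):
        model = make_random_feasible(n, seed)
        matrix = build_stoichiometric_matrix(model)
        bounds = _bounds(model)
        before = solve_lp(matrix, bounds, _objective(model)).objective_value
        j = which % n
        lb, ub = bounds[j]
        bounds[j] = (lb - widen, ub + widen)
        after = solve_lp(matrix, bounds, _objective(model)).objective_value
        assert after >= before - 1e-8

    @pytest.mark.parametrize("seed", range(1, 21))
    @pytest.mark.parametrize("n", [3, 5, 6])
    def test_agrees_with_vertex_enumeration_oracle(self, n, seed):
        model = make_random_feasible(n, seed)
        matrix = build_stoichiometric_matrix(model)
        solution = solve_lp(matrix, _bounds(model), _objective(model))
        oracle = enumerate_vertex_optimum(matrix, _bounds(model), _objective(model))
        assert solution.status == OPTIMAL and oracle is not None
        assert solution.objective_value == pytest.approx(oracle, abs=1e-6)


class TestAgainstReferenceImplementation:
    def test_core_model_biomass_optimum(self, core_model):
        solution = solve_lp(
            build_stoichiometric_matrix(core_model),
            [(r.lower_bound, r.upper_bound) for r in core_model.reactions],
            _objective(core_model),
        )
        assert solution.status == OPTIMAL
        assert round(solution.objective_value, 3) == 0.874

    def test_matches_cobrapy_on_core_model(self, core_json):
        cobra = pytest.importorskip("cobra")
        import cobra.io

        reference = cobra.io.from_json(core_json)
        model = __import__("fluxlens").parse_cobra_json(core_json)
        solution = solve_lp(
            build_stoichiometric_matrix(model),
            [(r.lower_bound, r.upper_bound) for r in model.reactions],
            _objective(model),
        )
        assert solution.objective_value == pytest.approx(
            reference.optimize().objective_value, abs=1e-6
        )
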