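"""Steady-state LP construction and solving for flux balance analysis.

FBA solves::

    maximize    c' v
    subject to  S v = 0
                lb <= v <= ub

where ``S`` is the stoichiometric matrix (metabolites x reactions), ``v`` the
flux vector in mmol/gDW/hr, and ``c`` an objective with coefficients
restricted to +1/-1 (maximize / minimize a reaction's flux; compound
objectives sum several such terms).

The default backend is SciPy's HiGHS dual simplex.  A simplex-type method is
deliberate: returned solutions are vertices of the flux polytope.  Note that
FBA optima are routinely non-unique — only the status and objective value are
well-defined; the flux vector is *one* optimal vertex among possibly many.
Backends are pluggable via :func:`register_backend`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = [
    "StoichiometricMatrix",
    "ObjectiveSpec",
    "FluxSolution",
    "SolverError",
    "build_stoichiometric_matrix",
    "solve_lp",
    "register_backend",
    "OPTIMAL",
    "INFEASIBLE",
    "UNBOUNDED",
]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

#: solver-level primal/dual feasibility tolerance
SOLVER_TOLERANCE = 1e-9
#: tolerance used when asserting feasibility of returned vectors
ASSERT_TOLERANCE = 1e-6


class SolverError(RuntimeError):
    """The backend failed for a reason other than infeasibility/unboundedness."""


@dataclass(frozen=True)
class StoichiometricMatrix:
    """Sparse stoichiometric matrix with row/column identifier bookkeeping.

    Rows are metabolites, columns are reactions; column order matches the
    model's reaction order exactly.
    """

    matrix: sp.csc_matrix
    row_ids: tuple[str, ...]
    column_ids: tuple[str, ...]

    @property
    def n_metabolites(self) -> int:
        return len(self.row_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.column_ids)

    def column_index(self, reaction_id: str) -> int:
        lookup = self.__dict__.get("_col_lookup")
        if lookup is None:
            lookup = {rid: j for j, rid in enumerate(self.column_ids)}
            object.__setattr__(self, "_col_lookup", lookup)
        try:
            return lookup[reaction_id]
        except KeyError:
            raise KeyError(f"no reaction {reaction_id!r} in matrix columns") from None

    def coefficient(self, metabolite_id: str, reaction_id: str) -> float:
        i = self.row_ids.index(metabolite_id)
        j = self.column_index(reaction_id)
        return float(self.matrix[i, j])

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass(frozen=True)
class ObjectiveSpec:
    """Linear objective with coefficients restricted to +1 or -1.

    The sense is always maximization; minimizing a reaction's flux is
    expressed with a -1 coefficient.  The restriction to unit coefficients is
    enforced at construction so arbitrary weights are unrepresentable.
    """

    entries: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        for rid, coef in self.entries:
            if coef not in (1.0, -1.0, 1, -1):
                raise ValueError(
                    f"objective coefficient for {rid!r} must be +1 or -1, got {coef}"
                )

    @classmethod
    def maximize(cls, reaction_id: str) -> "ObjectiveSpec":
        return cls(((reaction_id, 1.0),))

    @classmethod
    def minimize(cls, reaction_id: str) -> "ObjectiveSpec":
        return cls(((reaction_id, -1.0),))

    def negated(self) -> "ObjectiveSpec":
        return ObjectiveSpec(tuple((rid, -c) for rid, c in self.entries))

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.entries)

    def __bool__(self) -> bool:
        return bool(self.entries)


@dataclass(frozen=True)
class FluxSolution:
    """Outcome of one LP solve.

    ``objective_value`` and ``fluxes`` are only defined when ``status`` is
    ``"optimal"``; infeasible and unbounded solutions carry neither.
    """

    status: str
    objective_value: float | None = None
    fluxes: Mapping[str, float] | None = None

    @property
    def is_optimal(self) -> bool:
        return self.status == OPTIMAL

    def flux(self, reaction_id: str) -> float:
        if self.fluxes is None:
            raise ValueError(f"solution with status {self.status!r} carries no fluxes")
        return self.fluxes[reaction_id]


def build_stoichiometric_matrix(model) -> StoichiometricMatrix:
    """Assemble S from a model: entry (i, j) is the coefficient of
    metabolite i in reaction j; pairs not mentioned are zero."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(coef)
    matrix = sp.csc_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return StoichiometricMatrix(
        matrix=matrix,
        row_ids=tuple(m.id for m in model.metabolites),
        column_ids=tuple(r.id for r in model.reactions),
    )


# ---------------------------------------------------------------------------
# backends

Backend = Callable[
    [sp.csc_matrix, Sequence[tuple[float, float]], np.ndarray], tuple[str, np.ndarray | None]
]

_BACKENDS: dict[str, Backend] = {}
DEFAULT_BACKEND = "scipy-highs-ds"


def register_backend(name: str, backend: Backend) -> None:
    """Register an LP backend.

    A backend receives ``(S, bounds, c)`` for ``maximize c'v s.t. S v = 0``
    and returns ``(status, v)`` with status in {optimal, infeasible,
    unbounded} and ``v`` an optimal vertex when optimal, else None.
    """
    _BACKENDS[name] = backend


def _scipy_highs_backend(
    matrix: sp.csc_matrix,
    bounds: Sequence[tuple[float, float]],
    c: np.ndarray,
) -> tuple[str, np.ndarray | None]:
    result = linprog(
        -c,  # linprog minimizes
        A_eq=matrix,
        b_eq=np.zeros(matrix.shape[0]),
        bounds=list(bounds),
        method="highs-ds",
        options={
            "primal_feasibility_tolerance": SOLVER_TOLERANCE,
            "dual_feasibility_tolerance": SOLVER_TOLERANCE,
        },
    )
    if result.status == 0:
        return OPTIMAL, np.asarray(result.x)
    if result.status == 2:
        return INFEASIBLE, None
    if result.status == 3:
        return UNBOUNDED, None
    raise SolverError(f"LP solve failed (status {result.status}): {result.message}")


register_backend(DEFAULT_BACKEND, _scipy_highs_backend)


def solve_lp(
    matrix: StoichiometricMatrix,
    bounds: Sequence[tuple[float, float]] | Mapping[str, tuple[float, float]],
    objective: ObjectiveSpec,
    *,
    backend: str = DEFAULT_BACKEND,
) -> FluxSolution:
    """Maximize the objective over the steady-state flux polytope.

    Parameters
    ----------
    matrix:
        Stoichiometric matrix from :func:`build_stoichiometric_matrix`.
    bounds:
        One (lb, ub) pair per reaction, as a sequence in column order or a
        mapping keyed by reaction id.
    objective:
        Unit-coefficient objective; entries must name matrix columns.

    Returns
    -------
    FluxSolution
        Status ``optimal`` with objective value and one optimal flux vector,
        or ``infeasible`` / ``unbounded`` with neither.  Alternate optima are
        permitted: only status and objective value are contractual.

    Raises
    ------
    KeyError
        If the objective references a reaction absent from the matrix.
    SolverError
        On numerical failure or iteration limits in the backend.
    """
    if not objective.entries:
        raise ValueError("objective must have at least one entry at solve time")
    if isinstance(bounds, Mapping):
        bound_list = [bounds[rid] for rid in matrix.column_ids]
    else:
        bound_list = list(bounds)
        if len(bound_list) != matrix.n_reactions:
            raise ValueError(
                f"expected {matrix.n_reactions} bound pairs, got {len(bound_list)}"
            )
    c = np.zeros(matrix.n_reactions)
    for rid, coef in objective.entries:
        c[matrix.column_index(rid)] = coef

    status, x = _BACKENDS[backend](matrix.matrix, bound_list, c)
    if status != OPTIMAL:
        return FluxSolution(status=status)
    assert x is not None
    return FluxSolution(
        status=OPTIMAL,
        objective_value=float(c @ x),
        fluxes={rid: float(x[j]) for j, rid in enumerate(matrix.column_ids)},
    )
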