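"""Session-style perturbations on an immutable base model.

A :class:`SessionState` layers user edits — bound overrides, reaction
knockouts, and objective changes — over a base :class:`~fluxlens.model_io.
MetabolicModel` without ever mutating it.  Every operation returns a new
state, which makes per-reaction reset and global reset trivial: dropping the
overlay entry restores base behaviour exactly.

Semantics mirror an interactive FBA session:

* a knockout forces effective bounds (0, 0) and *dominates* any bound
  override on the same reaction until the reaction is reset;
* in single-objective mode, setting an objective replaces the previous one;
  in compound mode, entries accumulate (re-targeting a reaction replaces its
  coefficient);
* leaving compound mode collapses the objective to the most recently set
  entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

from .lp_core import (
    FluxSolution,
    ObjectiveSpec,
    StoichiometricMatrix,
    build_stoichiometric_matrix,
    solve_lp,
)
from .model_io import MetabolicModel

__all__ = ["SessionState", "Direction"]

Direction = Literal["maximize", "minimize"]


def _base_objective(model: MetabolicModel) -> ObjectiveSpec:
    """Objective from the model's nonzero objective coefficients, with
    coefficients collapsed to their sign (+1/-1)."""
    entries = tuple(
        (r.id, 1.0 if r.objective_coefficient > 0 else -1.0)
        for r in model.objective_reactions()
    )
    return ObjectiveSpec(entries)


@dataclass(frozen=True)
class SessionState:
    """Immutable overlay of perturbations on a base model.

    Construct with :meth:`from_model`; derive perturbed states with
    :meth:`set_bounds`, :meth:`knockout`, :meth:`set_objective`, etc., and
    solve with :meth:`evaluate`.  The stoichiometric matrix is built once per
    base model and shared across derived states.
    """

    base: MetabolicModel
    bound_overrides: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    knockouts: frozenset[str] = frozenset()
    objective: ObjectiveSpec = ObjectiveSpec()
    compound_mode: bool = False
    matrix: StoichiometricMatrix | None = None

    @classmethod
    def from_model(cls, model: MetabolicModel) -> "SessionState":
        """Pristine session: no edits, objective from the model itself."""
        return cls(
            base=model,
            objective=_base_objective(model),
            matrix=build_stoichiometric_matrix(model),
        )

    # -- internal helpers ---------------------------------------------------

    def _require_reaction(self, reaction_id: str) -> None:
        if not self.base.has_reaction(reaction_id):
            raise KeyError(f"no reaction {reaction_id!r} in model {self.base.id!r}")

    def _matrix(self) -> StoichiometricMatrix:
        if self.matrix is not None:
            return self.matrix
        return build_stoichiometric_matrix(self.base)

    # -- queries ------------------------------------------------------------

    def effective_bounds(self, reaction_id: str) -> tuple[float, float]:
        """Bounds actually used at solve time: knockout > override > base."""
        self._require_reaction(reaction_id)
        if reaction_id in self.knockouts:
            return (0.0, 0.0)
        if reaction_id in self.bound_overrides:
            return self.bound_overrides[reaction_id]
        rxn = self.base.reaction(reaction_id)
        return (rxn.lower_bound, rxn.upper_bound)

    def all_effective_bounds(self) -> list[tuple[float, float]]:
        """Effective (lb, ub) per reaction, in model column order."""
        out = []
        for rxn in self.base.reactions:
            if rxn.id in self.knockouts:
                out.append((0.0, 0.0))
            elif rxn.id in self.bound_overrides:
                out.append(self.bound_overrides[rxn.id])
            else:
                out.append((rxn.lower_bound, rxn.upper_bound))
        return out

    # -- perturbations ------------------------------------------------------

    def set_bounds(self, reaction_id: str, lower: float, upper: float) -> "SessionState":
        """Override one reaction's flux bounds (mmol/gDW/hr)."""
        self._require_reaction(reaction_id)
        if lower > upper:
            raise ValueError(
                f"lower bound {lower} exceeds upper bound {upper} for {reaction_id!r}"
            )
        overrides = dict(self.bound_overrides)
        overrides[reaction_id] = (float(lower), float(upper))
        return replace(self, bound_overrides=overrides)

    def knockout(self, reaction_id: str) -> "SessionState":
        """Knock a reaction out: effective bounds become (0, 0)."""
        self._require_reaction(reaction_id)
        return replace(self, knockouts=self.knockouts | {reaction_id})

    def reset_reaction(self, reaction_id: str) -> "SessionState":
        """Drop any override/knockout so the reaction reverts to base bounds."""
        self._require_reaction(reaction_id)
        overrides = {k: v for k, v in self.bound_overrides.items() if k != reaction_id}
        return replace(
            self,
            bound_overrides=overrides,
            knockouts=self.knockouts - {reaction_id},
        )

    def reset_all(self) -> "SessionState":
        """Clear every edit; objective reverts to the base model's own."""
        return replace(
            self,
            bound_overrides={},
            knockouts=frozenset(),
            objective=_base_objective(self.base),
            compound_mode=False,
        )

    def set_objective(self, reaction_id: str, direction: Direction) -> "SessionState":
        """Point the objective at a reaction.

        Single mode: the objective becomes exactly this one +/-1 entry.
        Compound mode: the entry is appended; re-targeting a reaction already
        present replaces its coefficient (and makes it the most recent).
        """
        self._require_reaction(reaction_id)
        if direction not in ("maximize", "minimize"):
            raise ValueError(f"direction must be 'maximize' or 'minimize', got {direction!r}")
        coef = 1.0 if direction == "maximize" else -1.0
        if not self.compound_mode:
            return replace(self, objective=ObjectiveSpec(((reaction_id, coef),)))
        entries = tuple(e for e in self.objective.entries if e[0] != reaction_id)
        return replace(self, objective=ObjectiveSpec(entries + ((reaction_id, coef),)))

    def set_compound_mode(self, enabled: bool) -> "SessionState":
        """Toggle compound objectives.

        Disabling collapses the objective to its most recently set entry, so
        the session lands back in a valid single-objective state.
        """
        if enabled == self.compound_mode:
            return self
        if enabled:
            return replace(self, compound_mode=True)
        entries = self.objective.entries[-1:] if self.objective.entries else ()
        return replace(self, compound_mode=False, objective=ObjectiveSpec(entries))

    # -- solving ------------------------------------------------------------

    def evaluate(self) -> FluxSolution:
        """Solve the FBA LP under the effective bounds and current objective.

        Pure: the state is unchanged and repeated calls return identical
        status and objective value.
        """
        if not self.objective.entries:
            raise ValueError("cannot evaluate a session with an empty objective")
        return solve_lp(self._matrix(), self.all_effective_bounds(), self.objective)
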