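"""Derived FBA procedures: flux variability, yields, carbon-source swaps,
and pathway-usage comparison at fixed production.

Each procedure is a pure composition of session operations: the caller's
:class:`~fluxlens.session.SessionState` is never mutated (states are
immutable values), and results agree by construction with performing the same
edits by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lp_core import FluxSolution, INFEASIBLE, OPTIMAL
from .session import SessionState

__all__ = [
    "FluxRange",
    "ProductionProbeResult",
    "flux_range",
    "flux_range_at_fraction",
    "max_yield",
    "swap_carbon_source",
    "min_flux_at_production_fraction",
]


@dataclass(frozen=True)
class FluxRange:
    """Feasible flux interval for one reaction under a fixed-anchor constraint.

    This is single-reaction flux variability analysis: with the anchor
    reaction (typically biomass) pinned to ``lb = ub = anchor_value``, the
    target flux is minimized and maximized.  A wide range signals alternate
    optima flowing through the target; a collapsed range means the flux is
    uniquely determined.
    """

    reaction: str
    minimum: float
    maximum: float
    constraint_description: str

    def __post_init__(self) -> None:
        if self.minimum > self.maximum + 1e-9:
            raise ValueError(
                f"flux range minimum {self.minimum} exceeds maximum {self.maximum}"
            )


@dataclass(frozen=True)
class ProductionProbeResult:
    """Outcome of minimizing a probe flux at near-maximal production.

    ``product_maximum`` is the unconstrained maximum of the product flux;
    ``probe_minimum`` the smallest probe flux compatible with holding
    production at ``fraction * product_maximum``.  When the network cannot
    produce the product at all (``producing`` is False) no minimization is
    attempted and ``probe_minimum`` is None.
    """

    product: str
    probe: str
    fraction: float
    product_maximum: float
    probe_minimum: float | None
    producing: bool


def flux_range(
    state: SessionState,
    target: str,
    anchor: str,
    anchor_value: float,
) -> FluxRange | FluxSolution:
    """Min/max flux of ``target`` with ``anchor`` fixed at ``anchor_value``.

    The anchor is pinned with ``lb = ub = anchor_value`` exactly (not the
    lower-bound-only convention some FVA implementations use), then the
    target flux is maximized and minimized.  Pure: the caller's state is
    untouched.

    Returns
    -------
    FluxRange
        When both solves are optimal.
    FluxSolution
        The status-bearing failure (infeasible/unbounded) when pinning the
        anchor at ``anchor_value`` leaves no feasible flux state.
    """
    anchored = state.set_bounds(anchor, anchor_value, anchor_value)
    hi = anchored.set_objective(target, "maximize").evaluate()
    if hi.status != OPTIMAL:
        return hi
    lo = anchored.set_objective(target, "minimize").evaluate()
    if lo.status != OPTIMAL:
        return lo
    # minimize reports max of -v, so the minimum is the negated objective
    return FluxRange(
        reaction=target,
        minimum=-lo.objective_value,
        maximum=hi.objective_value,
        constraint_description=f"{anchor} fixed at {anchor_value}",
    )


def flux_range_at_fraction(
    state: SessionState,
    target: str,
    anchor: str | None = None,
    fraction: float = 0.99,
) -> FluxRange | FluxSolution:
    """Convenience wrapper: anchor at ``fraction`` of the current optimum.

    With no explicit anchor the session's (single) objective reaction is
    used.  The anchor value is ``fraction`` times the current optimal
    objective value, mirroring the common near-optimal FVA convention.
    """
    if anchor is None:
        ids = state.objective.reaction_ids
        if len(ids) != 1:
            raise ValueError(
                "anchor can only be inferred from a single-entry objective; "
                f"got {len(ids)} entries"
            )
        anchor = ids[0]
    base = state.evaluate()
    if base.status != OPTIMAL:
        return base
    return flux_range(state, target, anchor, fraction * base.objective_value)


def max_yield(state: SessionState, sink: str) -> FluxSolution:
    """Maximize flux through a consuming sink reaction, e.g. ATPM for ATP.

    Maximizing a stoichiometrically balanced consumption reaction forces the
    network to regenerate its substrate (the cofactor of interest) at the
    highest possible rate, so the optimum is the cofactor's maximal yield on
    the current medium.  The caller's objective is untouched.
    """
    return state.set_objective(sink, "maximize").evaluate()


def swap_carbon_source(
    state: SessionState,
    close: str,
    open: str,
    uptake_rate: float,
) -> SessionState:
    """Switch the medium's carbon source from one exchange to another.

    Sets the closing exchange's lower bound to 0 (no more uptake) and the
    opening exchange's lower bound to ``uptake_rate`` (negative = uptake, the
    exchange-flux sign convention).  Upper bounds are preserved.
    """
    for rid in (close, open):
        state._require_reaction(rid)
        if not state.base.reaction(rid).is_exchange:
            raise ValueError(
                f"{rid!r} is not an exchange reaction (expected single-metabolite "
                "stoichiometry)"
            )
    if uptake_rate > 0:
        raise ValueError(
            f"uptake_rate must be <= 0 (uptake is negative exchange flux), got {uptake_rate}"
        )
    _, close_ub = state.effective_bounds(close)
    _, open_ub = state.effective_bounds(open)
    return state.set_bounds(close, 0.0, close_ub).set_bounds(
        open, float(uptake_rate), open_ub
    )


def min_flux_at_production_fraction(
    state: SessionState,
    product: str,
    probe: str,
    fraction: float = 0.99,
) -> ProductionProbeResult:
    """Minimal probe flux while production is held near its maximum.

    Procedure: maximize the product flux to find P*; force production by
    setting the product's lower bound to ``fraction * P*``; minimize the
    probe flux.  Used to ask which pathways a production phenotype *requires*
    — e.g. whether a heterologous production route can run without any
    oxidative pentose phosphate pathway flux (probe G6PDH2r).

    Pure; returns both P* and the minimized probe flux.  If P* <= 0 the
    network is reported as non-producing and no minimization is attempted.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    state._require_reaction(probe)
    top = state.set_objective(product, "maximize").evaluate()
    if top.status != OPTIMAL:
        raise RuntimeError(
            f"maximizing {product!r} returned status {top.status!r}; "
            "cannot assess pathway usage"
        )
    p_max = top.objective_value
    if p_max <= 0:
        return ProductionProbeResult(
            product=product,
            probe=probe,
            fraction=fraction,
            product_maximum=p_max,
            probe_minimum=None,
            producing=False,
        )
    _, product_ub = state.effective_bounds(product)
    forced = state.set_bounds(product, fraction * p_max, product_ub)
    low = forced.set_objective(probe, "minimize").evaluate()
    if low.status != OPTIMAL:  # cannot happen for fraction <= 1, guard anyway
        raise RuntimeError(
            f"minimizing {probe!r} at forced production returned {low.status!r}"
        )
    return ProductionProbeResult(
        product=product,
        probe=probe,
        fraction=fraction,
        product_maximum=p_max,
        probe_minimum=-low.objective_value,
        producing=True,
    )
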