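"""Synthetic models, test oracles, and literature pathway reconstructions.

Everything here is generated in memory so the package builds and tests
without downloading anything:

* tiny networks with analytically known optima (:func:`make_chain`,
  :func:`make_branch`, :func:`make_coupled_production`);
* seeded random networks that are feasible by construction
  (:func:`make_random_feasible`);
* a brute-force vertex-enumeration LP oracle
  (:func:`enumerate_vertex_optimum`) used to cross-check the simplex
  backend on small problems;
* a generated Escher map for chain models (:func:`make_chain_map`);
* synthetic reconstructions of published heterologous 1-propanol production
  pathways for *E. coli* (:func:`add_1propanol_pathway`).

None of the generated networks aim for biological realism beyond what the
tests require; stoichiometric coefficients of random fixtures are drawn from
{-2, -1, 1, 2} to keep the oracle's linear algebra well conditioned.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import scipy.linalg

from .lp_core import ObjectiveSpec, StoichiometricMatrix
from .model_io import MetabolicModel, Metabolite, Reaction

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_chain",
    "make_branch",
    "make_coupled_production",
    "make_random_feasible",
    "enumerate_vertex_optimum",
    "make_chain_map",
    "add_1propanol_pathway",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic model; generation is bit-reproducible from
    (kind, n_reactions, seed, uptake_bound)."""

    kind: Literal["chain", "branch", "coupled", "random"]
    n_reactions: int = 3
    seed: int = 0
    uptake_bound: float = 10.0

    def __post_init__(self) -> None:
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")


def make_fixture(spec: FixtureSpec) -> MetabolicModel:
    if spec.kind == "chain":
        return make_chain(spec.n_reactions, spec.uptake_bound)
    if spec.kind == "branch":
        return make_branch(spec.uptake_bound)
    if spec.kind == "coupled":
        return make_coupled_production(spec.uptake_bound)
    if spec.kind == "random":
        return make_random_feasible(spec.n_reactions, spec.seed)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def make_chain(n: int, uptake: float) -> MetabolicModel:
    """Linear pathway: exchange -> n-1 conversions -> objective sink.

    ``n`` counts the chain metabolites, so the model has ``n + 1`` reactions.
    The exchange allows uptake of the first metabolite at rate ``uptake``
    (lower bound ``-uptake``); every other reaction is irreversible with
    upper bound 1000.  The analytic optimum of maximizing the sink flux is
    exactly ``uptake``, and knocking out any single interior reaction drops
    it to 0 (single pathway).
    """
    if n < 1:
        raise ValueError("chain needs at least one metabolite")
    if uptake <= 0:
        raise ValueError("uptake must be positive")
    metabolites = tuple(
        Metabolite(id=f"A{i}_c", name=f"chain metabolite {i}", compartment="c")
        for i in range(n)
    )
    reactions = [
        Reaction(
            id="EX_A0",
            name="A0 exchange",
            stoichiometry={"A0_c": -1.0},
            lower_bound=-float(uptake),
            upper_bound=1000.0,
        )
    ]
    for i in range(1, n):
        reactions.append(
            Reaction(
                id=f"CONV_{i}",
                name=f"A{i - 1} -> A{i}",
                stoichiometry={f"A{i - 1}_c": -1.0, f"A{i}_c": 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
            )
        )
    reactions.append(
        Reaction(
            id="SINK",
            name=f"A{n - 1} sink",
            stoichiometry={f"A{n - 1}_c": -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            objective_coefficient=1.0,
        )
    )
    return MetabolicModel(
        id=f"chain_{n}", metabolites=metabolites, reactions=tuple(reactions)
    )


def make_branch(uptake: float) -> MetabolicModel:
    """Y-shaped network: one uptake splits into two sinks; only the first
    sink carries the objective, so the optimum equals ``uptake``."""
    metabolites = tuple(
        Metabolite(id=i, compartment="c") for i in ("A_c", "B_c", "C_c")
    )
    reactions = (
        Reaction(id="EX_A", stoichiometry={"A_c": -1.0}, lower_bound=-uptake, upper_bound=1000.0),
        Reaction(id="A_TO_B", stoichiometry={"A_c": -1.0, "B_c": 1.0}, lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="A_TO_C", stoichiometry={"A_c": -1.0, "C_c": 1.0}, lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="SINK_B", stoichiometry={"B_c": -1.0}, lower_bound=0.0, upper_bound=1000.0, objective_coefficient=1.0),
        Reaction(id="SINK_C", stoichiometry={"C_c": -1.0}, lower_bound=0.0, upper_bound=1000.0),
    )
    return MetabolicModel(id="branch", metabolites=metabolites, reactions=reactions)


def make_coupled_production(uptake: float) -> MetabolicModel:
    """Network whose product excretion is stoichiometrically coupled 1:1 to a
    probe flux: A -> P + Q, with separate exchanges for P (product) and Q
    (probe).  Any product flux forces an equal probe flux."""
    metabolites = tuple(
        Metabolite(id=i, compartment="c") for i in ("A_c", "P_c", "Q_c")
    )
    reactions = (
        Reaction(id="EX_A", stoichiometry={"A_c": -1.0}, lower_bound=-uptake, upper_bound=1000.0),
        Reaction(id="CONV", stoichiometry={"A_c": -1.0, "P_c": 1.0, "Q_c": 1.0}, lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="EX_P", stoichiometry={"P_c": -1.0}, lower_bound=0.0, upper_bound=1000.0, objective_coefficient=1.0),
        Reaction(id="EX_Q", stoichiometry={"Q_c": -1.0}, lower_bound=0.0, upper_bound=1000.0),
    )
    return MetabolicModel(id="coupled", metabolites=metabolites, reactions=reactions)


def make_random_feasible(n: int, seed: int) -> MetabolicModel:
    """Random feasible network with ``n`` reactions, deterministic per seed.

    Construction guarantees feasibility: integer stoichiometry is drawn
    first, a reference flux vector ``v_ref`` is taken from the null space of
    S (so ``S v_ref = 0`` exactly up to round-off), and every reaction's
    bounds are placed strictly around its reference flux.  The solve status
    is therefore never infeasible.  One randomly chosen reaction carries a
    +/-1 objective coefficient.
    """
    if not 2 <= n <= 12:
        raise ValueError("random fixtures support 2..12 reactions")
    rng = np.random.default_rng(seed)
    m = max(1, n // 2)
    coefs = np.array([-2.0, -1.0, 1.0, 2.0])
    while True:
        mask = rng.random((m, n)) < 0.6
        S = np.where(mask, rng.choice(coefs, size=(m, n)), 0.0)
        # every reaction must touch a metabolite, every metabolite a reaction
        for j in range(n):
            if not S[:, j].any():
                S[rng.integers(m), j] = rng.choice(coefs)
        for i in range(m):
            if not S[i].any():
                S[i, rng.integers(n)] = rng.choice(coefs)
        null = scipy.linalg.null_space(S)
        if null.shape[1] > 0 or n == m:
            break
    if null.shape[1] > 0:
        direction = null @ rng.normal(size=null.shape[1])
        peak = np.abs(direction).max()
        v_ref = (
            direction / peak * rng.uniform(1.0, 5.0)
            if peak > 1e-12
            else np.zeros(n)
        )
    else:
        v_ref = np.zeros(n)
    lower = v_ref - rng.uniform(0.5, 3.0, size=n)
    upper = v_ref + rng.uniform(0.5, 3.0, size=n)
    objective_index = int(rng.integers(n))
    objective_sign = float(rng.choice([-1.0, 1.0]))

    metabolites = tuple(
        Metabolite(id=f"M{i}_c", compartment="c") for i in range(m)
    )
    reactions = tuple(
        Reaction(
            id=f"R{j}",
            stoichiometry={
                f"M{i}_c": float(S[i, j]) for i in range(m) if S[i, j] != 0
            },
            lower_bound=float(lower[j]),
            upper_bound=float(upper[j]),
            objective_coefficient=objective_sign if j == objective_index else 0.0,
        )
        for j in range(n)
    )
    return MetabolicModel(
        id=f"random_{n}_{seed}", metabolites=metabolites, reactions=reactions
    )


def enumerate_vertex_optimum(
    matrix: StoichiometricMatrix,
    bounds,
    objective: ObjectiveSpec,
    *,
    tolerance: float = 1e-7,
) -> float | None:
    """Brute-force LP oracle: best objective over all polytope vertices.

    Enumerates candidate vertices of ``{v : S v = 0, lb <= v <= ub}`` by
    fixing ``n - rank(S)`` variables at a bound over all index subsets and
    bound sides, solving each remaining square system, and keeping feasible
    candidates.  Every vertex of the polytope arises this way (for a
    degenerate vertex, through some nonsingular basis choice), so the best
    candidate is the true optimum — exact up to linear-algebra round-off and
    entirely independent of any LP solver.

    Returns the optimal objective value, or None when no feasible vertex
    exists (infeasible).  Requires finite bounds and is combinatorial:
    intended for ``n_reactions <= 8``.
    """
    n = matrix.n_reactions
    if n > 8:
        raise ValueError("vertex enumeration is intended for n_reactions <= 8")
    S = matrix.dense()
    lb = np.array([b[0] for b in bounds], dtype=float)
    ub = np.array([b[1] for b in bounds], dtype=float)
    if not (np.isfinite(lb).all() and np.isfinite(ub).all()):
        raise ValueError("vertex enumeration requires finite bounds")
    c = np.zeros(n)
    for rid, coef in objective.entries:
        c[matrix.column_index(rid)] = coef

    rank = int(np.linalg.matrix_rank(S)) if S.size else 0
    k = n - rank
    best: float | None = None
    scale = max(1.0, np.abs(S).max() if S.size else 1.0, np.abs(ub).max(), np.abs(lb).max())
    feas_tol = tolerance * scale

    for fixed_combo in itertools.combinations(range(n), k):
        fixed = list(fixed_combo)
        free = [j for j in range(n) if j not in fixed_combo]
        S_free = S[:, free]
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue  # no unique basic solution for this basis; another covers it
        for sides in itertools.product((0, 1), repeat=k):
            v = np.empty(n)
            for j, side in zip(fixed, sides):
                v[j] = ub[j] if side else lb[j]
            if free:
                rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                if np.linalg.norm(S_free @ sol - rhs) > feas_tol:
                    continue
                v[free] = sol
            if S.size and np.abs(S @ v).max() > feas_tol:
                continue
            if (v < lb - feas_tol).any() or (v > ub + feas_tol).any():
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best


def make_chain_map(model: MetabolicModel) -> str:
    """Generate an Escher (schema 1) map JSON for a chain-style model.

    Metabolites become metabolite nodes laid out left to right; each reaction
    gets a midmarker node and segments connecting its substrate/product
    nodes.  The output parses with
    :func:`fluxlens.map_overlay.parse_escher_map`, which lets the overlay
    and rendering code paths be exercised without an external map file.
    """
    nodes: dict[str, dict] = {}
    met_node: dict[str, str] = {}
    x = 0.0
    for i, met in enumerate(model.metabolites):
        node_id = f"n{i}"
        met_node[met.id] = node_id
        nodes[node_id] = {
            "node_type": "metabolite",
            "x": 100.0 + 200.0 * i,
            "y": 200.0,
            "bigg_id": met.id,
        }
    reactions: dict[str, dict] = {}
    next_node = len(nodes)
    for j, rxn in enumerate(model.reactions):
        mid_id = f"n{next_node}"
        next_node += 1
        substrate_xs = [
            nodes[met_node[m]]["x"] for m in rxn.stoichiometry if m in met_node
        ]
        nodes[mid_id] = {
            "node_type": "midmarker",
            "x": float(np.mean(substrate_xs)) + 100.0,
            "y": 120.0,
        }
        segments: dict[str, dict] = {}
        seg = 0
        for met_id, coef in sorted(rxn.stoichiometry.items()):
            a, b = (met_node[met_id], mid_id) if coef < 0 else (mid_id, met_node[met_id])
            segments[f"s{j}_{seg}"] = {"from_node_id": a, "to_node_id": b}
            seg += 1
        reactions[f"r{j}"] = {
            "bigg_id": rxn.id,
            "label_x": nodes[mid_id]["x"],
            "label_y": 90.0,
            "segments": segments,
        }
    header = {
        "map_name": f"{model.id} (generated)",
        "map_id": f"fluxlens_{model.id}",
        "map_description": "generated layout for a synthetic model",
        "homepage": "https://escher.github.io",
        "schema": "https://escher.github.io/escher/jsonschema/1-0-0#",
    }
    body = {
        "reactions": reactions,
        "nodes": nodes,
        "text_labels": {},
        "canvas": {
            "x": 0.0,
            "y": 0.0,
            "width": 200.0 + 200.0 * len(model.metabolites),
            "height": 400.0,
        },
    }
    return json.dumps([header, body])


# ---------------------------------------------------------------------------
# heterologous 1-propanol pathways


def add_1propanol_pathway(
    model: MetabolicModel, *, include_citramalate: bool = False
) -> MetabolicModel:
    """Graft a synthetic 1-propanol production pathway onto an *E. coli* GEM.

    This is a reconstruction assembled from the published pathway
    stoichiometries, not a curated model file.  It expects a genome-scale
    *E. coli* model (e.g. iJO1366) that already contains 2-ketobutyrate
    (``2obut_c``), propanal (``ppal_c``) and the usual cofactor pool.

    Always added (the keto-acid route: 2-ketobutyrate, supplied natively via
    threonine deaminase, is decarboxylated and reduced to 1-propanol):

    * ``2OBUTDC``  2obut + h -> ppal + co2      (2-ketoacid decarboxylase)
    * ``PPOHDH``   ppal + nadh + h -> 1poh + nad  (alcohol dehydrogenase)
    * ``1POHt``    1poh_c <-> 1poh_e             (diffusion)
    * ``EX_1poh_e`` 1-propanol excretion

    With ``include_citramalate=True``, the synergistic citramalate route to
    2-ketobutyrate is added as well, bypassing threonine biosynthesis (and
    its NADPH demand):

    * ``CIMA``     accoa + pyr + h2o -> citmal + coa + h  (citramalate synthase)
    * ``CITMISO``  citmal <-> 3mmal                       (isomerase, net)
    * ``3MMALDH``  3mmal + nad -> 2obut + co2 + nadh      (dehydrogenase)
    """
    for required in ("2obut_c", "ppal_c", "h_c", "nadh_c", "nad_c", "co2_c"):
        model.metabolite(required)  # raises KeyError with a clear message

    new_metabolites = [
        Metabolite(id="1poh_c", name="1-propanol", compartment="c", formula="C3H8O"),
        Metabolite(id="1poh_e", name="1-propanol", compartment="e", formula="C3H8O"),
    ]
    new_reactions = [
        Reaction(
            id="2OBUTDC",
            name="2-ketobutyrate decarboxylase",
            stoichiometry={"2obut_c": -1.0, "h_c": -1.0, "ppal_c": 1.0, "co2_c": 1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        ),
        Reaction(
            id="PPOHDH",
            name="1-propanol dehydrogenase",
            stoichiometry={
                "ppal_c": -1.0,
                "h_c": -1.0,
                "nadh_c": -1.0,
                "1poh_c": 1.0,
                "nad_c": 1.0,
            },
            lower_bound=0.0,
            upper_bound=1000.0,
        ),
        Reaction(
            id="1POHt",
            name="1-propanol transport (diffusion)",
            stoichiometry={"1poh_c": -1.0, "1poh_e": 1.0},
            lower_bound=-1000.0,
            upper_bound=1000.0,
        ),
        Reaction(
            id="EX_1poh_e",
            name="1-propanol exchange",
            stoichiometry={"1poh_e": -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        ),
    ]
    if include_citramalate:
        for required in ("accoa_c", "coa_c", "pyr_c", "h2o_c"):
            model.metabolite(required)
        new_metabolites += [
            Metabolite(id="citmal_c", name="(R)-citramalate", compartment="c", formula="C5H6O5"),
            Metabolite(id="3mmal_c", name="beta-methyl-D-malate", compartment="c", formula="C5H6O5"),
        ]
        new_reactions += [
            Reaction(
                id="CIMA",
                name="citramalate synthase",
                stoichiometry={
                    "accoa_c": -1.0,
                    "pyr_c": -1.0,
                    "h2o_c": -1.0,
                    "citmal_c": 1.0,
                    "coa_c": 1.0,
                    "h_c": 1.0,
                },
                lower_bound=0.0,
                upper_bound=1000.0,
            ),
            Reaction(
                id="CITMISO",
                name="citramalate isomerase (net)",
                stoichiometry={"citmal_c": -1.0, "3mmal_c": 1.0},
                lower_bound=-1000.0,
                upper_bound=1000.0,
            ),
            Reaction(
                id="3MMALDH",
                name="3-methylmalate dehydrogenase",
                stoichiometry={
                    "3mmal_c": -1.0,
                    "nad_c": -1.0,
                    "2obut_c": 1.0,
                    "co2_c": 1.0,
                    "nadh_c": 1.0,
                },
                lower_bound=0.0,
                upper_bound=1000.0,
            ),
        ]
    return replace(
        model,
        id=f"{model.id}_1poh" + ("_synergistic" if include_citramalate else ""),
        metabolites=model.metabolites + tuple(new_metabolites),
        reactions=model.reactions + tuple(new_reactions),
    )
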