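# Methods

## The model

fluxlens implements flux balance analysis (FBA): given a genome-scale
metabolic network with stoichiometric matrix `S` (metabolites × reactions),
it assumes the internal metabolite pools are at steady state (`S v = 0`),
bounds each flux `v_j` to `[lb_j, ub_j]` (mmol/gDW/hr; the biomass
pseudo-reaction's flux is in h⁻¹), and maximizes a linear objective
`cᵀ v`. The assumptions inherited from FBA apply in full: no kinetics, no
regulation, no metabolite concentrations — predictions are stoichiometric
capabilities, not rates a real cell necessarily achieves; the growth medium
enters only through exchange-reaction lower bounds (negative = uptake
allowed), and uptake bounds stand in for experimental measurements.

Objective coefficients are restricted to ±1 by construction
(`ObjectiveSpec` rejects anything else): an objective is "maximize this
reaction's flux", "minimize it", or a compound sum of such terms. This keeps
the session API honest — arbitrary objective weights are unrepresentable —
at the cost of not expressing weighted multi-objective trade-offs, which are
out of scope.

## LP solving

The default backend is SciPy's interface to **HiGHS dual simplex**
(`method="highs-ds"`). A simplex-type method is a deliberate design choice:
the returned flux vector is then a vertex of the flux polytope, which makes
solutions reproducible for a fixed backend and makes the vertex-enumeration
oracle (below) a complete cross-check. Backends are pluggable through
`lp_core.register_backend`; the contract is `(S, bounds, c) -> (status, v)`
with status in {optimal, infeasible, unbounded}.

Numerical choices:

* solver primal/dual feasibility tolerance `1e-9`; assertions on returned
  vectors (steady state, bounds) use the looser `1e-6`, leaving two decades
  of headroom for double-precision accumulation;
* solver statuses outside {optimal, infeasible, unbounded} (iteration
  limits, numerical failure) raise `SolverError` rather than being mapped to
  a status — callers should never mistake a numerical breakdown for
  infeasibility;
* **no tie-break between alternate optima.** FBA optima are routinely
  degenerate; only status and objective value are contractual. `flux_range`
  exists precisely to quantify the ambiguity; parsimonious or
  norm-minimizing variants are out of scope.

## Sessions

`SessionState` is an immutable value: every edit returns a new state, and
the base model plus its stoichiometric matrix (built once, shared across
derived states) are never touched. Effective bounds resolve as
knockout > override > base, so a knockout dominates any bound override on
the same reaction until that reaction is reset — matching the intuition that
a knocked-out reaction stays off no matter how its slider is moved.
Single-objective mode keeps exactly one ±1 entry; compound mode accumulates
entries, re-targeting replaces a reaction's coefficient (and refreshes its
recency), and leaving compound mode collapses the objective to the most
recently set entry — the least surprising reading of an underspecified
toggle.

## Analysis procedures

* `flux_range(state, target, anchor, anchor_value)` pins the anchor with
  `lb = ub = anchor_value` **exactly** — not the `lb`-only convention some
  FVA tools use — then maximizes and minimizes the target. The exact-pin
  convention is what reproduces the documented GAPD/MALS ranges on the core
  model. The primitive takes an explicit anchor value (e.g. 0.870, just
  below the 0.874 optimum); `flux_range_at_fraction` computes
  `fraction × current optimum` (default 0.99) for convenience. An infeasible
  anchor returns the status-bearing `FluxSolution` rather than raising:
  "that growth rate is not achievable" is a result, not an error.
* `max_yield(state, sink)` maximizes a stoichiometrically balanced
  consumption reaction (e.g. ATPM), which forces maximal regeneration of the
  consumed cofactor. Sinks must already exist in the model; creating demand
  reactions automatically is an explicit non-goal.
* `min_flux_at_production_fraction` maximizes a product flux (P*), forces
  production ≥ `fraction·P*`, then minimizes a probe flux — the standard
  question "which pathway flux does this production phenotype *require*?".
* `swap_carbon_source` composes two bound edits (close: lb→0; open:
  lb→uptake_rate ≤ 0) and validates that both reactions are exchanges
  (single-metabolite stoichiometry).

## Reference models and the 1-propanol reconstruction

The *E. coli* core network (BiGG `e_coli_core`, 95 reactions) and iJO1366
are obtained at run time by converting COBRApy's bundled SBML files to COBRA
JSON with COBRApy itself — the standard converter for formats this package
deliberately does not read (SBML import is a non-goal). All computation
downstream of the JSON text is fluxlens's own.

`fixtures.add_1propanol_pathway` grafts **synthetic reconstructions** of two
published heterologous 1-propanol production routes onto iJO1366; they are
assembled from the literature pathway stoichiometries, not taken from any
curated model file. The single (keto-acid) route adds 2-ketobutyrate
decarboxylase and an NADH-dependent alcohol dehydrogenase plus transport and
exchange; 2-ketobutyrate itself comes from native threonine biosynthesis,
which consumes 2 NADPH per molecule — hence the route's demand for oxidative
pentose-phosphate-pathway (PPP) flux. The synergistic variant adds the
citramalate route (citramalate synthase, net isomerase, 3-methylmalate
dehydrogenase), which reaches 2-ketobutyrate from pyruvate + acetyl-CoA with
no NADPH demand and is stoichiometrically balanced with glycolysis. The
package's acceptance run reproduces the qualitative contrast (minimal
G6PDH2r flux strictly positive for the single route, zero for the
synergistic one, higher maximal yield for the synergistic design); exact
flux magnitudes depend on this reconstruction's stoichiometry and should be
read qualitatively.

## Synthetic fixtures and the oracle

The fixture generator emulates the *structure* of metabolic LPs — sparse
integer stoichiometry, irreversibility via bounds, exchange/sink boundary
reactions — not their biology: no cofactor coupling, no biomass composition,
no realistic network motifs. Passing fixture tests therefore demonstrates
correctness of the LP/session machinery, not predictive validity on real
organisms; the reference-model tests carry that weight.

* `make_chain(n, uptake)`: exchange → n−1 conversions → objective sink
  (`n` chain metabolites, `n+1` reactions); analytic optimum = `uptake`,
  and any interior knockout drops it to 0.
* `make_random_feasible(n, seed)`: integer coefficients from {−2, −1, 1, 2}
  (kept small so the oracle's linear algebra stays well-conditioned), with
  `m = n//2` metabolites so the null space is non-trivial; a reference flux
  `v_ref` is drawn from the null space and bounds are placed strictly around
  it, guaranteeing `S v_ref = 0` and hence feasibility. Deterministic per
  seed via `numpy.random.default_rng`; no global random state.
* `enumerate_vertex_optimum` is the independent oracle: it enumerates all
  candidate basic solutions by fixing `n − rank(S)` variables at a bound
  over every index subset and bound side, solves each reduced system, keeps
  feasible candidates, and returns the best objective (None = infeasible).
  It shares no code with the simplex path and is exact up to round-off;
  combinatorics restrict it to ≤ 8 reactions and finite bounds.

## Maps and rendering

Escher map schema 1 (`[header, body]`) is parsed with unknown header fields
tolerated (schema URLs drift between releases); segment endpoints must
resolve to declared nodes. Coordinates are used as given in Escher's y-down
screen convention — no re-layout. The SVG renderer draws one path per
segment with stroke width linear in `|flux|`, normalized to the overlay's
largest `|flux|`, between configurable endpoints (default 2–14 px);
reactions without overlay data are drawn dashed at the minimum width, and
negative fluxes use the same width rule (arrowhead direction is out of
scope). Output is deterministic: reactions, segments and nodes are emitted
in sorted id order.

## CLI edit ordering

Repeatable edit flags cannot recover their interleaved order on the command
line, so edits apply in a fixed order — bound overrides (later repeats of
the same flag win), then knockouts, then the objective. Because knockouts
dominate bound overrides on the same reaction regardless of ordering, this
reproduces the outcome of applying the same edits one at a time
interactively in all non-pathological cases.

## Problem sizes and limitations

The test suite and acceptance script run the full core model (95 reactions),
iJO1366 (2583 reactions, a few LP solves), a 100-network oracle sweep at
3–6 reactions, and property tests over seeded fixture families — sizes
chosen so a complete run takes well under a minute of solver time while
still exercising genome scale once. Known limitations: no gene-level
knockouts (GPR rules are stored verbatim, never evaluated), no whole-network
batch FVA beyond the thin CLI loop, no parsimonious/loopless FBA, no
SBML/MAT import, no automatic demand-reaction creation, and flux vectors at
degenerate optima depend on the backend.
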