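# fluxlens

Scriptable **flux balance analysis** (FBA) for genome-scale metabolic models
in COBRA JSON, with session-style perturbations (bound edits, knockouts,
objective switching), single-reaction flux variability, yield analysis, and
flux overlays for [Escher](https://escher.github.io) pathway maps.

FBA predicts steady-state reaction fluxes in a metabolic network by solving
the linear program

```
maximize    cᵀ v
subject to  S v = 0
            lb ≤ v ≤ ub
```

where `S` is the stoichiometric matrix (metabolites × reactions), `v` the
flux vector in mmol/gDW/hr, `lb`/`ub` the flux bounds encoding reaction
reversibility and the growth medium, and `c` selects the objective —
typically the biomass pseudo-reaction, whose flux (h⁻¹) approximates the
growth rate. fluxlens is aimed at people who want to *script* the kind of
interactive what-if experiments usually done by hand: change a carbon
source, knock out a reaction, re-point the objective, and immediately see
how the optimal flux state responds — then export the fluxes onto a pathway
map.

Objective coefficients are deliberately restricted to ±1 ("maximize" /
"minimize" a reaction's flux, optionally combined in a compound objective);
the LP backend is a simplex method (HiGHS dual simplex via SciPy), so
returned flux vectors are vertices of the flux polytope. FBA optima are
routinely non-unique — only the status and objective value are well-defined,
and the reported flux vector is one optimal vertex among possibly many (see
`flux_range` for quantifying that ambiguity).

## Worked example

Switch *E. coli* from glucose to succinate and watch growth drop, then probe
how constrained glycolytic flux is at near-maximal growth:

```python
from fluxlens import SessionState, datasets, flux_range, swap_carbon_source

state = SessionState.from_model(datasets.load_e_coli_core())
print(round(state.evaluate().objective_value, 3))          # 0.874

succ = swap_carbon_source(state, "EX_glc__D_e", "EX_succ_e", -10.0)
succ = succ.knockout("EX_glc__D_e")
print(round(succ.evaluate().objective_value, 3))           # 0.398

anaerobic = succ.knockout("EX_o2_e")
print(anaerobic.evaluate().status)                         # infeasible

gapd = flux_range(state, "GAPD", "Biomass_Ecoli_core", 0.870)
print(round(gapd.minimum, 2), round(gapd.maximum, 2))      # 15.44 16.68
```

Reading the numbers: on glucose the predicted growth rate is 0.874 h⁻¹;
on succinate at the same uptake rate it falls to 0.398 h⁻¹ (lower growth
yield per carbon); without oxygen a succinate-only medium supports no
feasible flux state at all — the cell is predicted dead. With biomass pinned
just below its optimum (0.870 h⁻¹), the glyceraldehyde-3-phosphate
dehydrogenase flux can only range over 15.44–16.68 mmol/gDW/hr: glycolysis
is tightly constrained at high growth, whereas e.g. the glyoxylate-shunt
reaction MALS ranges over 0–2.64 and is entirely optional.

The same experiments from the shell:

```sh
fluxlens fixture --kind chain --n 3 --uptake 10 --out chain.json --map-out chain.map.json
fluxlens fba chain.json --knockout CONV_1        # exit 0, objective 0.0
fluxlens fva chain.json CONV_1 --anchor SINK --anchor-value 10
fluxlens overlay chain.json chain.map.json --out overlay.json --svg overlay.svg
```

Exit codes: 0 optimal, 3 infeasible, 4 unbounded, 2 usage error, 1 internal.

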