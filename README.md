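# pdoflux

Constraint-based strain design for photoautotrophic 1,3-propanediol
(1,3-PDO) production in *Synechococcus elongatus*.

Cyanobacteria can convert CO₂ directly into chemicals. A production strain
carrying a heterologous four-step pathway drains the Calvin-cycle metabolite
dihydroxyacetone phosphate (DHAP) through glycerol and
3-hydroxypropionaldehyde into 1,3-PDO. `pdoflux` implements the in-silico
workflow used to find gene knockouts that improve that drain:

1. **Pathway grafting** — add the synthetic pathway (8 genes, 6 reactions,
   3 new metabolites; the glycerol-dehydratase/reactivase step is an
   AND-type multi-subunit complex) onto a stoichiometric wild-type model.
2. **Input-flux estimation** — photoautotrophic inputs cannot be measured
   directly, so with measured outputs (growth rate μ, specific production
   rates q_PDO, q_glycerol) fixed, a two-step optimization first minimizes
   the carbon-fixation uptake and then, with carbon fixed at that minimum,
   the photon uptake (after Shastri & Morgan).
3. **FBA solution space** — flux balance analysis (maximize v_biomass
   subject to S·v = 0 and bounds) under the estimated input constraints,
   plus the growth-vs-production envelope (min/max q_PDO on a μ grid).
4. **MOMA deletion screen** — for every single-gene deletion (pathway genes
   excluded), minimization of metabolic adjustment: the quadratic program
   min ‖v − w‖² over steady-state flux vectors with the GPR-disabled
   reactions forced to zero, carbon fixation held fixed, photons capped,
   and the measured q_PDO as a production lower limit. The wild-type
   reference w is the unique minimum-norm flux anchored to the measured
   rates. Phenotypes fall into four groups — (1) infeasible, (2) feasible
   but zero growth, (3) growing with a lower product score, (4) growing
   with a top product score μ·q_PDO — and deletions with identical flux
   distributions (complex subunits, serial unbranched steps) collapse into
   flux patterns.

The package ships a synthetic toy photoautotroph (photon/CO₂ exchanges, a
RubisCO with the photorespiration-lumped 1.97 3-PG yield, a Calvin branch
point at DHAP, an NDH-1-like AND complex for cyclic electron flow, isozymes,
a glycogen sink) whose FBA optima are known in closed form, so the entire
pipeline is testable without any external genome-scale model. Real models
are read from SBML Level 3 + FBC v2 or a native JSON dialect.

## Worked example

```sh
pdoflux run --out run1 --pdo-lower 0.03
```

runs the full pipeline on the toy model with measured rates
μ = 0.1 h⁻¹, q_PDO = 0.03, q_glycerol = 0.05 mmol (g DCW)⁻¹ h⁻¹, logging

```
INFO stage 3/6: input-flux estimation
INFO   carbon fixation 0.923077, photon 8.81154 mmol/(g DCW)/h
```

i.e. the measured outputs require fixing 0.923 mmol CO₂ and absorbing
8.81 mmol photons per g DCW per hour. `run1/manifest.json` then reports

```
"group_counts": {"1": 6, "2": 1, "3": 6, "4": 0},
"mu_max": 0.10249999999999997,
"n_patterns": 3
```

Growth could reach 0.1025 h⁻¹ if production stopped; of the 13 screened
genes, 6 deletions cannot meet the constraints (group 1, e.g. RubisCO),
1 abolishes growth while carbon still reaches the pathway (group 2), and
the three subunits of the cyclic-electron-flow complex share one flux
pattern in which q_PDO rises from 0.030 to 0.044 — the screen's top
candidate (with `--group4-rule top-pattern` on the `screen` subcommand they
form group 4). Individual stages are available as `toy`, `stub`,
`augment`, `fba`, `inputs`, `envelope`, `screen` and `summarize`
subcommands, and everything is importable from Python (`import pdoflux`).

A strain-comparison summary from a rates table:

```sh
pdoflux summarize --rates rates.tsv --reference-strain TA2984
```

prints, for each strain, the product sum q_PDO + q_glycerol (total DHAP
drain), its fold-change versus the reference, and the 1,3-PDO ratio
q_PDO / sum — e.g. `0.0752  1.00  0.315` for a reference measured at
q_PDO = 0.0237 and q_glycerol = 0.0515.

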