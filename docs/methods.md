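# Methods

## The model class

`pdoflux` works on stoichiometric metabolic models: metabolites, reactions
with flux bounds (mmol (g DCW)⁻¹ h⁻¹; the biomass pseudo-reaction carries
units of h⁻¹), and gene–protein–reaction (GPR) boolean associations where
AND encodes complex subunits and OR encodes isozymes. The steady-state
assumption S·v = 0 is the central constraint; exchange reactions are
written `metabolite →` so uptake is a negative flux, and reported "input
fluxes" (carbon fixation, photon use) are uptake magnitudes. Non-integer
stoichiometry is stored as plain floats — deliberately, because the
photorespiration-lumped RubisCO of cyanobacterial reconstructions produces
a fractional 1.97 3-PG per RuBP and per fixed CO₂.

Gene deletions act only through GPRs: a reaction is disabled exactly when
its GPR evaluates false with the deleted genes removed. This makes deletion
effects monotone (a larger deleted set never re-activates a reaction) and
implies that all subunits of an AND complex produce the same disabled set,
which is why deletion simulations collapse into *flux patterns*.

## Pathway grafting

A `PathwaySpec` is data, not code: new metabolites, reactions, genes and
role ids, serializable in the same JSON dialect as models. The default
1,3-PDO spec has 8 genes (gpd1, hor2, dhaB1–3, gdrA, gdrB, yqhD — the
canonical heterologous route), 6 reactions (4 enzymatic steps plus glycerol
and 1,3-PDO exchanges, all irreversible forward: the pathway is a committed
sink) and exactly 3 new metabolites (glycerol, 3-HPA, 1,3-PDO). The DHAP
and glycerol-3-phosphate species are *anchors mapped onto the base model*
(`dhap_id`, `g3p_id`); G3P is assumed present in the base because real
reconstructions carry it as a lipid precursor, and the toy model carries it
for the same reason. Which species are new versus mapped is an assumption
the spec makes explicit and overridable; the composition of the published
production-strain model is not enumerated anywhere, only its count deltas
(+8 genes, +6 reactions, +3 metabolites), which the default reproduces.
Cofactor usage per reductive step (`gpd_cofactor_id`,
`reductase_cofactor_id`) is likewise spec data; `None` omits the cofactor
(used for count stubs), and the toy maps both onto its lumped NADPH pool.

Augmentation is conservative by construction: the base model is never
mutated, counts increase by exactly the spec sizes, and any base-feasible
flux state extends with zeros on the new reactions.

## LP and QP layer

FBA is solved with scipy's HiGHS interface (feasibility and optimality
tolerances 1e-9). Infeasibility and unboundedness are reported as statuses,
never silent zeros.

MOMA and the reference flux are projections onto the feasible polytope
{S·v = 0, l ≤ v ≤ u}: strictly convex QPs with unique solutions. They are
solved with OSQP (eps 1e-10, polishing on) followed by an exact KKT solve
on the detected active set; the refined point is accepted only if feasible
and not worse, which gives near machine precision, bit-reproducibility
across runs, and insensitivity to reaction ordering. Feasibility is gated
by an LP first so that "infeasible" is detected crisply rather than
inferred from QP solver codes. An independent QP route (scipy SLSQP on the
same projection) serves as a cross-check in the test suite, never as the
implementation.

The MOMA reference is the minimum-L2-norm flux vector among states
attaining the constrained biomass optimum (two-stage: fix the objective,
then minimize ‖v‖²). In the pipeline the constraint set already pins
biomass, q_PDO and q_glycerol to their measured values — anchoring the
reference to the observed phenotype — so stage 1 is a no-op; anchoring to
the unconstrained FBA optimum instead is available by passing a constraint
set without those equalities.

## Input-flux estimation

Measured rates enter as equalities (tolerance of the LP itself, ~1e-9),
reflecting their role as observed fluxes rather than requirements. The
two-step order is carbon-then-photon by default: carbon fixation is
stoichiometrically pinned by the outputs, and photon demand then measures
the energy cost of that carbon budget. The reverse order
(`order="photon-first"`) is implemented because the published description
of the procedure ("with some modifications") does not fix the order; on
networks where the two resources are not interchangeable the results
coincide, and both orders are exercised in tests.

## The deletion screen

Across all deletions the carbon-fixation flux is held fixed (the one
assumption stated explicitly in the source workflow) and photon uptake is
capped at its estimated value (configurable to fixed). The measured 1,3-PDO
rate is a screen-wide production lower bound and is enforced uniformly,
including for zero-growth records — that uniform enforcement is what makes
the infeasible group non-empty. The lower bound is a **required** input
with no default: the published numbers for it conflict internally (0.0250
in the screen description versus 0.0273 in the text and 0.0237 in the
table of the same study), so silently choosing one would hide a real
ambiguity. For the same reason the published group arithmetic (595 genes
minus 8 pathway genes versus "581 strains"; group counts summing to 595)
cannot be reproduced exactly from its own description; the screen simply
reports exact counts for whatever exclusion list is supplied.

Classification: group 1 = infeasible; group 2 = feasible with
μ ≤ `zero_growth_tol` (default 1e-6 h⁻¹ — "null growth" is published
without a tolerance); groups 3/4 split the growing remainder by the product
score μ·q_PDO. The split rule is explicit configuration with three
built-ins — `top-pattern` (records attaining the maximal score),
`quantile:q`, `threshold:x` — because the published 231/36 split states no
rule. The library default `quantile:0.87` mirrors "top ~13% of 267
candidates" as a documented heuristic, not as ground truth; on the toy
screen, where half the candidates tie at the maximum, `top-pattern` is the
informative choice and is what the example pipeline and acceptance script
use.

Pattern collapsing compares flux vectors in max-norm after clipping
|v| < 1e-9 to zero, with tolerance 1e-6; pattern ids are dense integers
ordered by descending representative score. Genes with identical disabled
sets are solved once and share a state, so subunit co-assignment is exact
by construction, while serial-unbranched gene pairs (different disabled
sets, identical flux consequences) are caught by the numerical comparison.

## The toy photoautotroph

The generator emulates the structural features the pipeline must exercise:
photon and CO₂ exchanges; linear electron flow producing ATP and NADPH at
fixed yields (defaults 0.375 and 0.25 per photon ≈ 3 ATP + 2 NADPH per 8
photons); an NDH-1-analog cyclic flow producing ATP only (0.5 per photon)
behind an AND GPR of configurable size; RubisCO with the 1.97 3-PG yield; a
condensed Calvin loop (5 GAP + 3 ATP → 3 RuBP) giving a net triose yield of
pg_yield − 5/3 ≈ 0.303 per CO₂, close to the 1/3 of an unlumped cycle; a
PGK/GAPDH serial pair; TPI isozymes; a DHAP branch point feeding a lumped
lower glycolysis (pyk) toward biomass; dissipation valves (a Mehler-like
reductant valve and a non-forced ATP maintenance valve, both gene-free so
they are never deletable); and an optional glycogen sink. Default uptake
limits are 20 (photon) and 1.35 (CO₂) mmol (g DCW)⁻¹ h⁻¹, and the default
measured rates for the example pipeline are μ = 0.1 h⁻¹, q_PDO = 0.03,
q_glycerol = 0.05 — small-integer stoichiometry throughout so the optima
are exact rational functions of the yields.

Because photon demand for any (ATP, NADPH) requirement has the closed form
P = N/n + max(0, A − (a/n)·N)/max(c, a) (with cyclic flow; P = max(N/n,
A/a) without), maximal growth and maximal production are computable by
hand and are emitted in a manifest next to the model; tests verify
manifest-vs-LP agreement to 1e-8 relative over 100 random parameter draws.
The seed shuffles only the order of metabolite and reaction lists — never
stoichiometry — so runs are reproducible and order-robustness is exercised
for free.

What the toy does *not* capture: quantitative cyanobacterial
photophysiology (light attenuation, photoinhibition, spectral effects),
compartmentation and proton/charge bookkeeping, NADH/NADPH distinction
(one lumped reductant pool), thermodynamic feasibility, and genome-scale
redundancy (its GPRs are one-complex/one-isozyme-pair deep). Passing tests
therefore demonstrate correctness of the algorithms on a network with the
right *shape*, not predictions about the real organism; genome-scale
quantities (e.g. a 0.029 h⁻¹ maximal growth under 1.35/19.0 input fluxes,
or a 254-gene essential group) require the external published
reconstruction, which the I/O layer can load but which is not distributed
here.

## Numerical choices

- Steady-state check: max-norm of S·v, default tolerance 1e-6.
- LP: HiGHS, tolerances 1e-9/1e-9; QP: OSQP 1e-10 + exact active-set
  refinement (acceptance: feasible within 1e-9 and objective not worse).
- Zero-clipping at 1e-9 before pattern comparison; pattern tolerance 1e-6.
- Display rounding (3 significant digits for rates and ratios, 2 decimals
  for folds) is applied only in display accessors and TSV rendering; all
  comparisons and stored values are unrounded.
- Tie-breaks are deterministic everywhere: ranking by (group, −score,
  gene id); report rows sorted by gene id; JSON with sorted keys.
- Degenerate inputs: infeasible MOMA is an outcome (status), infeasible
  reference constraints are an error; an envelope apex that is infeasible
  at the exact μ_max retreats by one part in 1e9.

## Known limitations

- SBML round-trips preserve semantics (stoichiometry, bounds, GPR truth
  tables, objective) but not annotations; exchange status is inferred from
  single-species reactions with an `EX_` id prefix, and the pipeline's role
  ids travel in model notes rather than a standard SBML slot.
- Linear (L1) MOMA is available as `solve_moma(..., variant="linear")` for
  solver robustness, but its optimum can be degenerate (non-unique), so the
  screen uses the quadratic form. Double deletions, ROOM and bilevel
  (OptKnock-style) design are out of scope.
- `estimate_input_fluxes` treats measured rates as exact; there is no
  error propagation from rate uncertainty.
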