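# Methods

## Model

`qualflux` couples two steady-state formalisms.

The regulatory layer is a qualitative multi-state logical network: each
component (gene, protein, signalling molecule, environmental metabolite)
takes an integer level in `[0, max_level]`; at most one transition rule
per component gives its next level as the first matching case of an
ordered list of logical conditions (comparisons of component levels
against integer constants combined with AND/OR/NOT), with a default
level when no case matches. Components without a rule are constant
inputs. Updating is **synchronous**: every regulated component moves
simultaneously as a function of the previous global state. Because the
state space is finite (∏(max_level+1) states) and the update
deterministic, every trajectory enters a cycle; the regulatory
steady-state analysis (RSA) iterates until a state repeats and reports
the cycle — a point attractor (fixed point) or a cyclic attractor.
Random asynchronous updating is deliberately out of scope; the only
asynchrony supported is the deterministic per-species expression delay
used by the dynamic simulation (below).

The metabolic layer is a standard stoichiometric model: FBA maximises a
linear objective c·v subject to S·v = 0 over internal metabolites and
flux bounds (mmol/(gDW·h)). External (boundary) metabolites are exempt
from mass balance and connect to the network through exchange
reactions.

The bridge between the layers is the state↔interval **equivalence**: a
user-declared mapping from each qualitative level of a component to a
continuous interval. It is used in both directions — inbound, to
discretise a concentration (mmol/l) from the constraint file into an
initial level; outbound, to turn an attractor level into a flux
interval. For a cyclic attractor the per-component summary is the
interval [mean of member lower bounds, mean of member upper bounds]
(arithmetic mean of levels for components without equivalences). The
averaging models an unsynchronised population in which every phase of
the cycle is equally represented; a mean with an unbounded member bound
is unbounded, and is later clipped by the model's own bounds.

Constraints enter the LP in three ways. A constraint on a reaction id
intersects the reaction's bounds with the interval (an interval end of
±inf defers to the model bound; an empty intersection is reported as an
infeasible-bound error naming the reaction). A gene's constraint feeds
the reaction GPRs: a gene counts as *off* only when its constraint is
exactly zero (interval [0,0] or mean 0); any positive mean — e.g. 0.5
from a two-phase cycle — counts as active, since the population
interpretation above means some cells express it. A reaction whose GPR
evaluates false gets bounds (0,0). An external metabolite constrained to
zero caps the *uptake* direction of its exchange reaction at zero;
secretion is unaffected. Genes absent from the steady state are
unregulated and default to active.

## Derived analyses

**FVA** fixes the objective at γ·optimum (default γ = 1, imposed as an
inequality with a 1e-6 relative slack for numerical robustness) and then
minimises and maximises each target flux. The assembled constraint
matrices are built once and reused across the per-reaction solves; a
test verifies the result equals fully cold per-reaction LPs.

**Knockouts** clamp one component at a time to zero — reactions get
bounds (0,0); regulatory components are frozen at level 0 for the whole
RSA (their rule suspended); bare genes force their GPRs to evaluate with
the gene off; external metabolites get uptake capped at zero — then
rerun RSA + constraint translation + FBA.

**Phenotype phases** scan one or two reaction fluxes over a grid, fixing
them and re-optimising. The shadow price along each axis is the forward
finite difference of the optimal objective over one grid step (backward
at the far edge), which makes phase labels independent of the LP
backend's choice of dual solution. Points whose shadow-price vectors
agree after rounding to 6 decimals share a phase; labels are consecutive
integers in scan order; infeasible points are labelled −1, never
dropped. The grouping tolerance and label order are this package's own
conventions.

**Attractor census** runs RSA from many initial conditions and groups
identical attractors. Attractor identity is canonical: states are level
tuples over species ids sorted lexicographically, and the cycle is
rotated so the smallest tuple comes first, so different entry phases of
one cycle compare equal. Initial conditions are sampled uniformly and
independently per species from [0, max_level] with a seeded numpy
generator; the seed is a required argument so census runs are
reproducible. Exhaustive enumeration is refused above a configurable
state-count cap (default 2^20) — for large networks (e.g. 139 Boolean
species, 2^139 states) sampling is the only option.

**Time-dependent regulated FBA** iterates per step of length dt:
concentrations → input levels via equivalences; one regulatory update;
instantaneous state → constraints (no averaging); uptake capped at
S/(X·dt) per metabolite so no pool can go negative; FBA maximising
biomass; then the batch-culture closed form X′ = X·e^(μ·dt),
S′ = max(0, S − v·X·(e^(μ·dt) − 1)/μ), switching to the linear form
below μ = 1e-9. An infeasible step is treated as starvation (μ = 0, no
exchange) and logged. Secretion (negative uptake) adds to the pool with
the same closed form, so secreted by-products can later act as
regulatory inputs. Expression delays are optional per-species
non-negative integers: a rule's changed outcome must persist for that
many consecutive steps before the species adopts it (delay 0 is plain
synchronous). This persistence semantics is this package's own
definition of delay-based asynchrony. Default dt = 0.1 h.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `default_bound` | 9999 | magnitude used where SBML omits bounds and when clipping ±inf intervals |
| feasibility tolerance | 1e-9 | bound-pair sanity checks |
| comparison tolerance | 1e-6 | FVA optimum slack, mass-balance residual, backend agreement |
| phase rounding | 6 decimals | shadow-price grouping |
| `dt` | 0.1 h | dynamic-FBA step |
| iteration cap | 1,000,000 | RSA safety cap; exceeding it is an internal error, never a truncation |
| `max-exhaustive` | 2^20 | census refusal threshold for exhaustive mode |

Solver: SciPy's HiGHS interface, with the dual-simplex (`simplex`) and
interior-point (`interior-point`) backends selectable; the test suite
requires them to agree to 1e-6. Alternate optima are genuinely
non-unique, so tests assert objective values, FVA ranges and phase
labels — never individual fluxes of degenerate optima.

## File formats and dialects

SBML-qual Level 3 (qual v1) is read and written; the supported MathML
subset in function terms is and/or/not plus the six relational operators
with one species and one integer constant per comparison — anything else
is rejected naming the construct. Equivalences live in the
qualitativeSpecies notes, one directive per line:
`STATE <int> : <[ ]or (> <real> , <real|+inf> <] [ or )>`, `#` comments;
both `]0, 8.8]` and `(0, 8.8]` open-bracket dialects are accepted, and
the exact grammar is this package's own (only the semantic contract —
level ↔ interval — is fixed by the method). If a quantitative value
falls on a boundary shared by two intervals through dialect mixing, the
lowest matching level wins. A species missing `maxLevel` gets the
largest level referenced by any rule or equivalence; a missing initial
level is an error (the constraint file is the sanctioned override path).

Metabolic SBML is read in two dialects: Level 3 + fbc v2 (bound
parameters, geneProductAssociation) and legacy Level 2 COBRA notes
(kinetic-law LOWER_BOUND/UPPER_BOUND, `GENE_ASSOCIATION:` note, boundary
metabolites by `boundaryCondition="true"` or the `_b` id suffix).
Reactions without bound annotations get (0, default) or
(−default, default) if reversible. An unparsable GPR is a warning, not
an error, and drops the GPR.

The constraint file is line-oriented: `obj : MAX(<linear expr>)` or
`MIN(...)`; `<id> <value>`; `<id> <lb> <ub>`; `#` comments. A single
value on a reaction fixes both bounds and *replaces* the SBML bounds
(the file is an explicit user override); on a regulatory component it is
an initial override; on an external metabolite it is a concentration in
mmol/l (also the initial pool for dynamic runs).

## Synthetic fixtures and what the tests show

The package bundles generators rather than data files. The lac-operon
pair is a minimal Boolean reconstruction of catabolite repression —
E = NOT glucose (EIIA signalling), I = NOT lactose (repressor),
P = B = E AND NOT I — wired to a 5-reaction toy model where both sugars
feed one carbon pool and biomass costs 2 carbon units (yield 0.5 gDW per
mmol, a round number so hand LP checks are exact). The maltose extension
makes glucose three-state with thresholds {0} / ]0, 0.6] / ]0.6, ∞[
mmol/l, the maltose operon inducible at levels ≤ 1 and the lactose
operon only at level 0. These rule sets are the package's own minimal
reconstructions consistent with the component roles and the 0.6 mM
repression threshold; they are not published networks. Random Boolean
network generation (seeded, n ≤ 16, ≤ k regulators per rule) and an
exhaustive brute-force attractor enumerator — an independent code path
from the sampling census — serve as oracles.

Consequently the tests demonstrate correctness of the *algorithms* (LP
optima against vertex enumeration, census against exhaustive
enumeration, averaging against direct arithmetic, mass balance,
determinism, diauxic ordering) at desk scale; they do not validate any
particular organism's regulatory network, and genome-scale models are
exercised only through the same code paths at toy size. Problem sizes
used throughout (≤ 10-species random networks for oracle equivalence,
10,000 sampled initial conditions for the census, 15 h trajectories at
dt = 0.05–0.1 h) were chosen as the smallest sizes at which each
property is informative.

## Known limitations

- No MILP-embedded regulation (SR-FBA style), no probabilistic
  constraints, no ODE coupling, no loopless/parsimonious FBA, no Pareto
  analysis.
- The LP flux vector at degenerate optima is backend-dependent; only
  objective-level quantities are stable.
- Shadow prices are finite differences at grid resolution: a phase
  boundary falling between grid points produces an intermediate slope at
  the straddling point.
- SBML coverage is the subset described above; groups/layout/annotations
  beyond GPR and bounds are ignored, and GINsim/BoolNet native formats
  are not read.
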