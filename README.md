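# qualflux

Constraint-based metabolic models (FBA) answer "how fast can this cell
grow on this medium?", but plain FBA is blind to gene regulation: offered
glucose and lactose together, it happily co-consumes both, although real
*E. coli* represses the lactose operon until glucose is gone. `qualflux`
couples the two network layers without kinetic parameters: it computes
the steady state of a **qualitative multi-state regulatory network**
(SBML-qual) by synchronous updating, translates the resulting qualitative
levels into **continuous flux intervals**, and applies those as
constraints to an FBA model (SBML), plus the usual derived analyses —
FVA, knockouts, phenotype phase planes, attractor censuses of large
networks, and a time-dependent regulated FBA for batch-culture dynamics.

It is aimed at systems biologists who have a logical model of regulation
(Boolean or multi-level) and a stoichiometric model of metabolism and
want to simulate them together.

## The method

**FBA.** Maximise (or minimise) a linear objective *c·v* subject to
steady-state mass balance *S·v = 0* over internal metabolites and bounds
*lb ≤ v ≤ ub* (fluxes in mmol/(gDW·h)). Solved with HiGHS via SciPy.

**Regulatory steady-state analysis (RSA).** Four steps:

1. *Initial state.* Each qualitative species starts at its declared
   level; the constraint file may override it, either with a level or
   with a quantitative value (e.g. a concentration in mmol/l) that is
   discretised through the species' declared state↔interval
   *equivalences* (`STATE 1 : ]0, +inf[` notes in the SBML-qual file).
2. *Attractor search.* All regulated species update synchronously by
   their logical rules. The update is deterministic over a finite state
   space, so the trajectory must revisit a state; the cycle between the
   two visits is the attractor — a *point* attractor (fixed point) or a
   *cyclic* one.
3. *Translation.* Each attractor level of a species with equivalences
   maps to its continuous interval.
4. *Averaging.* A cyclic attractor is summarised per species by
   [mean of lower bounds, mean of upper bounds] (or the arithmetic mean
   of levels when no equivalences exist), modelling an unsynchronised
   population spread over the cycle's phases.

**Coupling.** A steady-state constraint on a *reaction* intersects its
flux bounds; a *gene* at zero switches off every reaction whose GPR
(gene-protein-reaction boolean) then fails; an *external metabolite* at
zero caps the uptake direction of its exchange reaction at zero.

**Time-dependent regulated FBA.** For dynamics, the same translation is
applied per time step dt with no averaging: concentrations → input
levels → one regulatory update (optional per-species expression delays)
→ constraints → FBA maximising biomass → exponential update
X′ = X·e^(μ·dt), S′ = S − v·X·(e^(μ·dt) − 1)/μ.

## Worked example

The bundled lac-operon fixture (a 6-component Boolean network: glucose,
lactose, EIIA signalling E, repressor I, permease P, β-galactosidase B,
plus a 5-reaction toy metabolic model) reproduces catabolite repression
end to end:

```sh
$ qualflux fixtures --write demo
$ qualflux fba --sbml demo/lac_metabolic.xml --qual demo/lac_regulatory.xml \
               --cons demo/lac_constraints.txt
# objective: 5
#reaction	flux
R_BIOMASS	5
R_EX_glc	10
R_EX_lcts	0
R_GLC_CAT	10
R_LCTS_CAT	0
```

The constraint file puts both sugars in the medium (glucose 11.1 mmol/l,
lactose 5.6 mmol/l). The RSA lands in a point attractor with the operon
off, so lactose uptake is zero and growth (5, in the biomass reaction's
flux units) comes from glucose alone — the same objective as a
glucose-only medium. Dropping `--qual` (no regulation) yields
`# objective: 10`: the overestimate from co-consuming both sugars.
The steady state itself:

```sh
$ qualflux rsa --qual demo/lac_regulatory.xml --cons demo/lac_constraints.txt
# attractor: point, size 1
#component	kind	lower	upper
B	mean	0	0
E	mean	0	0
I	mean	0	0
M_glc_b	interval	0	+inf
M_lcts_b	interval	0	+inf
P	mean	0	0
```

B = P = 0 is the repressed operon; the sugar inputs carry their
translated intervals. Other subcommands: `multirsa` (attractor census,
`--n/--seed` sampling or `--exhaustive`), `randcond`, `fva`, `ko`,
`ppa`, and `tdfba` (which reproduces the diauxic shift: glucose is
exhausted before any lactose is consumed).

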