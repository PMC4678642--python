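"""Synthetic model generators and brute-force oracles.

The package is fully testable offline: these generators build a minimal
lac-operon regulatory network with a matching toy metabolic model, a
multi-state maltose extension, and seeded random Boolean networks, and
`brute_force_attractors` provides an attractor census oracle that shares
no code with the sampling path.

The lac pair encodes the textbook catabolite-repression logic:

    E = NOT (glucose >= 1)     EIIA signalling, active without glucose
    I = NOT (lactose >= 1)     lac repressor, bound in absence of inducer
    P = E AND NOT I            lactose permease
    B = E AND NOT I            beta-galactosidase

so glucose shuts the operon regardless of lactose, and lactose alone
switches it on.  The rules are this package's own minimal reconstruction
consistent with the component roles and known lac biology; they are not a
published network.  Metabolic yields are round numbers (0.5 gDW per mmol
carbon) so every hand LP check is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .metnet import MetabolicModel, Metabolite, Objective, Reaction, parse_gpr
from .qualio import (
    And,
    Cmp,
    Interval,
    Lit,
    LogicExpr,
    NetworkState,
    Not,
    Or,
    QualSpecies,
    RegulatoryNetwork,
    Transition,
    apply_transition,
)
from .rsa import Attractor

__all__ = [
    "ToyPair",
    "make_lac_operon",
    "make_maltose_extension",
    "make_random_boolean_network",
    "brute_force_attractors",
    "GLC",
    "LCTS",
    "MALT",
]

GLC = "M_glc_b"
LCTS = "M_lcts_b"
MALT = "M_malt_b"

BOOLEAN_EQ = {0: Interval(0, 0), 1: Interval(0, math.inf, lower_open=True)}


@dataclass
class ToyPair:
    """A regulatory network, a matching metabolic model, and the
    documented phenotype table (condition → expected steady levels)."""

    regulatory: RegulatoryNetwork
    metabolic: MetabolicModel
    phenotypes: Dict[str, Dict[str, int]] = field(default_factory=dict)


def _bool_species(sid: str, name: str = "", initial: int = 0, eqs=None) -> QualSpecies:
    return QualSpecies(id=sid, name=name, max_level=1, initial_level=initial,
                       equivalences=eqs)


def make_lac_operon() -> ToyPair:
    """Boolean lac-operon pair: catabolite repression plus induction.

    Metabolic side: both sugars import into a carbon pool feeding a
    biomass drain at yield 0.5 gDW per mmol carbon unit; the lactose
    route is gated by the permease (transport) and beta-galactosidase
    (catabolism) GPRs.
    """
    net = RegulatoryNetwork()
    net.add_species(_bool_species(GLC, "glucose", initial=0, eqs=dict(BOOLEAN_EQ)))
    net.add_species(_bool_species(LCTS, "lactose", initial=0, eqs=dict(BOOLEAN_EQ)))
    net.add_species(_bool_species("E", "EIIA (PTS) signalling"))
    net.add_species(_bool_species("I", "lac repressor", initial=1))
    net.add_species(_bool_species("P", "lactose permease"))
    net.add_species(_bool_species("B", "beta-galactosidase"))

    on = lambda sid: Cmp(sid, ">=", 1)
    net.add_transition(Transition("E", [(Not(on(GLC)), 1)], 0))
    net.add_transition(Transition("I", [(Not(on(LCTS)), 1)], 0))
    operon = And(on("E"), Not(on("I")))
    net.add_transition(Transition("P", [(operon, 1)], 0))
    net.add_transition(Transition("B", [(operon, 1)], 0))
    net.validate()

    model = MetabolicModel(id="toy_lac")
    model.add_metabolite(Metabolite(GLC, "glucose (external)", "e", is_external=True))
    model.add_metabolite(Metabolite(LCTS, "lactose (external)", "e", is_external=True))
    model.add_metabolite(Metabolite("M_glc_c", "glucose (cytosol)"))
    model.add_metabolite(Metabolite("M_lcts_c", "lactose (cytosol)"))
    model.add_metabolite(Metabolite("M_carbon", "carbon pool"))

    model.add_reaction(Reaction("R_EX_glc", {GLC: -1, "M_glc_c": 1}, 0, 10))
    model.add_reaction(
        Reaction("R_EX_lcts", {LCTS: -1, "M_lcts_c": 1}, 0, 10, gpr=parse_gpr("P"))
    )
    model.add_reaction(Reaction("R_GLC_CAT", {"M_glc_c": -1, "M_carbon": 1}, 0, 100))
    model.add_reaction(
        Reaction("R_LCTS_CAT", {"M_lcts_c": -1, "M_carbon": 1}, 0, 100,
                 gpr=parse_gpr("B"))
    )
    # biomass: 2 carbon units per unit growth → yield 0.5 gDW/mmol carbon
    model.add_metabolite(Metabolite("M_biomass_b", "biomass (drain)", "e", is_external=True))
    model.add_reaction(Reaction("R_BIOMASS", {"M_carbon": -2, "M_biomass_b": 1}, 0, 1000))
    model.objective = Objective({"R_BIOMASS": 1.0}, "MAX")
    model.validate()

    phen = {
        "glucose_only": {"E": 0, "I": 1, "P": 0, "B": 0},
        "lactose_only": {"E": 1, "I": 0, "P": 1, "B": 1},
        "both": {"E": 0, "I": 0, "P": 0, "B": 0},
        "neither": {"E": 1, "I": 1, "P": 0, "B": 0},
    }
    return ToyPair(net, model, phen)


def make_maltose_extension() -> ToyPair:
    """Multi-state extension: graded catabolite repression of maltose.

    Glucose becomes three-state with equivalences
    {0: [0,0], 1: ]0, 0.6], 2: ]0.6, +inf[} (mmol/l): the maltose operon
    is induced below the 0.6 mM repression threshold, the lactose operon
    only when glucose is fully absent.
    """
    pair = make_lac_operon()
    net = pair.regulatory
    model = pair.metabolic

    glc = net.species[GLC]
    glc.max_level = 2
    glc.equivalences = {
        0: Interval(0, 0),
        1: Interval(0, 0.6, lower_open=True),
        2: Interval(0.6, math.inf, lower_open=True),
    }

    net.add_species(_bool_species(MALT, "maltose", initial=0, eqs=dict(BOOLEAN_EQ)))
    net.add_species(_bool_species("MalT", "maltose operon activator"))
    net.add_species(_bool_species("Mal", "maltose system"))
    net.add_transition(Transition("MalT", [(Cmp(GLC, "<=", 1), 1)], 0))
    net.add_transition(
        Transition("Mal", [(And(Cmp("MalT", ">=", 1), Cmp(MALT, ">=", 1)), 1)], 0)
    )
    net.validate()

    model.add_metabolite(Metabolite(MALT, "maltose (external)", "e", is_external=True))
    model.add_metabolite(Metabolite("M_malt_c", "maltose (cytosol)"))
    model.add_reaction(
        Reaction("R_EX_malt", {MALT: -1, "M_malt_c": 1}, 0, 10, gpr=parse_gpr("Mal"))
    )
    model.add_reaction(Reaction("R_MALT_CAT", {"M_malt_c": -1, "M_carbon": 1}, 0, 100))
    model.validate()

    pair.phenotypes = {
        "glc_0": {GLC: 0, "B": 1, "Mal": 1},       # both secondary sugars usable
        "glc_0.3": {GLC: 1, "B": 0, "Mal": 1},     # maltose only
        "glc_22": {GLC: 2, "B": 0, "Mal": 0},      # full repression
    }
    return pair


def make_random_boolean_network(n: int, k: int, seed: int) -> RegulatoryNetwork:
    """A seeded random Boolean network: each species gets a random logic
    rule over at most ``k`` regulators (k = 0 gives a constant network)."""
    if not 1 <= n <= 16:
        raise ValueError("n must be in [1, 16]")
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    net = RegulatoryNetwork()
    for sid in ids:
        net.add_species(
            QualSpecies(sid, max_level=1, initial_level=int(rng.integers(0, 2)))
        )

    def random_expr(regs: List[str], depth: int) -> LogicExpr:
        if not regs or depth <= 0:
            choice = rng.integers(0, 3)
            if not regs or choice == 0:
                return Lit(bool(rng.integers(0, 2)))
            sid = regs[rng.integers(0, len(regs))]
            return Cmp(sid, ">=", 1)
        kind = rng.integers(0, 4)
        if kind == 0:
            return Not(random_expr(regs, depth - 1))
        if kind in (1, 2):
            op = And if kind == 1 else Or
            return op(random_expr(regs, depth - 1), random_expr(regs, depth - 1))
        sid = regs[rng.integers(0, len(regs))]
        return Cmp(sid, ">=", 1)

    for sid in ids:
        n_reg = int(rng.integers(0, k + 1))
        regs = list(rng.choice(ids, size=min(n_reg, n), replace=False)) if n_reg else []
        expr = random_expr([str(r) for r in regs], depth=2)
        net.add_transition(Transition(sid, [(expr, 1)], 0))
    net.validate()
    return net


def brute_force_attractors(net: RegulatoryNetwork) -> Dict[Attractor, int]:
    """Exhaustive attractor census: every initial state, explicit trajectory
    hashing, independent of the sampling code path.

    Returns canonical attractors with their basin sizes; basins sum to the
    full state-space size.
    """
    if net.n_states() > 2 ** 16:
        raise ValueError(
            f"state space of {net.n_states()} states is too large to enumerate"
        )
    ids = sorted(net.species)
    ranges = [range(net.species[i].max_level + 1) for i in ids]
    rules = [(i, net.transitions[sid]) for i, sid in enumerate(ids) if sid in net.transitions]

    def succ(key: Tuple[int, ...]) -> Tuple[int, ...]:
        state = dict(zip(ids, key))
        out = list(key)
        for i, t in rules:
            out[i] = apply_transition(t, state)
        return tuple(out)

    import itertools

    basins: Dict[Attractor, int] = {}
    attractor_of: Dict[Tuple[int, ...], Attractor] = {}
    for key in itertools.product(*ranges):
        path: List[Tuple[int, ...]] = []
        seen_at: Dict[Tuple[int, ...], int] = {}
        cur = key
        while cur not in attractor_of and cur not in seen_at:
            seen_at[cur] = len(path)
            path.append(cur)
            cur = succ(cur)
        if cur in attractor_of:
            att = attractor_of[cur]
        else:
            cycle = path[seen_at[cur]:]
            att = Attractor.from_cycle([dict(zip(ids, s)) for s in cycle])
        for visited in path:
            attractor_of[visited] = att
        basins[att] = basins.get(att, 0) + 1
    return basins
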