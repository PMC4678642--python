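"""Regulatory steady-state analysis (RSA).

Four steps: (1) build the initial network state, overriding declared
initial levels with values from a constraint file — quantitative values
are discretised through the species' state/interval equivalences;
(2) iterate the synchronous update until a previously seen state recurs,
which closes an attractor (a fixed point or a cycle); (3) translate each
attractor level into its continuous interval where equivalences exist;
(4) for cyclic attractors, average the interval bounds (or the raw levels
for species without equivalences) into a single steady-state constraint
per component.  The averaged constraint models an unsynchronised
population in which every phase of the cycle is equally represented.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np

from .qualio import (
    Interval,
    NetworkState,
    QualModelError,
    RegulatoryNetwork,
    apply_transition,
)

__all__ = [
    "Attractor",
    "SteadyState",
    "InitialOverrides",
    "build_initial_state",
    "synchronous_step",
    "find_attractor",
    "attractor_to_steady_state",
    "run_rsa",
    "random_initial_states",
    "multi_rsa_census",
    "all_states",
]

#: per-component steady-state constraint: an interval (species with
#: equivalences) or a real qualitative mean (species without)
SteadyState = Dict[str, Union[Interval, float]]

#: constraint-file overrides: quantitative value (float) or level (int)
InitialOverrides = Mapping[str, Union[int, float]]


@dataclass(frozen=True)
class Attractor:
    """A canonicalised synchronous attractor.

    ``states[i+1]`` is the synchronous successor of ``states[i]`` (and
    ``states[0]`` of ``states[-1]``).  States are level tuples over
    ``species_ids`` sorted lexicographically by id; the cycle is rotated
    so the smallest state tuple comes first, which makes equality
    phase-independent.
    """

    species_ids: Tuple[str, ...]
    states: Tuple[Tuple[int, ...], ...]

    @property
    def kind(self) -> str:
        return "point" if len(self.states) == 1 else "cyclic"

    def __len__(self) -> int:
        return len(self.states)

    def state_dicts(self) -> List[NetworkState]:
        return [dict(zip(self.species_ids, s)) for s in self.states]

    @staticmethod
    def from_cycle(states: Sequence[NetworkState]) -> "Attractor":
        if not states:
            raise QualModelError("an attractor needs at least one state")
        ids = tuple(sorted(states[0]))
        tuples = [tuple(s[i] for i in ids) for s in states]
        pivot = min(range(len(tuples)), key=lambda k: tuples[k])
        rotated = tuple(tuples[pivot:] + tuples[:pivot])
        return Attractor(ids, rotated)


def build_initial_state(
    net: RegulatoryNetwork, overrides: InitialOverrides | None = None
) -> NetworkState:
    """Initial state: declared levels, overridden by constraint-file values.

    Integer overrides are taken as qualitative levels; float overrides are
    quantitative (a concentration or flux) and are translated through the
    species' equivalences to the level whose interval contains the value.
    """
    state = net.initial_state()
    for sid, value in (overrides or {}).items():
        if sid not in net.species:
            raise QualModelError(f"override for unknown species {sid!r}")
        sp = net.species[sid]
        if isinstance(value, bool) or isinstance(value, (int, np.integer)):
            level = int(value)
            if not 0 <= level <= sp.max_level:
                raise QualModelError(
                    f"override level {level} for {sid!r} outside [0, {sp.max_level}]"
                )
        else:
            level = sp.level_for_value(float(value))
        state[sid] = level
    return state


def synchronous_step(net: RegulatoryNetwork, state: NetworkState) -> NetworkState:
    """All regulated species update simultaneously from the previous state."""
    nxt = dict(state)
    for sid, t in net.transitions.items():
        nxt[sid] = apply_transition(t, state)
    return nxt


def find_attractor(
    net: RegulatoryNetwork,
    initial: NetworkState,
    max_iter: int = 1_000_000,
) -> Attractor:
    """Follow the synchronous trajectory until a state repeats.

    The synchronous update is deterministic and the state space finite, so
    a repeat is guaranteed within ∏(max_level+1)+1 steps; the configurable
    cap exists only to surface implementation bugs.
    """
    ids = tuple(sorted(net.species))
    seen: Dict[Tuple[int, ...], int] = {}
    trajectory: List[NetworkState] = []
    state = dict(initial)
    for _ in range(max_iter + 1):
        key = tuple(state[i] for i in ids)
        if key in seen:
            cycle = trajectory[seen[key]:]
            return Attractor.from_cycle(cycle)
        seen[key] = len(trajectory)
        trajectory.append(state)
        state = synchronous_step(net, state)
    raise RuntimeError(
        f"no attractor within {max_iter} iterations — internal error"
    )


def attractor_to_steady_state(
    net: RegulatoryNetwork, att: Attractor
) -> SteadyState:
    """One constraint per component: averaged interval or qualitative mean.

    Species with equivalences get the interval
    [mean of member lower bounds, mean of member upper bounds]; an
    unbounded member makes the mean upper bound +inf.  Species without
    equivalences get the arithmetic mean of their attractor levels.  For a
    point attractor both rules degenerate to the single translated
    interval or level.
    """
    ss: SteadyState = {}
    n = len(att.states)
    for j, sid in enumerate(att.species_ids):
        sp = net.species[sid]
        levels = [s[j] for s in att.states]
        if sp.equivalences is not None:
            ivs = [sp.equivalences[lv] for lv in levels]
            if n == 1:
                ss[sid] = ivs[0]
            else:
                lo = sum(iv.lower for iv in ivs) / n
                hi = (
                    math.inf
                    if any(math.isinf(iv.upper) for iv in ivs)
                    else sum(iv.upper for iv in ivs) / n
                )
                ss[sid] = Interval(lo, hi)
        else:
            ss[sid] = float(sum(levels)) / n
    return ss


def run_rsa(
    net: RegulatoryNetwork,
    overrides: InitialOverrides | None = None,
    max_iter: int = 1_000_000,
) -> Tuple[Attractor, SteadyState]:
    """The full pipeline: initial state → attractor → steady-state constraints."""
    initial = build_initial_state(net, overrides)
    att = find_attractor(net, initial, max_iter=max_iter)
    return att, attractor_to_steady_state(net, att)


def random_initial_states(
    net: RegulatoryNetwork, n: int, seed: int
) -> List[NetworkState]:
    """``n`` states with each level drawn uniformly from [0, max_level]."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    ids = sorted(net.species)
    maxes = np.array([net.species[i].max_level for i in ids], dtype=np.int64)
    out: List[NetworkState] = []
    for _ in range(n):
        if ids:
            draws = rng.integers(0, maxes + 1)
            out.append({i: int(v) for i, v in zip(ids, draws)})
        else:
            out.append({})
    return out


def all_states(net: RegulatoryNetwork) -> Iterable[NetworkState]:
    """Every network state, in lexicographic order over sorted species ids."""
    ids = sorted(net.species)
    ranges = [range(net.species[i].max_level + 1) for i in ids]
    for combo in itertools.product(*ranges):
        yield dict(zip(ids, combo))


def multi_rsa_census(
    net: RegulatoryNetwork, initials: Iterable[NetworkState]
) -> Dict[Attractor, int]:
    """Group attractors reached from many initial states and count them.

    Canonicalisation makes different entry phases of one cycle count as a
    single attractor.
    """
    census: Dict[Attractor, int] = {}
    for state in initials:
        att = find_attractor(net, state)
        census[att] = census.get(att, 0) + 1
    return census
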