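"""Time-dependent regulated FBA: batch-culture dynamics with a logical
regulatory layer.

Each step of length ``dt`` (hours): external concentrations are
discretised into qualitative input levels through the species'
equivalences; the regulatory state advances by one update (optionally
delayed per species — a change of rule outcome must persist for the
species' delay count of steps before it takes effect; delay 0 is plain
synchronous); the instantaneous regulatory state is translated into flux
constraints exactly as for a steady state (no averaging); uptake is
capped so no concentration can go negative; the FBA maximises biomass;
and cell density X (g/l) and concentrations S (mmol/l) integrate
exponential growth within the step:

    X' = X·e^(μ·dt),     S_i' = S_i − v_i·X·(e^(μ·dt) − 1)/μ

with the linear limit for μ → 0.  An infeasible FBA step means
starvation: μ = 0 and all exchange fluxes 0 for that step.  The whole
loop is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .fba import ConstrainedModel, apply_bound_overrides, apply_steady_state, solve_fba
from .metnet import MetabolicModel, ModelError, Objective, find_exchange_reactions
from .qualio import NetworkState, RegulatoryNetwork, apply_transition
from .rsa import SteadyState, build_initial_state

__all__ = ["DynamicsState", "Trajectory", "uptake_caps", "step_dynamics", "time_dependent_fba"]

log = logging.getLogger(__name__)

MU_EPS = 1e-9


@dataclass
class DynamicsState:
    t: float                      # h
    X: float                      # cell density, g/l
    S: Dict[str, float]           # external concentrations, mmol/l
    reg_state: NetworkState
    mu: float = 0.0               # growth rate of the last FBA, 1/h

    def __post_init__(self) -> None:
        assert self.X >= 0
        assert all(v >= -1e-12 for v in self.S.values())


@dataclass
class Trajectory:
    states: List[DynamicsState] = field(default_factory=list)
    fluxes: List[Dict[str, float]] = field(default_factory=list)

    def column(self, metabolite: str) -> List[float]:
        return [st.S.get(metabolite, 0.0) for st in self.states]

    @property
    def times(self) -> List[float]:
        return [st.t for st in self.states]

    @property
    def densities(self) -> List[float]:
        return [st.X for st in self.states]


def uptake_caps(
    S: Mapping[str, float], X: float, dt: float
) -> Dict[str, float]:
    """Maximum uptake flux per metabolite so the pool cannot go negative.

    A pool of S mmol/l consumed at flux v mmol/(gDW·h) by X g/l of cells
    for dt h removes ≈ v·X·dt mmol/l, so the cap is S/(X·dt).
    """
    if X <= 0 or dt <= 0:
        raise ValueError("uptake caps need X > 0 and dt > 0")
    return {mid: conc / (X * dt) for mid, conc in S.items()}


def step_dynamics(
    state: DynamicsState,
    fluxes: Mapping[str, float],
    mu: float,
    dt: float,
    uptake_of: Mapping[str, Tuple[str, int]],
) -> DynamicsState:
    """Integrate one step of exponential growth and substrate exchange.

    ``uptake_of`` maps each tracked metabolite to its exchange reaction
    and uptake sign; net uptake v_i > 0 consumes the pool, v_i < 0
    (secretion) feeds it.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if mu > MU_EPS:
        growth = math.exp(mu * dt)
        biomass_integral = state.X * (growth - 1.0) / mu
    else:
        growth = 1.0 + max(mu, 0.0) * dt
        biomass_integral = state.X * dt
    new_X = state.X * growth
    new_S: Dict[str, float] = {}
    for mid, conc in state.S.items():
        v = 0.0
        if mid in uptake_of:
            rid, direction = uptake_of[mid]
            v = direction * fluxes.get(rid, 0.0)  # positive = uptake
        updated = conc - v * biomass_integral
        if updated < 0:
            log.debug("clamping %s at 0 (was %.3g)", mid, updated)
            updated = 0.0
        new_S[mid] = updated
    return DynamicsState(
        t=state.t + dt, X=new_X, S=new_S, reg_state=dict(state.reg_state), mu=mu
    )


def _delayed_update(
    net: RegulatoryNetwork,
    state: NetworkState,
    delays: Mapping[str, int],
    pending: Dict[str, Tuple[int, int]],
) -> NetworkState:
    """One regulatory update honouring per-species persistence delays.

    ``pending[sid] = (proposed_level, age)``: the rule outcome must stay
    identical for ``delays[sid]`` consecutive steps before it is adopted.
    """
    nxt = dict(state)
    for sid, t in net.transitions.items():
        proposed = apply_transition(t, state)
        delay = delays.get(sid, 0)
        if delay <= 0:
            nxt[sid] = proposed
            pending.pop(sid, None)
            continue
        if proposed == state[sid]:
            pending.pop(sid, None)
            continue
        prev_level, age = pending.get(sid, (None, 0))
        age = age + 1 if prev_level == proposed else 1
        if age >= delay:
            nxt[sid] = proposed
            pending.pop(sid, None)
        else:
            pending[sid] = (proposed, age)
    return nxt


def time_dependent_fba(
    model: MetabolicModel,
    net: Optional[RegulatoryNetwork],
    S0: Mapping[str, float],
    X0: float,
    biomass_id: str,
    dt: float = 0.1,
    t_end: float = 10.0,
    delays: Optional[Mapping[str, int]] = None,
    solver: str = "auto",
    bound_overrides: Optional[Mapping[str, Tuple[float, float]]] = None,
    reg_overrides: Optional[Mapping[str, float]] = None,
) -> Trajectory:
    """Simulate batch growth under regulatory control.

    ``S0`` holds initial external concentrations (mmol/l), ``X0`` the
    initial cell density (g/l); biomass is maximised each step.
    """
    if biomass_id not in model.reactions:
        raise ModelError(f"biomass reaction {biomass_id!r} not in model")
    if dt <= 0:
        raise ValueError("dt must be positive")
    delays = delays or {}
    exchanges = find_exchange_reactions(model)
    uptake_of = {m: exchanges[m] for m in S0 if m in exchanges}
    objective = Objective({biomass_id: 1.0}, "MAX")

    if net is not None:
        reg_state = build_initial_state(net, dict(reg_overrides or {}))
    else:
        reg_state = {}
    pending: Dict[str, Tuple[int, int]] = {}

    traj = Trajectory()
    state = DynamicsState(t=0.0, X=float(X0), S=dict(S0), reg_state=reg_state, mu=0.0)
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        # 1) concentrations → qualitative input levels
        if net is not None:
            for mid, conc in state.S.items():
                if mid in net.species and net.species[mid].equivalences is not None:
                    state.reg_state[mid] = net.species[mid].level_for_value(conc)
            # 2) one (possibly delayed) regulatory update
            state.reg_state = _delayed_update(net, state.reg_state, delays, pending)
            # 3) instantaneous state → constraints, no averaging
            ss: SteadyState = {}
            for sid, level in state.reg_state.items():
                sp = net.species[sid]
                if sp.equivalences is not None:
                    ss[sid] = sp.equivalences[level]
                else:
                    ss[sid] = float(level)
            cm = apply_steady_state(model, ss, net)
        else:
            cm = apply_steady_state(model, {}, None)
        if bound_overrides:
            cm = apply_bound_overrides(cm, bound_overrides)
        cm.objective = objective

        # 4) cap uptake so pools stay non-negative
        caps = uptake_caps(state.S, state.X, dt) if state.X > 0 else {}
        for mid, cap in caps.items():
            if mid not in uptake_of:
                continue
            rid, direction = uptake_of[mid]
            lb, ub = cm.effective_bounds[rid]
            if direction > 0:
                cm.effective_bounds[rid] = (lb, min(ub, cap))
            else:
                cm.effective_bounds[rid] = (max(lb, -cap), ub)

        # 5) FBA
        result = solve_fba(cm, solver=solver)
        if result.optimal:
            mu = result.objective_value
            fluxes = result.fluxes
        else:
            log.debug("t=%.3f: FBA %s — starvation step", state.t, result.status)
            mu = 0.0
            fluxes = {}

        traj.states.append(state)
        traj.fluxes.append(fluxes)

        # 6) integrate
        state = step_dynamics(state, fluxes, mu, dt, uptake_of)

    traj.states.append(state)
    traj.fluxes.append({})
    return traj
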