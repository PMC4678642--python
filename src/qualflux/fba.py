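"""Flux balance analysis constrained by regulatory steady states.

The LP is the standard FBA problem: optimise a linear objective c·v
subject to steady-state mass balance S·v = 0 over internal metabolites
and per-reaction flux bounds.  Regulatory steady-state constraints enter
in three ways:

* a constraint on a *reaction* id intersects the reaction's bounds with
  the steady-state interval (an unbounded end defers to the model bound);
* a *gene* at zero switches off every reaction whose GPR then evaluates
  false (bounds pinned to zero);
* an *external metabolite* at zero caps the uptake direction of its
  exchange reaction at zero — secretion is unaffected.

Solving goes through scipy's HiGHS interface; both the dual-simplex and
the interior-point backends are exposed and must agree to 1e-6 on the
test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import linprog

from .metnet import (
    MetabolicModel,
    ModelError,
    Objective,
    evaluate_gpr,
    find_exchange_reactions,
)
from .qualio import Interval, RegulatoryNetwork, expr_species
from .rsa import InitialOverrides, SteadyState, run_rsa

__all__ = [
    "FBAResult",
    "ConstrainedModel",
    "InfeasibleBoundError",
    "apply_steady_state",
    "apply_bound_overrides",
    "solve_fba",
    "flux_variability",
    "knockout_scan",
    "phenotype_phases",
    "SOLVERS",
]

log = logging.getLogger(__name__)

#: selectable LP backends (scipy method names)
SOLVERS = {"simplex": "highs-ds", "interior-point": "highs-ipm", "auto": "highs"}

FEAS_TOL = 1e-9
CMP_TOL = 1e-6


class InfeasibleBoundError(ModelError):
    """A steady-state interval is disjoint from the model bounds."""


@dataclass
class FBAResult:
    status: str  # optimal | infeasible | unbounded | error
    objective_value: float
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class ConstrainedModel:
    """A metabolic model plus effective bounds after all constraints."""

    base: MetabolicModel
    effective_bounds: Dict[str, Tuple[float, float]]
    objective: Optional[Objective] = None

    def __post_init__(self) -> None:
        if self.objective is None:
            self.objective = self.base.objective

    def copy(self) -> "ConstrainedModel":
        return ConstrainedModel(
            self.base, dict(self.effective_bounds), self.objective
        )


def constrain(model: MetabolicModel, objective: Optional[Objective] = None) -> ConstrainedModel:
    """Wrap a model with its own bounds as the effective bounds."""
    return ConstrainedModel(
        model,
        {r.id: (r.lower_bound, r.upper_bound) for r in model.reactions.values()},
        objective or model.objective,
    )


def apply_bound_overrides(
    cm: ConstrainedModel, bounds: Mapping[str, Tuple[float, float]]
) -> ConstrainedModel:
    """Replace effective bounds for the given reactions (user overrides)."""
    out = cm.copy()
    for rid, (lb, ub) in bounds.items():
        if rid not in out.effective_bounds:
            raise ModelError(f"bound override for unknown reaction {rid!r}")
        if lb > ub:
            raise ModelError(f"override for {rid!r}: lb {lb} > ub {ub}")
        out.effective_bounds[rid] = (lb, ub)
    return out


def _is_zero_constraint(value: Union[Interval, float]) -> bool:
    if isinstance(value, Interval):
        return value.lower == 0 and value.upper == 0
    return value == 0


def apply_steady_state(
    model: Union[MetabolicModel, ConstrainedModel],
    ss: SteadyState,
    net: Optional[RegulatoryNetwork] = None,
    forced_zero_genes: Iterable[str] = (),
) -> ConstrainedModel:
    """Translate RSA steady-state constraints into effective flux bounds.

    Ids resolve to reactions, genes (GPR members), or external
    metabolites; anything else is ignored with a debug log (regulatory
    intermediates like transcription factors legitimately match nothing).
    Idempotent: applying the same steady state twice changes nothing.
    """
    cm = model.copy() if isinstance(model, ConstrainedModel) else constrain(model)
    base = cm.base
    gene_ids = base.genes()
    exchanges = find_exchange_reactions(base)

    gene_states: Dict[str, float] = {g: 0.0 for g in forced_zero_genes}

    for cid, value in ss.items():
        if cid in base.reactions:
            lb, ub = cm.effective_bounds[cid]
            if isinstance(value, Interval):
                new_lb = max(lb, value.lower) if not math.isinf(value.lower) else lb
                new_ub = min(ub, value.upper) if not math.isinf(value.upper) else ub
            else:
                new_lb = max(lb, value)
                new_ub = min(ub, value)
            if new_lb > new_ub + FEAS_TOL:
                raise InfeasibleBoundError(
                    f"steady-state constraint {value} on reaction {cid!r} is "
                    f"disjoint from bounds ({lb}, {ub})"
                )
            cm.effective_bounds[cid] = (new_lb, min(new_ub, max(new_lb, new_ub)))
        elif cid in gene_ids:
            if cid not in gene_states:
                gene_states[cid] = 0.0 if _is_zero_constraint(value) else 1.0
        elif cid in base.metabolites and base.metabolites[cid].is_external:
            if _is_zero_constraint(value) and cid in exchanges:
                rid, direction = exchanges[cid]
                lb, ub = cm.effective_bounds[rid]
                if direction > 0:
                    cm.effective_bounds[rid] = (lb, min(ub, 0.0))
                else:
                    cm.effective_bounds[rid] = (max(lb, 0.0), ub)
        else:
            log.debug("steady-state id %r resolves to no model entity", cid)

    for r in base.reactions.values():
        if r.gpr is None:
            continue
        if expr_species(r.gpr) & set(gene_states):
            if not evaluate_gpr(r.gpr, gene_states):
                cm.effective_bounds[r.id] = (0.0, 0.0)
    return cm


# --------------------------------------------------------------------------
# The LP


class _LP:
    """Assembled mass-balance LP, reusable across FVA/scan solves."""

    def __init__(self, cm: ConstrainedModel):
        base = cm.base
        self.rids: List[str] = sorted(base.reactions)
        self.ridx = {r: i for i, r in enumerate(self.rids)}
        internal = [
            m for m in sorted(base.metabolites) if not base.metabolites[m].is_external
        ]
        midx = {m: i for i, m in enumerate(internal)}
        S = np.zeros((len(internal), len(self.rids)))
        for rid, r in base.reactions.items():
            j = self.ridx[rid]
            for mid, coeff in r.stoichiometry.items():
                if mid in midx:
                    S[midx[mid], j] = coeff
        self.S = S
        self.internal = internal
        self.bounds = [cm.effective_bounds[r] for r in self.rids]

    def cost(self, coeffs: Mapping[str, float]) -> np.ndarray:
        c = np.zeros(len(self.rids))
        for rid, w in coeffs.items():
            if rid not in self.ridx:
                raise ModelError(f"objective references unknown reaction {rid!r}")
            c[self.ridx[rid]] = w
        return c

    def solve(
        self,
        coeffs: Mapping[str, float],
        sense: str,
        solver: str = "auto",
        extra_ub: Optional[Tuple[np.ndarray, float]] = None,
        bounds: Optional[Sequence[Tuple[float, float]]] = None,
    ):
        c = self.cost(coeffs)
        sign = -1.0 if sense == "MAX" else 1.0
        A_ub = b_ub = None
        if extra_ub is not None:
            A_ub = extra_ub[0][None, :]
            b_ub = [extra_ub[1]]
        res = linprog(
            sign * c,
            A_eq=self.S if self.S.size else None,
            b_eq=np.zeros(self.S.shape[0]) if self.S.size else None,
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=list(bounds if bounds is not None else self.bounds),
            method=SOLVERS.get(solver, solver),
        )
        return res, sign


_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


def solve_fba(
    cm: ConstrainedModel,
    solver: str = "auto",
    objective: Optional[Objective] = None,
) -> FBAResult:
    """Optimise the objective under mass balance and effective bounds."""
    obj = objective or cm.objective
    if obj is None:
        raise ModelError("no objective defined")
    for rid, (lb, ub) in cm.effective_bounds.items():
        if lb > ub + FEAS_TOL:
            return FBAResult("infeasible", math.nan)
    lp = _LP(cm)
    res, sign = lp.solve(obj.coeffs, obj.sense, solver=solver)
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FBAResult(status, math.nan)
    fluxes = {rid: float(res.x[lp.ridx[rid]]) for rid in lp.rids}
    value = float(-res.fun) if obj.sense == "MAX" else float(res.fun)
    return FBAResult("optimal", value, fluxes)


def flux_variability(
    cm: ConstrainedModel,
    targets: Optional[Iterable[str]] = None,
    gamma: float = 1.0,
    solver: str = "auto",
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction flux ranges with the objective held at γ × optimum.

    The optimum is fixed as an inequality (objective ≥ (γ − 1e-6)·opt for
    maximisation) for numerical robustness; each target is then
    consecutively minimised and maximised over the same assembled LP.
    """
    if not 0 < gamma <= 1:
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    obj = cm.objective
    if obj is None:
        raise ModelError("no objective defined")
    base_res = solve_fba(cm, solver=solver)
    if not base_res.optimal:
        raise ModelError(f"FVA base problem is {base_res.status}")
    opt = base_res.objective_value

    lp = _LP(cm)
    c = lp.cost(obj.coeffs)
    slack = CMP_TOL * max(1.0, abs(opt))
    if obj.sense == "MAX":
        threshold = opt - (1.0 - gamma) * abs(opt) - slack
        extra = (-c, -threshold)  # c·v >= threshold
    else:
        threshold = opt + (1.0 - gamma) * abs(opt) + slack
        extra = (c, threshold)  # c·v <= threshold

    tids = list(targets) if targets is not None else list(lp.rids)
    out: Dict[str, Tuple[float, float]] = {}
    for rid in tids:
        if rid not in lp.ridx:
            raise ModelError(f"FVA target {rid!r} is not a reaction")
        lo_res, _ = lp.solve({rid: 1.0}, "MIN", solver=solver, extra_ub=extra)
        hi_res, _ = lp.solve({rid: 1.0}, "MAX", solver=solver, extra_ub=extra)
        if lo_res.status != 0 or hi_res.status != 0:
            raise ModelError(f"FVA subproblem for {rid!r} failed")
        out[rid] = (float(lo_res.fun), float(-hi_res.fun))
    return out


# --------------------------------------------------------------------------
# Knockouts


def _freeze_component(net: RegulatoryNetwork, sid: str) -> RegulatoryNetwork:
    """Copy of the network with ``sid`` pinned to level 0 (rule removed)."""
    frozen = RegulatoryNetwork(dict(net.species), dict(net.transitions))
    frozen.transitions = {k: v for k, v in net.transitions.items() if k != sid}
    return frozen


def knockout_scan(
    model: MetabolicModel,
    net: Optional[RegulatoryNetwork],
    ids: Iterable[str],
    overrides: Optional[InitialOverrides] = None,
    solver: str = "auto",
    bound_overrides: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> Dict[str, FBAResult]:
    """Clamp each id to zero in turn, rerun RSA (if a network is given),
    reapply the steady-state constraints, and solve the FBA.

    Reactions get bounds (0,0); regulatory components are frozen at level
    0 throughout the RSA (their rule suspended); bare genes force their
    GPRs to evaluate with that gene off; external metabolites get their
    uptake capped at zero.
    """
    overrides = dict(overrides or {})
    results: Dict[str, FBAResult] = {}
    gene_ids = model.genes()
    exchanges = find_exchange_reactions(model)

    for kid in ids:
        ko_net = net
        ko_overrides = dict(overrides)
        forced_genes: Tuple[str, ...] = ()
        known = False

        if net is not None and kid in net.species:
            ko_net = _freeze_component(net, kid)
            ko_overrides[kid] = 0
            known = True
        if kid in gene_ids and not known:
            forced_genes = (kid,)
            known = True

        if ko_net is not None:
            _, ss = run_rsa(ko_net, ko_overrides)
        else:
            ss = {}
        cm = apply_steady_state(model, ss, ko_net, forced_zero_genes=forced_genes)
        if bound_overrides:
            cm = apply_bound_overrides(cm, bound_overrides)

        if kid in model.reactions:
            cm.effective_bounds[kid] = (0.0, 0.0)
            known = True
        elif kid in model.metabolites:
            if kid in exchanges:
                rid, direction = exchanges[kid]
                lb, ub = cm.effective_bounds[rid]
                cm.effective_bounds[rid] = (
                    (lb, min(ub, 0.0)) if direction > 0 else (max(lb, 0.0), ub)
                )
            known = True

        if not known:
            raise ModelError(f"knockout id {kid!r} matches no component")
        results[kid] = solve_fba(cm, solver=solver)
    return results


# --------------------------------------------------------------------------
# Phenotypic phase analysis


@dataclass
class PhasePoint:
    coords: Tuple[float, ...]
    objective_value: float
    shadow_price: Tuple[float, ...]
    phase: int  # -1 marks infeasible points


def phenotype_phases(
    cm: ConstrainedModel,
    axes: Sequence[str],
    ranges: Sequence[Tuple[float, float]],
    steps: int = 10,
    solver: str = "auto",
) -> List[PhasePoint]:
    """Scan one or two reaction fluxes and group grid points into phases.

    At each grid point the axis fluxes are fixed and the objective
    optimised.  The shadow price along each axis is the forward finite
    difference of the objective over one grid step (backward at the far
    edge).  Points whose shadow-price vectors agree after rounding to six
    decimals share a phase; labels are consecutive integers in scan
    order.  Infeasible points get phase -1.
    """
    if len(axes) not in (1, 2):
        raise ValueError("phenotype phase analysis supports 1 or 2 axes")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    obj = cm.objective
    if obj is None:
        raise ModelError("no objective defined")
    grids = [np.linspace(lo, hi, steps) for lo, hi in ranges]
    deltas = [g[1] - g[0] for g in grids]
    shape = tuple(steps for _ in axes)

    objective = np.full(shape, np.nan)
    lp = _LP(cm)
    for index in np.ndindex(*shape):
        bounds = list(lp.bounds)
        for a, (axis, i) in enumerate(zip(axes, index)):
            v = float(grids[a][i])
            bounds[lp.ridx[axis]] = (v, v)
        res, _ = lp.solve(obj.coeffs, obj.sense, solver=solver, bounds=bounds)
        if res.status == 0:
            objective[index] = float(-res.fun) if obj.sense == "MAX" else float(res.fun)

    def shadow(index) -> Tuple[float, ...]:
        sp = []
        for a in range(len(axes)):
            idx_f = list(index)
            if index[a] + 1 < steps:
                idx_f[a] += 1
                diff = objective[tuple(idx_f)] - objective[index]
            else:
                idx_f[a] -= 1
                diff = objective[index] - objective[tuple(idx_f)]
            sp.append(diff / deltas[a] if deltas[a] != 0 else 0.0)
        return tuple(sp)

    points: List[PhasePoint] = []
    labels: Dict[Tuple[float, ...], int] = {}
    for index in np.ndindex(*shape):
        coords = tuple(float(grids[a][i]) for a, i in enumerate(index))
        if math.isnan(objective[index]):
            points.append(PhasePoint(coords, math.nan, (math.nan,) * len(axes), -1))
            continue
        sp = shadow(index)
        if any(math.isnan(s) for s in sp):
            # neighbour infeasible: the point sits on a feasibility edge
            key = ("edge",)
        else:
            key = tuple(round(s, 6) for s in sp)
        if key not in labels:
            labels[key] = len(labels)
        points.append(PhasePoint(coords, float(objective[index]), sp, labels[key]))
    return points
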