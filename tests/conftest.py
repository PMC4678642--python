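"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from typing import Dict, List, Tuple

import numpy as np
import pytest

from qualflux.fixtures import make_lac_operon, make_maltose_extension
from qualflux.metnet import MetabolicModel


@pytest.fixture
def lac_pair():
    return make_lac_operon()


@pytest.fixture
def maltose_pair():
    return make_maltose_extension()


# --------------------------------------------------------------------------
# Independent LP oracle: exhaustive vertex enumeration of the flux polytope


def enumerate_vertices(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, tol: float = 1e-9
) -> List[np.ndarray]:
    """All vertices of {v : S v = 0, lb <= v <= ub} by basis enumeration.

    A vertex pins n - rank(S) coordinates at a bound and solves the
    equality system for the rest.  Exponential; only for tiny models.
    """
    n = S.shape[1] if S.size else len(lb)
    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    verts: List[np.ndarray] = []
    for free in itertools.combinations(range(n), r):
        fixed = [i for i in range(n) if i not in free]
        A = S[:, list(free)] if S.size else np.zeros((0, 0))
        if r and np.linalg.matrix_rank(A) < r:
            continue
        for vals in itertools.product(*[(lb[i], ub[i]) for i in fixed]):
            v = np.empty(n)
            for i, val in zip(fixed, vals):
                v[i] = val
            if r:
                b = -S[:, fixed] @ np.asarray(vals) if fixed else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[list(free)] = sol
            if S.size and np.max(np.abs(S @ v)) > 1e-6:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                verts.append(v)
    return verts


def oracle_optimum(model: MetabolicModel, bounds=None) -> float:
    """Optimal objective by vertex enumeration (bounded polytopes only)."""
    rids = sorted(model.reactions)
    internal = [m for m in sorted(model.metabolites)
                if not model.metabolites[m].is_external]
    midx = {m: i for i, m in enumerate(internal)}
    S = np.zeros((len(internal), len(rids)))
    for j, rid in enumerate(rids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            if mid in midx:
                S[midx[mid], j] = coeff
    eff = bounds or {
        rid: (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
        for rid in rids
    }
    lb = np.array([eff[r][0] for r in rids])
    ub = np.array([eff[r][1] for r in rids])
    c = np.zeros(len(rids))
    for rid, w in model.objective.coeffs.items():
        c[rids.index(rid)] = w
    verts = enumerate_vertices(S, lb, ub)
    assert verts, "oracle found no feasible vertex"
    values = [float(c @ v) for v in verts]
    return max(values) if model.objective.sense == "MAX" else min(values)
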