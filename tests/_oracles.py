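"""Independent oracles for the LP layer: brute-force vertex enumeration.

A bounded polyhedron {S v = 0, l <= v <= u} has its optima at basic feasible
solutions: fix (n - rank S) coordinates at one of their bounds and solve the
remaining square system.  Enumerating every such combination is exponential
but exact, and entirely independent of the package's LP code path.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_vertices(S: np.ndarray, lbs, ubs, tol: float = 1e-9):
    """All basic feasible solutions of {S v = 0, l <= v <= u}."""
    S = np.asarray(S, float)
    lbs, ubs = np.asarray(lbs, float), np.asarray(ubs, float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S, tol=1e-10)
    n_fix = n - rank
    vertices = []
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        B = S[:, free]
        if free and np.linalg.matrix_rank(B, tol=1e-10) < len(free):
            continue
        for choice in itertools.product(*[(lbs[j], ubs[j]) for j in fixed]):
            v = np.empty(n)
            for j, val in zip(fixed, choice):
                v[j] = val
            if free:
                rhs = -S[:, fixed] @ np.array(choice)
                sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
                if np.abs(B @ sol - rhs).max() > tol:
                    continue
                v[free] = sol
            if (v >= lbs - tol).all() and (v <= ubs + tol).all():
                if np.abs(S @ v).max() <= 1e-8:
                    vertices.append(np.clip(v, lbs, ubs))
    return vertices


def lp_by_enumeration(S, lbs, ubs, c, tol: float = 1e-9):
    """(optimum, optimal vertices) of max c.v by vertex enumeration."""
    vertices = enumerate_vertices(S, lbs, ubs, tol)
    if not vertices:
        return None, []
    values = [float(np.dot(c, v)) for v in vertices]
    best = max(values)
    winners = [v for v, val in zip(vertices, values) if abs(val - best) <= 1e-9]
    return best, winners


def fva_by_enumeration(S, lbs, ubs, c, tol: float = 1e-9):
    """Per-variable (min, max) over the optimal face, by enumeration."""
    best, winners = lp_by_enumeration(S, lbs, ubs, c, tol)
    arr = np.array(winners)
    return best, arr.min(axis=0), arr.max(axis=0)


def model_arrays(model, objective: dict[str, float]):
    """Extract (S, lbs, ubs, c, rxn_ids) from a CommunityModel."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    lbs = [model.reactions[r].lower_bound for r in rxn_ids]
    ubs = [model.reactions[r].upper_bound for r in rxn_ids]
    c = np.array([objective.get(r, 0.0) for r in rxn_ids])
    return S, np.array(lbs), np.array(ubs), c, rxn_ids
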