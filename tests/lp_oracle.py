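"""Independent brute-force oracle for small flux polytopes.

Enumerates all vertices of {v : S v = 0, lb <= v <= ub} by fixing every
possible choice of n - rank(S) variables at a bound and solving the
remaining square system. Only intended for toy networks (a dozen reactions
at most); used to check the LP solvers without relying on any LP code.
"""

from itertools import combinations, product

import numpy as np


def enumerate_vertices(model, tol: float = 1e-9) -> np.ndarray:
    """All vertices of the steady-state flux polytope, one per row."""
    S, _mets, rxn_ids, = model.stoichiometric_matrix()[0:3]
    bounds = np.array(
        [
            (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
            for r in rxn_ids
        ]
    )
    n = len(rxn_ids)
    rank = np.linalg.matrix_rank(S)
    n_fixed = n - rank
    vertices = []
    for fixed in combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free]
        if np.linalg.matrix_rank(S_free) < rank:
            continue
        for choices in product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for j, side in zip(fixed, choices):
                v[j] = bounds[j, side]
            rhs = -S[:, list(fixed)] @ v[list(fixed)]
            sol, residual, _rk, _sv = np.linalg.lstsq(S_free, rhs, rcond=None)
            v[free] = sol
            if np.abs(S @ v).max() > tol:
                continue
            if np.any(v < bounds[:, 0] - tol) or np.any(v > bounds[:, 1] + tol):
                continue
            vertices.append(np.clip(v, bounds[:, 0], bounds[:, 1]))
    if not vertices:
        return np.empty((0, n))
    vertices = np.array(vertices)
    # deduplicate
    keep = []
    for row in vertices:
        if not any(np.allclose(row, vertices[k], atol=1e-7) for k in keep):
            keep.append(len(keep))
            if len(keep) == 1:
                unique = row[None, :]
            else:
                unique = np.vstack([unique, row])
    return unique


def oracle_fba_optimum(model) -> float:
    """Maximal objective flux over the enumerated vertices."""
    _S, _mets, rxn_ids = model.stoichiometric_matrix()
    j = rxn_ids.index(model.objective_reaction)
    verts = enumerate_vertices(model)
    if verts.shape[0] == 0:
        raise ValueError("no feasible vertex")
    values = verts[:, j]
    return float(values.max() if model.objective_sense == "maximize" else values.min())


def oracle_min_total_flux_at_optimum(model, tol: float = 1e-7) -> float:
    """Minimal sum of |v| among enumerated vertices attaining the optimum."""
    _S, _mets, rxn_ids = model.stoichiometric_matrix()
    j = rxn_ids.index(model.objective_reaction)
    verts = enumerate_vertices(model)
    opt = oracle_fba_optimum(model)
    optimal = verts[np.abs(verts[:, j] - opt) <= tol * max(1.0, abs(opt))]
    return float(np.abs(optimal).sum(axis=1).min())
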