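"""Exhaustive validation oracles for small networks.

For a flux polytope P = {v : S·v = 0, lb ≤ v ≤ ub} with finite bounds,
every vertex has n − rank(S) coordinates pinned at a bound.  Enumerating
all such basic solutions and filtering for feasibility yields every vertex
of P; the best objective over vertices is the LP optimum.  This is
exponential in the reaction count and is meant for networks of at most a
dozen reactions, where it provides a ground truth that is entirely
independent of the simplex solver: it uses only dense linear algebra.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Iterable

import numpy as np
from scipy import sparse as _sparse

from .model import MetabolicModel, build_stoichiometric_matrix


def enumerate_vertices(
    S, lb, ub, tol: float = 1e-9, max_reactions: int = 14
) -> np.ndarray:
    """All vertices of {v : S v = 0, lb ≤ v ≤ ub}, one per row.

    Requires finite bounds.  Raises for systems wider than
    ``max_reactions`` columns (the enumeration is exponential).
    """
    if _sparse.issparse(S):
        S = S.toarray()
    S = np.atleast_2d(np.asarray(S, float))
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    m, n = S.shape
    if n > max_reactions:
        raise ValueError(f"vertex enumeration limited to {max_reactions} reactions")
    if not (np.isfinite(lb).all() and np.isfinite(ub).all()):
        raise ValueError("vertex enumeration requires finite bounds")
    r = np.linalg.matrix_rank(S, tol=1e-10) if S.size else 0
    k = n - r
    scale = max(1.0, np.abs(S).max() if S.size else 1.0, np.abs(ub).max(initial=1.0))
    verts: list[np.ndarray] = []
    for fixed_t in combinations(range(n), k):
        fixed = list(fixed_t)
        basic = [j for j in range(n) if j not in fixed_t]
        S_B = S[:, basic]
        if basic and np.linalg.matrix_rank(S_B, tol=1e-10) < r:
            continue
        for bits in product((0, 1), repeat=k):
            v = np.empty(n)
            for j, b in zip(fixed, bits):
                v[j] = lb[j] if b == 0 else ub[j]
            if basic:
                rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(m)
                sol, *_ = np.linalg.lstsq(S_B, rhs, rcond=None)
                if np.max(np.abs(S_B @ sol - rhs), initial=0.0) > tol * scale:
                    continue
                v[basic] = sol
            if np.max(np.abs(S @ v), initial=0.0) > tol * scale:
                continue
            if (v < lb - tol).any() or (v > ub + tol).any():
                continue
            verts.append(np.clip(v, lb, ub))
    if not verts:
        return np.empty((0, n))
    V = np.vstack(verts)
    # dedupe within tolerance
    order = np.lexsort(V.T[::-1])
    V = V[order]
    keep = [0]
    for i in range(1, len(V)):
        if np.max(np.abs(V[i] - V[keep[-1]])) > 1e-7:
            keep.append(i)
    return V[keep]


def brute_force_optimum(S, lb, ub, c) -> tuple[float | None, np.ndarray | None]:
    """LP optimum max cᵀv over the flux polytope by vertex enumeration.

    Returns (None, None) for an empty polytope.
    """
    V = enumerate_vertices(S, lb, ub)
    if V.shape[0] == 0:
        return None, None
    c = np.asarray(c, float)
    vals = V @ c
    i = int(np.argmax(vals))
    return float(vals[i]), V[i]


def brute_force_fba(
    model: MetabolicModel, objective: str | dict[str, float] | None = None
) -> tuple[float | None, dict[str, float] | None]:
    """FBA optimum by exhaustive vertex enumeration (independent of HiGHS)."""
    S, _, rxn_ids = build_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    if objective is None:
        objective = model.objective_coefficients or model.biomass_reaction_id
    c = np.zeros(len(rxn_ids))
    if isinstance(objective, str):
        c[rxn_ids.index(objective)] = 1.0
    else:
        for rid, coef in objective.items():
            c[rxn_ids.index(rid)] = coef
    z, v = brute_force_optimum(S, lb, ub, c)
    if z is None:
        return None, None
    return z, dict(zip(rxn_ids, v))


def brute_force_fva(
    model: MetabolicModel, gamma: float = 1.0, tol: float = 1e-9
) -> dict[str, tuple[float, float]] | None:
    """FVA ranges by vertex enumeration of the γ-constrained polytope.

    The objective floor cᵀv ≥ γ·Z_max is folded in as an equality with a
    bounded slack column, so the same vertex enumeration applies; ranges
    are the coordinate-wise min/max over the lifted polytope's vertices.
    """
    S, _, rxn_ids = build_stoichiometric_matrix(model)
    S = S.toarray()
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    objective = model.objective_coefficients or model.biomass_reaction_id
    c = np.zeros(len(rxn_ids))
    if isinstance(objective, str):
        c[rxn_ids.index(objective)] = 1.0
    else:
        for rid, coef in objective.items():
            c[rxn_ids.index(rid)] = coef
    z_max, _ = brute_force_optimum(S, lb, ub, c)
    if z_max is None:
        return None
    # c^T v - s = gamma*z_max with slack s in [0, s_max]
    s_max = float(np.abs(c) @ np.maximum(np.abs(lb), np.abs(ub))) + abs(z_max) + 1.0
    S_lift = np.hstack([np.vstack([S, c.reshape(1, -1)]),
                        np.concatenate([np.zeros(S.shape[0]), [-1.0]]).reshape(-1, 1)])
    # shift: S v = 0 rows unchanged; last row c^T v - s = gamma*z_max requires
    # inhomogeneous rhs, so substitute s = s' + gamma*z_max shifted into bounds
    lb_lift = np.concatenate([lb, [gamma * z_max - 0.0]])
    ub_lift = np.concatenate([ub, [gamma * z_max + s_max]])
    # now rows read S v = 0 and c^T v - t = 0 with t in [gamma*z_max, ...]
    V = enumerate_vertices(S_lift, lb_lift, ub_lift, tol=tol)
    if V.shape[0] == 0:
        return None
    out = {}
    for j, rid in enumerate(rxn_ids):
        out[rid] = (float(V[:, j].min()), float(V[:, j].max()))
    return out
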