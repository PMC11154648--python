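"""Independent reference implementations used for cross-validation.

These deliberately avoid the code paths of the main modules: the IPF here
is a plain nested-loop scaling, the food-web solution is a fixed-point
iteration rather than a direct linear solve, and the transportation
optimum is found by exhaustively enumerating candidate bases of the
transportation polytope.  They exist so that the package can be checked
against brute force, not for production use.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .errors import ConfigError
from .foodweb import (
    EnvironmentCell,
    FoodWeb,
    GRAMS_PER_KG,
    plankton_concentration,
    porewater_concentration,
    rate_constants,
)

__all__ = [
    "naive_ipf",
    "fixed_point_concentrations",
    "transport_vertex_optimum",
]


def naive_ipf(
    weights: np.ndarray,
    supply: np.ndarray,
    demand: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100000,
) -> np.ndarray:
    """Scalar-loop iterative proportional fitting for balanced margins."""
    if abs(supply.sum() - demand.sum()) > 1e-9 * max(supply.sum(), 1.0):
        raise ConfigError("naive_ipf requires balanced margins")
    m = [[supply[i] * demand[j] * weights[i][j] for j in range(len(demand))]
         for i in range(len(supply))]
    for _ in range(max_iter):
        worst = 0.0
        for i in range(len(supply)):
            row = sum(m[i])
            if row > 0:
                f = supply[i] / row
                m[i] = [v * f for v in m[i]]
        for j in range(len(demand)):
            col = sum(m[i][j] for i in range(len(supply)))
            if col > 0:
                f = demand[j] / col
                for i in range(len(supply)):
                    m[i][j] *= f
        for i in range(len(supply)):
            worst = max(worst, abs(sum(m[i]) - supply[i]))
        for j in range(len(demand)):
            worst = max(worst, abs(sum(m[i][j] for i in range(len(supply))) - demand[j]))
        if worst <= tol * max(max(supply, default=1.0), max(demand, default=1.0)):
            return np.array(m)
    raise ConfigError("naive IPF did not converge")


def fixed_point_concentrations(
    web: FoodWeb, cell: EnvironmentCell, tol: float = 1e-14, max_iter: int = 100000
) -> np.ndarray:
    """Iterate C <- (source + kD P C) / k_tot from zero until stationary.

    Returns concentrations in ng g^-1 ww, independently of the direct
    linear solve in the foodweb module.
    """
    n = len(web)
    source = np.zeros(n)
    k_tot = np.zeros(n)
    k_d = np.zeros(n)
    for i, s in enumerate(web.species):
        r = rate_constants(s, cell)
        k_tot[i] = r["k2"] + r["kE"] + s.k_g + s.k_m
        k_d[i] = r["kD"]
        c_phyto = plankton_concentration(cell, s.logkow, web.phyto_lipid) * GRAMS_PER_KG
        c_zoo = plankton_concentration(cell, s.logkow, web.zoo_lipid) * GRAMS_PER_KG
        respired = (1 - s.phi_sed) * cell.c_water + s.phi_sed * porewater_concentration(
            cell, s.logkow
        )
        source[i] = r["k1"] * respired + r["kD"] * (
            s.diet_phytoplankton * c_phyto
            + s.diet_zooplankton * c_zoo
            + s.diet_sediment * cell.c_sediment * GRAMS_PER_KG
        )
    p = web.prey.values
    c = np.zeros(n)
    for _ in range(max_iter):
        c_new = (source + k_d * (p @ c)) / k_tot
        if np.abs(c_new - c).max() <= tol * max(np.abs(c_new).max(), 1e-300):
            return c_new / GRAMS_PER_KG
        c = c_new
    raise ConfigError("fixed-point iteration did not converge")


def transport_vertex_optimum(
    supply: np.ndarray,
    demand: np.ndarray,
    cost: np.ndarray,
    chunk: int = 20000,
) -> float:
    """Brute-force optimum of a balanced transportation problem.

    Enumerates every subset of m+n-1 cells as a candidate basis, solves the
    margin equations for each, keeps feasible (non-negative, margin-exact)
    solutions and returns the minimum objective.  Exponential; intended for
    instances up to about 5x5.
    """
    s = np.asarray(supply, dtype=float)
    d = np.asarray(demand, dtype=float)
    c = np.asarray(cost, dtype=float)
    if abs(s.sum() - d.sum()) > 1e-9 * max(s.sum(), 1.0):
        raise ConfigError("vertex enumeration requires balanced margins")
    m, n = c.shape
    r = m + n - 1
    # margin constraint matrix with the redundant last demand row dropped
    a = np.zeros((m + n, m * n))
    for i in range(m):
        a[i, i * n : (i + 1) * n] = 1.0
    for j in range(n):
        a[m + j, j::n] = 1.0
    a_red = a[:-1]
    b_red = np.concatenate([s, d])[:-1]
    scale = max(float(s.max()), float(d.max()), 1.0)
    best = np.inf
    cols_iter = combinations(range(m * n), r)
    flat_cost = c.ravel()
    while True:
        batch = []
        for _ in range(chunk):
            nxt = next(cols_iter, None)
            if nxt is None:
                break
            batch.append(nxt)
        if not batch:
            break
        idx = np.array(batch)  # (k, r)
        mats = a_red[:, idx].transpose(1, 0, 2)  # (k, r, r)
        dets = np.linalg.det(mats)
        ok = np.abs(dets) > 1e-9
        if not ok.any():
            continue
        rhs = np.broadcast_to(b_red[:, None], (int(ok.sum()), r, 1)).copy()
        sol = np.linalg.solve(mats[ok], rhs)[..., 0]
        feas = np.all(sol >= -1e-9 * scale, axis=1)
        if not feas.any():
            continue
        costs = (flat_cost[idx[ok]] * sol).sum(axis=1)
        best = min(best, float(costs[feas].min()))
    if not np.isfinite(best):
        raise ConfigError("no feasible basic solution found")
    return best
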