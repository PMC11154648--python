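"""Multiobjective re-routing of trade flows by linear programming.

Per species, flows T[i,j] >= 0 are chosen to minimize a weighted sum of
shipping cost and population exposure,

    min  sum_ij (w_cost * c_ij / C0 + w_health * h_ij / H0) T_ij
    s.t. sum_j T_ij <= supply_i,   sum_i T_ij = demand_j,

with c_ij = unit_cost x d_ij (yuan kiloton^-1 km^-1 x km) and
h_ij = C_origin[i] (origin tissue concentration, ng g^-1 ww), so that
sum h.T is proportional to the national mass of contaminant delivered and
eaten.  Each objective is normalized by its value C0, H0 at the
gravity-model baseline, making the weights dimensionless; at the baseline
both normalized terms equal 1.  An epsilon-constraint mode (minimize cost
subject to a cap on the health term) is provided as an alternative
scalarization.

Solved with the HiGHS simplex via scipy.optimize.linprog, which returns an
optimal vertex deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import ConfigError, InfeasibleError, OptimizationError
from .trade import TradeMatrix

__all__ = [
    "OptimizationProblem",
    "OptimizationResult",
    "build_problem",
    "solve",
    "solve_epsilon",
    "pareto_sweep",
    "compare_scenarios",
]


@dataclass
class OptimizationProblem:
    """One species' transportation LP with cost and health coefficient layers."""

    species: str
    supply: np.ndarray
    demand: np.ndarray
    cost: np.ndarray  # c_ij, yuan kiloton^-1
    health: np.ndarray  # h_ij, proportional to intake per kiloton routed i->j
    w_cost: float
    w_health: float
    cost_norm: float
    health_norm: float
    labels: list[str]

    @property
    def objective_coefficients(self) -> np.ndarray:
        return self.w_cost * self.cost / self.cost_norm + (
            self.w_health * self.health / self.health_norm
        )

    def objective_value(self, flows: np.ndarray) -> float:
        return float((self.objective_coefficients * flows).sum())


@dataclass
class OptimizationResult:
    """Optimized flows plus the objective decomposition."""

    flows: TradeMatrix
    objective: float
    total_cost: float  # sum c.T, yuan
    health_term: float  # sum h.T, proportional to national intake
    status: int
    species: str


def build_problem(
    supply: np.ndarray | pd.Series,
    demand: np.ndarray | pd.Series,
    distance: np.ndarray,
    origin_conc: np.ndarray | pd.Series,
    baseline: TradeMatrix,
    w_cost: float = 1.0,
    w_health: float = 1.0,
    unit_cost: float = 1.0,
    species: str = "total",
    labels: list[str] | None = None,
) -> OptimizationProblem:
    """Assemble the per-species LP, normalizing objectives at the baseline."""
    if isinstance(supply, pd.Series) and labels is None:
        labels = list(supply.index)
    s = np.asarray(supply, dtype=float)
    d = np.asarray(demand, dtype=float)
    conc = np.asarray(origin_conc, dtype=float)
    dist = np.asarray(distance, dtype=float)
    if w_cost < 0 or w_health < 0 or w_cost + w_health <= 0:
        raise ConfigError("weights must be >= 0 with at least one positive")
    if s.sum() < d.sum() - 1e-12 * max(s.sum(), 1.0):
        raise InfeasibleError(
            f"total supply {s.sum():g} below total demand {d.sum():g}"
        )
    if np.any(conc < 0) or np.any(dist < 0):
        raise ConfigError("coefficients must be >= 0 and finite")
    cost = unit_cost * dist
    health = np.broadcast_to(conc[:, None], cost.shape).copy()
    t0 = baseline.values
    cost_norm = float((cost * t0).sum())
    health_norm = float((health * t0).sum())
    if cost_norm <= 0 or health_norm <= 0:
        raise ConfigError("baseline objective terms must be positive for normalization")
    n = len(s)
    labels = labels if labels is not None else [f"P{i:02d}" for i in range(1, n + 1)]
    return OptimizationProblem(
        species=species, supply=s, demand=d, cost=cost, health=health,
        w_cost=w_cost, w_health=w_health, cost_norm=cost_norm,
        health_norm=health_norm, labels=labels,
    )


def _margin_matrices(m: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-sum (supply) and column-sum (demand) constraint matrices."""
    a_ub = np.zeros((m, m * n))
    for i in range(m):
        a_ub[i, i * n : (i + 1) * n] = 1.0
    a_eq = np.zeros((n, m * n))
    for j in range(n):
        a_eq[j, j::n] = 1.0
    return a_ub, a_eq


def solve(
    problem: OptimizationProblem, initial: TradeMatrix | None = None
) -> OptimizationResult:
    """Solve the LP to an optimal vertex (HiGHS dual simplex, deterministic).

    ``initial`` (typically the gravity baseline) is used as a feasibility
    and improvement reference: the optimum can never be worse.
    """
    m = n = len(problem.supply)
    a_ub, a_eq = _margin_matrices(m, n)
    res = linprog(
        c=problem.objective_coefficients.ravel(),
        A_ub=a_ub,
        b_ub=problem.supply,
        A_eq=a_eq,
        b_eq=problem.demand,
        bounds=(0, None),
        method="highs-ds",
    )
    if res.status != 0:
        raise OptimizationError(
            f"{problem.species}: solver status {res.status}: {res.message}"
        )
    t = res.x.reshape(m, n)
    if initial is not None:
        ref = problem.objective_value(initial.values)
        if res.fun > ref + 1e-9 * max(abs(ref), 1.0):
            raise OptimizationError(
                f"{problem.species}: optimum {res.fun} worse than initial {ref}"
            )
    flows = pd.DataFrame(t, index=problem.labels, columns=problem.labels)
    slack = pd.Series(problem.supply - t.sum(axis=1), index=problem.labels).clip(lower=0)
    return OptimizationResult(
        flows=TradeMatrix(flows=flows, slack=slack, species=problem.species),
        objective=float(res.fun),
        total_cost=float((problem.cost * t).sum()),
        health_term=float((problem.health * t).sum()),
        status=int(res.status),
        species=problem.species,
    )


def solve_epsilon(
    problem: OptimizationProblem, health_cap: float
) -> OptimizationResult:
    """Epsilon-constraint mode: minimize cost s.t. sum h.T <= health_cap."""
    m = n = len(problem.supply)
    a_ub, a_eq = _margin_matrices(m, n)
    a_ub = np.vstack([a_ub, problem.health.ravel()[None, :]])
    b_ub = np.append(problem.supply, health_cap)
    res = linprog(
        c=problem.cost.ravel(),
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=problem.demand,
        bounds=(0, None),
        method="highs-ds",
    )
    if res.status != 0:
        raise OptimizationError(
            f"{problem.species}: epsilon-constraint status {res.status}: {res.message}"
        )
    t = res.x.reshape(m, n)
    flows = pd.DataFrame(t, index=problem.labels, columns=problem.labels)
    slack = pd.Series(problem.supply - t.sum(axis=1), index=problem.labels).clip(lower=0)
    return OptimizationResult(
        flows=TradeMatrix(flows=flows, slack=slack, species=problem.species),
        objective=float(res.fun),
        total_cost=float((problem.cost * t).sum()),
        health_term=float((problem.health * t).sum()),
        status=int(res.status),
        species=problem.species,
    )


def pareto_sweep(
    supply: np.ndarray,
    demand: np.ndarray,
    distance: np.ndarray,
    origin_conc: np.ndarray,
    baseline: TradeMatrix,
    weight_grid: np.ndarray,
    unit_cost: float = 1.0,
) -> pd.DataFrame:
    """Trace the cost-health frontier over a grid of health weights.

    Returns one row per w_health with the achieved total cost and health
    term; along the grid the health term is non-increasing and the cost
    non-decreasing in w_health.
    """
    grid = np.asarray(weight_grid, dtype=float)
    if grid.size < 2:
        raise ConfigError("weight grid needs at least 2 points")
    rows = []
    for w in grid:
        problem = build_problem(
            supply, demand, distance, origin_conc, baseline,
            w_cost=1.0, w_health=float(w), unit_cost=unit_cost,
        )
        res = solve(problem)
        rows.append(
            {"w_health": float(w), "total_cost": res.total_cost,
             "health_term": res.health_term}
        )
    return pd.DataFrame(rows)


def compare_scenarios(
    edi_optimized: pd.Series,
    edi_current: pd.Series,
    cost_optimized: pd.Series | None = None,
    cost_current: pd.Series | None = None,
) -> pd.DataFrame:
    """Fig.-5-style relative differences per province.

    EDI_RD = (EDI_optimized - EDI_current) x 100 / EDI_current; Cost_DF is
    the analogous relative change in per-unit-trade cost.  Provinces with
    zero current value get NaN (flagged undefined).
    """
    if not edi_optimized.index.equals(edi_current.index):
        raise ConfigError("scenario tables cover different provinces")
    with np.errstate(divide="ignore", invalid="ignore"):
        edi_rd = np.where(
            edi_current.values > 0,
            (edi_optimized.values - edi_current.values) / edi_current.values * 100.0,
            np.nan,
        )
    out = pd.DataFrame({"edi_rd_pct": edi_rd}, index=edi_current.index)
    if cost_optimized is not None and cost_current is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            cost_df = np.where(
                cost_current.values > 0,
                (cost_optimized.values - cost_current.values)
                / cost_current.values * 100.0,
                np.nan,
            )
        out["cost_df_pct"] = cost_df
    return out
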