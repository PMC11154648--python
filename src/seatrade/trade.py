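"""Doubly constrained gravity model for interprovincial commodity flows.

Flows follow the Leontief-Strout form T[i,j] = a_i b_j s_i d_j f(d_ij),
where s and d are provincial supply (outflow) and demand (inflow) margins,
f is a decreasing deterrence function of intercapital distance, and the
balancing factors a, b are found by iterative proportional fitting (IPF).
Because national supply exceeds national demand, a virtual slack
destination with uniform deterrence absorbs the surplus, so both true
margins are met exactly.

Also provides the no-trade counterfactual (each province consumes only its
own catch), origin shares of consumption, and least-squares recovery of the
deterrence exponent from an observed flow matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import ConfigError, ConvergenceError, InfeasibleError, TradeError

__all__ = [
    "GravityParams",
    "TradeMatrix",
    "deterrence",
    "effective_distance",
    "gravity_flows",
    "rebalance_flows",
    "estimate_beta",
    "consumption_shares",
    "no_trade_flows",
]


@dataclass(frozen=True)
class GravityParams:
    """Deterrence and IPF settings.

    beta is the deterrence exponent (power form d^-beta or exponential
    exp(-beta d)); d_intra_factor sets the intra-provincial distance as a
    fraction of the nearest-neighbour distance.
    """

    beta: float = 1.0
    deterrence_form: str = "power"
    d_intra_factor: float = 0.5
    ipf_tol: float = 1e-10
    ipf_max_iter: int = 5000
    beta_max: float = 10.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ConfigError(f"beta must be >= 0, got {self.beta}")
        if self.deterrence_form not in ("power", "exponential"):
            raise ConfigError(f"unknown deterrence form {self.deterrence_form!r}")
        if self.ipf_tol <= 0 or self.ipf_max_iter < 1:
            raise ConfigError("ipf_tol must be > 0 and ipf_max_iter >= 1")
        if not 0 < self.d_intra_factor:
            raise ConfigError("d_intra_factor must be > 0")


@dataclass
class TradeMatrix:
    """Origin x destination flows (kilotons yr^-1) plus unsold slack per origin."""

    flows: pd.DataFrame
    slack: pd.Series
    species: str | None = None

    @property
    def values(self) -> np.ndarray:
        return self.flows.values

    def row_totals(self) -> pd.Series:
        """Shipped + unsold tonnage per origin (should equal supply)."""
        return self.flows.sum(axis=1) + self.slack

    def margin_error(self, supply: np.ndarray, demand: np.ndarray) -> float:
        """Maximum relative deviation of the realized margins."""
        scale_s = max(float(np.max(supply)), 1e-300)
        scale_d = max(float(np.max(demand)), 1e-300)
        err_s = np.abs(self.row_totals().values - supply).max() / scale_s
        err_d = np.abs(self.flows.sum(axis=0).values - demand).max() / scale_d
        return float(max(err_s, err_d))


def deterrence(d: np.ndarray | float, params: GravityParams) -> np.ndarray | float:
    """Distance deterrence weight: d^-beta (power) or exp(-beta d)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ConfigError("distances must be >= 0")
    if params.deterrence_form == "power":
        if params.beta > 0 and np.any(d == 0):
            raise ConfigError(
                "zero distance with power deterrence; apply the intra-provincial "
                "distance rule first"
            )
        with np.errstate(divide="ignore"):
            return d ** (-params.beta) if params.beta > 0 else np.ones_like(d)
    return np.exp(-params.beta * d)


def effective_distance(distance: np.ndarray, params: GravityParams) -> np.ndarray:
    """Replace the zero diagonal with d_intra_factor x nearest-neighbour distance."""
    d = np.array(distance, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ConfigError("distance matrix must be square")
    if n == 1:
        d[0, 0] = 1.0
        return d
    off = d + np.diag(np.full(n, np.inf))
    np.fill_diagonal(d, params.d_intra_factor * off.min(axis=1))
    return d


def _ipf(
    seed: np.ndarray,
    supply: np.ndarray,
    demand_ext: np.ndarray,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Alternate row/column scaling of a seed matrix to the given margins."""
    m = seed.copy()
    scale = max(float(supply.max()), float(demand_ext.max()), 1e-300)
    for _ in range(max_iter):
        rows = m.sum(axis=1)
        bad = (rows <= 0) & (supply > 0)
        if np.any(bad):
            raise InfeasibleError(
                f"origins {np.nonzero(bad)[0].tolist()} have positive supply but "
                "no admissible destination"
            )
        r = np.divide(supply, rows, out=np.zeros_like(supply), where=rows > 0)
        m *= r[:, None]
        cols = m.sum(axis=0)
        bad = (cols <= 0) & (demand_ext > 0)
        if np.any(bad):
            raise InfeasibleError(
                f"destinations {np.nonzero(bad)[0].tolist()} have positive demand "
                "but are reachable from no positive-supply origin"
            )
        c = np.divide(demand_ext, cols, out=np.zeros_like(demand_ext), where=cols > 0)
        m *= c[None, :]
        err_r = np.abs(m.sum(axis=1) - supply).max() / scale
        err_c = np.abs(m.sum(axis=0) - demand_ext).max() / scale
        if max(err_r, err_c) <= tol:
            return m
    raise ConvergenceError(
        f"IPF did not converge in {max_iter} iterations; final margin residual "
        f"{max(err_r, err_c):.3e}"
    )


def _extend_with_slack(
    supply: np.ndarray, demand: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Append a slack destination absorbing the national surplus, if any."""
    surplus = float(supply.sum() - demand.sum())
    scale = max(float(supply.sum()), 1e-300)
    if surplus < -1e-12 * scale:
        raise InfeasibleError(
            f"total demand {demand.sum():g} exceeds total supply {supply.sum():g}"
        )
    if surplus <= 1e-15 * scale:
        return demand, weights
    demand_ext = np.append(demand, surplus)
    weights_ext = np.hstack([weights, np.ones((weights.shape[0], 1))])
    return demand_ext, weights_ext


def gravity_flows(
    supply: np.ndarray | pd.Series,
    demand: np.ndarray | pd.Series,
    distance: np.ndarray | pd.DataFrame,
    params: GravityParams | None = None,
    labels: list[str] | None = None,
    species: str | None = None,
) -> TradeMatrix:
    """Doubly constrained gravity flows balanced to the supply/demand margins."""
    params = params or GravityParams()
    if isinstance(supply, pd.Series) and labels is None:
        labels = list(supply.index)
    s = np.asarray(supply, dtype=float)
    d = np.asarray(demand, dtype=float)
    dist = np.asarray(distance, dtype=float)
    if np.any(s < 0) or np.any(d < 0):
        raise ConfigError("supply and demand must be >= 0")
    n = len(s)
    labels = labels if labels is not None else [f"P{i:02d}" for i in range(1, n + 1)]
    weights = np.asarray(deterrence(effective_distance(dist, params), params))
    demand_ext, weights_ext = _extend_with_slack(s, d, weights)
    seed = np.outer(s, demand_ext) * weights_ext
    m = _ipf(seed, s, demand_ext, params.ipf_tol, params.ipf_max_iter)
    slack = m[:, n] if m.shape[1] > n else np.zeros(n)
    flows = pd.DataFrame(m[:, :n], index=labels, columns=labels)
    return TradeMatrix(flows=flows, slack=pd.Series(slack, index=labels), species=species)


def rebalance_flows(
    raw: np.ndarray,
    supply: np.ndarray,
    demand: np.ndarray,
    params: GravityParams | None = None,
    labels: list[str] | None = None,
    species: str | None = None,
    slack_seed: np.ndarray | None = None,
) -> TradeMatrix:
    """Re-impose the supply/demand margins on a perturbed flow matrix by IPF.

    ``slack_seed`` seeds the surplus-absorbing column (e.g. the perturbed
    slack of the matrix being rebalanced); it defaults to a uniform column.
    """
    params = params or GravityParams()
    s = np.asarray(supply, dtype=float)
    d = np.asarray(demand, dtype=float)
    n = len(s)
    raw = np.asarray(raw, dtype=float)
    surplus = float(s.sum() - d.sum())
    if slack_seed is not None and surplus > 1e-15 * max(s.sum(), 1e-300):
        demand_ext = np.append(d, surplus)
        seed = np.hstack([raw, np.asarray(slack_seed, dtype=float)[:, None]])
    else:
        demand_ext, seed = _extend_with_slack(s, d, raw)
    m = _ipf(seed, s, demand_ext, params.ipf_tol, params.ipf_max_iter)
    labels = labels if labels is not None else [f"P{i:02d}" for i in range(1, n + 1)]
    slack = m[:, n] if m.shape[1] > n else np.zeros(n)
    flows = pd.DataFrame(m[:, :n], index=labels, columns=labels)
    return TradeMatrix(flows=flows, slack=pd.Series(slack, index=labels), species=species)


def estimate_beta(
    observed: TradeMatrix,
    supply: np.ndarray,
    demand: np.ndarray,
    distance: np.ndarray,
    params: GravityParams | None = None,
) -> tuple[float, float]:
    """Recover the deterrence exponent by 1-D bounded least squares on log flows.

    Minimizes sum over positive observed entries of
    (log T_model(beta) - log T_obs)^2.  Returns (beta_hat, objective).
    """
    params = params or GravityParams()
    t_obs = observed.values
    mask = t_obs > 0
    dist_eff = effective_distance(np.asarray(distance, dtype=float), params)
    used = dist_eff[mask]
    if np.unique(np.round(used, 9)).size < 3:
        raise TradeError(
            "beta is unidentifiable: fewer than 3 distinct distances among "
            "positive flows"
        )
    log_obs = np.log(t_obs[mask])

    def objective(beta: float) -> float:
        p = GravityParams(
            beta=beta,
            deterrence_form=params.deterrence_form,
            d_intra_factor=params.d_intra_factor,
            ipf_tol=params.ipf_tol,
            ipf_max_iter=params.ipf_max_iter,
            beta_max=params.beta_max,
        )
        model = gravity_flows(supply, demand, distance, p).values
        with np.errstate(divide="ignore"):
            log_model = np.log(model[mask])
        if not np.all(np.isfinite(log_model)):
            return np.inf
        return float(((log_model - log_obs) ** 2).sum())

    res = minimize_scalar(
        objective,
        bounds=(0.0, params.beta_max),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x), float(res.fun)


def consumption_shares(t: TradeMatrix) -> pd.DataFrame:
    """Origin shares of each destination's consumption; columns sum to 1.

    Destinations with zero inflow get a zero column and are listed in
    ``shares.attrs['zero_demand']``.
    """
    totals = t.flows.sum(axis=0)
    zero = list(totals.index[totals <= 0])
    safe = totals.replace(0.0, np.nan)
    shares = t.flows.div(safe, axis=1).fillna(0.0)
    shares.attrs["zero_demand"] = zero
    return shares


def no_trade_flows(
    supply: np.ndarray | pd.Series,
    demand: np.ndarray | pd.Series,
    labels: list[str] | None = None,
    species: str | None = None,
) -> TradeMatrix:
    """Local-consumption-only counterfactual: T[i,i] = min(supply_i, demand_i)."""
    if isinstance(supply, pd.Series) and labels is None:
        labels = list(supply.index)
    s = np.asarray(supply, dtype=float)
    d = np.asarray(demand, dtype=float)
    if np.any(s < 0) or np.any(d < 0):
        raise ConfigError("supply and demand must be >= 0")
    n = len(s)
    labels = labels if labels is not None else [f"P{i:02d}" for i in range(1, n + 1)]
    local = np.minimum(s, d)
    flows = pd.DataFrame(np.diag(local), index=labels, columns=labels)
    return TradeMatrix(
        flows=flows, slack=pd.Series(s - local, index=labels), species=species
    )
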