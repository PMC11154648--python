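"""Provincial dietary exposure: EDI, attribution, scenarios, evaluation.

The estimated daily intake for species i in a province is
EDI_i = C_i x I_i / W, with C_i the tissue concentration of the seafood
actually consumed there (a trade-share-weighted mix of origin
concentrations, ng g^-1 ww), I_i the per-capita daily consumption
(g day^-1) and W the standard adult body weight (63 kg).  Total seafood
consumption (TSC) EDI is the sum over species, in ng kg^-1 day^-1.

Origin attribution decomposes each province's EDI over the producing
provinces its seafood came from, which supports the trade-embodied share
(the population-weighted fraction of national exposure carried by
non-local seafood) and the trade vs. no-trade scenario difference
EDI_DF = EDI_T - EDI_NT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, SeatradeError

__all__ = [
    "ExposureTable",
    "EvalMetrics",
    "DEFAULT_BODY_WEIGHT",
    "consumed_concentration",
    "edi",
    "build_exposure",
    "total_edi",
    "species_contributions",
    "scenario_diff",
    "trade_embodied_share",
    "evaluate_model",
    "uncertainty_interval",
]

#: Standard body weight of an adult consumer, kg.
DEFAULT_BODY_WEIGHT = 63.0
#: Default multiplicative uncertainty factor on EDIs.
DEFAULT_UNCERTAINTY_FACTOR = 10.0


@dataclass
class ExposureTable:
    """Per-province exposure bundle.

    per_species: province x species EDI (ng kg^-1 day^-1);
    total: per-province TSC EDI; ci_low/ci_high: uncertainty bounds on the
    total; attribution: origin x destination EDI, whose column sums equal
    the destination totals.
    """

    per_species: pd.DataFrame
    total: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    attribution: pd.DataFrame
    body_weight: float = DEFAULT_BODY_WEIGHT
    uncertainty_factor: float = DEFAULT_UNCERTAINTY_FACTOR

    def validate(self) -> None:
        if (self.per_species.values < 0).any():
            raise SeatradeError("negative EDI")
        if not np.allclose(
            self.per_species.sum(axis=1), self.total, rtol=1e-12, atol=1e-300
        ):
            raise SeatradeError("per-species EDIs do not sum to the total")
        if not np.allclose(
            self.attribution.sum(axis=0), self.total, rtol=1e-12, atol=1e-300
        ):
            raise SeatradeError("origin attribution does not sum to the total")
        if ((self.ci_low > self.total + 1e-15) | (self.total > self.ci_high + 1e-15)).any():
            raise SeatradeError("CI bounds do not bracket the EDI")


@dataclass(frozen=True)
class EvalMetrics:
    """Model-vs-measurement agreement metrics."""

    mb: float  # mean bias, ng g^-1 ww
    nmb_pct: float  # normalized mean bias, %
    r2: float
    pct_within_factor: dict[int, float] = field(default_factory=dict)


def consumed_concentration(
    conc: pd.DataFrame, shares: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Trade-mix tissue concentration at each destination, per species.

    ``conc`` is origin x species (ng g^-1 ww); ``shares[species]`` is an
    origin x destination column-stochastic matrix.  The result is a convex
    combination of origin concentrations, so it lies within their range.
    """
    out = {}
    for species in conc.columns:
        sh = shares[species]
        missing = set(sh.index) - set(conc.index)
        if missing:
            raise ConfigError(f"origins {sorted(missing)} missing from concentrations")
        out[species] = sh.mul(conc.loc[sh.index, species], axis=0).sum(axis=0)
    return pd.DataFrame(out)


def edi(
    c: float | np.ndarray,
    intake: float | np.ndarray,
    body_weight: float = DEFAULT_BODY_WEIGHT,
) -> float | np.ndarray:
    """EDI = C x I / W (ng g^-1 x g day^-1 / kg = ng kg^-1 day^-1)."""
    if body_weight <= 0:
        raise ConfigError(f"body weight must be > 0, got {body_weight}")
    c = np.asarray(c, dtype=float)
    intake = np.asarray(intake, dtype=float)
    if np.any(c < 0) or np.any(intake < 0):
        raise ConfigError("concentration and intake must be >= 0")
    out = c * intake / body_weight
    return float(out) if out.ndim == 0 else out


def build_exposure(
    conc: pd.DataFrame,
    shares: dict[str, pd.DataFrame],
    consumption: pd.DataFrame,
    body_weight: float = DEFAULT_BODY_WEIGHT,
    uncertainty_factor: float = DEFAULT_UNCERTAINTY_FACTOR,
) -> ExposureTable:
    """Assemble the full exposure table for one trade scenario.

    ``consumption`` is destination x species per-capita intake (g day^-1).
    Attribution allocates each destination's EDI across origins with the
    species-level trade shares, so origin sums reproduce totals exactly.
    """
    c_mix = consumed_concentration(conc, shares)
    destinations = consumption.index
    per_species = pd.DataFrame(
        edi(c_mix.loc[destinations].values, consumption.values, body_weight),
        index=destinations,
        columns=consumption.columns,
    )
    origins = next(iter(shares.values())).index
    attribution = pd.DataFrame(0.0, index=origins, columns=destinations)
    for species in consumption.columns:
        sh = shares[species].loc[origins, destinations]
        contrib = sh.mul(conc.loc[origins, species], axis=0).mul(
            consumption[species] / body_weight, axis=1
        )
        attribution += contrib
    total = per_species.sum(axis=1)
    low, high = uncertainty_interval(total.values, uncertainty_factor)
    table = ExposureTable(
        per_species=per_species,
        total=total,
        ci_low=pd.Series(low, index=destinations),
        ci_high=pd.Series(high, index=destinations),
        attribution=attribution,
        body_weight=body_weight,
        uncertainty_factor=uncertainty_factor,
    )
    table.validate()
    return table


def total_edi(per_species: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Per-province TSC EDI and per-province species contributions (%).

    Contribution rows sum to 100 for provinces with nonzero exposure.
    """
    total = per_species.sum(axis=1)
    safe = total.replace(0.0, np.nan)
    contrib = per_species.div(safe, axis=0).fillna(0.0) * 100.0
    return total, contrib


def species_contributions(
    per_species: pd.DataFrame, populations: pd.Series
) -> pd.Series:
    """National species contributions (%) to TSC EDI, population-weighted."""
    w = populations.loc[per_species.index]
    national = per_species.mul(w, axis=0).sum(axis=0)
    if national.sum() <= 0:
        raise SeatradeError("national EDI is zero; contributions undefined")
    return national / national.sum() * 100.0


def scenario_diff(edi_t: pd.Series, edi_nt: pd.Series) -> pd.DataFrame:
    """Trade-minus-no-trade differencing per province.

    EDI_DF = EDI_T - EDI_NT; the relative change is EDI_DF / EDI_T x 100
    (the trade-scenario EDI is the denominator).  Provinces with zero
    trade-scenario EDI get NaN relative change.
    """
    if not edi_t.index.equals(edi_nt.index):
        raise ConfigError("scenario tables cover different provinces")
    df = edi_t - edi_nt
    rel = pd.Series(
        np.where(edi_t.values > 0, df.values / edi_t.values * 100.0, np.nan),
        index=edi_t.index,
    )
    return pd.DataFrame({"edi_t": edi_t, "edi_nt": edi_nt, "edi_df": df,
                         "rel_change_pct": rel})


def trade_embodied_share(attribution: pd.DataFrame, populations: pd.Series) -> float:
    """National % of exposure embodied in trade (non-local origins).

    Population-weighted: sum_p pop_p x sum_{i != p} EDI_attr[i, p] over
    sum_p pop_p x EDI_total[p], x 100.
    """
    pop = populations.loc[attribution.columns].values
    total = attribution.sum(axis=0).values
    denom = float((pop * total).sum())
    if denom <= 0:
        raise SeatradeError("national EDI is zero; embodied share undefined")
    local = np.array(
        [
            attribution.at[dest, dest] if dest in attribution.index else 0.0
            for dest in attribution.columns
        ]
    )
    imported = total - local
    return float((pop * imported).sum() / denom * 100.0)


def evaluate_model(
    modeled: np.ndarray, measured: np.ndarray, factors: tuple[int, ...] = (2, 5)
) -> EvalMetrics:
    """Mean bias, normalized mean bias, R^2 and factor-k coverage.

    MB = mean(model - obs); NMB = sum(model - obs) / sum(obs) x 100;
    R^2 from the least-squares fit of modeled on measured; factor-k
    coverage counts pairs with 1/k <= model/obs <= k (inclusive).
    """
    m = np.asarray(modeled, dtype=float)
    o = np.asarray(measured, dtype=float)
    if m.shape != o.shape:
        raise ConfigError("modeled and measured must be paired")
    if m.size < 2:
        raise ConfigError("need at least 2 pairs for R^2")
    if np.any(o <= 0):
        raise ConfigError("measured values must be > 0 for factor coverage")
    mb = float(np.mean(m - o))
    nmb = float((m - o).sum() / o.sum() * 100.0)
    r2 = float(stats.linregress(o, m).rvalue ** 2)
    ratio = m / o
    coverage = {
        int(k): float(np.mean((ratio >= 1.0 / k) & (ratio <= k)) * 100.0)
        for k in factors
    }
    return EvalMetrics(mb=mb, nmb_pct=nmb, r2=r2, pct_within_factor=coverage)


def uncertainty_interval(
    value: float | np.ndarray, uf: float = DEFAULT_UNCERTAINTY_FACTOR
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Multiplicative uncertainty interval (value/uf, value*uf)."""
    if uf < 1:
        raise ConfigError(f"uncertainty factor must be >= 1, got {uf}")
    v = np.asarray(value, dtype=float)
    low, high = v / uf, v * uf
    if v.ndim == 0:
        return float(low), float(high)
    return low, high


def monte_carlo_interval(
    value: float,
    gsd: float,
    rng: np.random.Generator,
    n: int = 10000,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded lognormal Monte-Carlo alternative to the fixed-factor interval."""
    if gsd < 1:
        raise ConfigError("gsd must be >= 1")
    draws = value * gsd ** rng.standard_normal(n)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(draws, alpha)), float(np.quantile(draws, 1.0 - alpha))
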