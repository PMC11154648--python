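"""Synthetic national seafood system with the structure the analysis assumes.

Generates, from one seeded configuration, everything the pipeline consumes:
a contaminant field over coastal fishing regions with a nearshore-high
offshore-decaying lognormal gradient; a province table (populations,
coordinates/distances, per-species consumption, supply and demand) in which
national supply exceeds national demand; gravity-consistent "observed"
trade flows with multiplicative lognormal noise for deterrence-exponent
recovery; and paired noisy tissue measurements for model evaluation.

The default scale mirrors a China-like geometry at desk scale: 31
provinces of which 11 are coastal, eight species with benthic bivalves and
a piscivorous fish chain, national supply 13,742.9 kilotons against a
smaller national demand, and coastal per-capita seafood consumption about
twice the inland rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .foodweb import FoodWeb, default_foodweb
from .trade import GravityParams, TradeMatrix, gravity_flows, rebalance_flows

__all__ = [
    "WorldConfig",
    "World",
    "DEFAULT_INTAKE_SHARES",
    "generate_environment",
    "generate_provinces",
    "generate_world",
    "generate_observed_flows",
    "generate_measurements",
    "cell_concentrations",
]

#: Stage names -> substream indices, so every stage draws from its own
#: deterministic child of the root seed.
STAGE_STREAMS = {
    "environment": 0,
    "provinces": 1,
    "flows": 2,
    "measurements": 3,
    "pipeline": 4,
}

#: National per-species shares of seafood intake (sum to 1); bivalves
#: dominate, mirroring shellfish-heavy consumption patterns.
DEFAULT_INTAKE_SHARES = {
    "hairtail": 0.12,
    "large_yellow_croaker": 0.06,
    "small_yellow_croaker": 0.07,
    "sea_bass": 0.05,
    "pomfret": 0.04,
    "prawn": 0.08,
    "clam": 0.32,
    "oyster": 0.26,
}


@dataclass(frozen=True)
class WorldConfig:
    """Scale, noise and economics of the synthetic national system.

    Units: concentrations ng L^-1 (water) and ng g^-1 dry (sediment);
    supply/demand kilotons yr^-1; consumption g day^-1; distances km.
    conc_gsd and the other *_gsd values are geometric standard deviations
    of multiplicative lognormal noise (>= 1); offshore_decay is the
    per-cell multiplicative decay of concentration away from shore.
    """

    n_provinces: int = 31
    n_coastal: int = 11
    grid_cells_per_region: int = 8
    conc_gsd: float = 1.8
    offshore_decay: float = 0.7
    beta_true: float = 1.0
    total_supply: float = 13742.9
    total_demand: float = 11000.0
    seed: int = 0
    # environment
    water_median: float = 1.0  # national geometric mean of region medians, ng/L
    region_gsd: float = 2.5  # spread of region medians
    sediment_enrichment: float = 3.0  # sediment excess over water equilibrium
    f_oc: float = 0.02
    temperature: float = 15.0
    logkow: float = 6.2
    # provinces
    domain_km: float = 2500.0
    mean_population: float = 4.5e7
    population_gsd: float = 1.8
    coastal_consumption_factor: float = 2.0
    consumption_gsd: float = 1.3
    share_jitter_gsd: float = 1.2
    # observed-flow and measurement noise
    flow_noise_gsd: float = 1.3
    meas_gsd: float = 2.0
    intake_shares: dict = field(default_factory=lambda: dict(DEFAULT_INTAKE_SHARES))

    def __post_init__(self) -> None:
        if self.n_coastal > self.n_provinces or self.n_coastal < 1:
            raise ConfigError("need 1 <= n_coastal <= n_provinces")
        if self.total_demand > self.total_supply:
            raise ConfigError(
                f"total demand {self.total_demand} exceeds national supply "
                f"{self.total_supply}"
            )
        for name in ("grid_cells_per_region", "total_supply", "total_demand",
                     "water_median", "domain_km", "mean_population",
                     "sediment_enrichment", "coastal_consumption_factor"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.offshore_decay <= 0:
            raise ConfigError("offshore_decay must be > 0")
        for name in ("conc_gsd", "region_gsd", "population_gsd", "consumption_gsd",
                     "share_jitter_gsd", "flow_noise_gsd", "meas_gsd"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} is a geometric SD and must be >= 1")
        if self.beta_true < 0:
            raise ConfigError("beta_true must be >= 0")
        total = sum(self.intake_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"intake shares sum to {total}, expected 1")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage substream of the root seed."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), STAGE_STREAMS[stage]])
        )


@dataclass
class World:
    """Full synthetic input set for one run."""

    config: WorldConfig
    provinces: pd.DataFrame  # name-indexed: coastal, population, x, y
    distance: pd.DataFrame  # km, symmetric, zero diagonal
    consumption: pd.DataFrame  # province x species, g day^-1 per capita
    supply: pd.DataFrame  # province x species, kilotons yr^-1
    demand: pd.DataFrame  # province x species, kilotons yr^-1
    environment: pd.DataFrame  # cells: region, cell, c_water, c_sediment, ...

    @property
    def names(self) -> list[str]:
        return list(self.provinces.index)

    @property
    def coastal(self) -> list[str]:
        return list(self.provinces.index[self.provinces.coastal])

    @property
    def species(self) -> list[str]:
        return list(self.consumption.columns)

    def foodweb(self) -> FoodWeb:
        return default_foodweb(self.config.logkow)


def _lognormal(rng: np.random.Generator, gsd: float, size) -> np.ndarray:
    """Median-1 multiplicative lognormal noise with geometric SD ``gsd``."""
    if gsd == 1.0:
        return np.ones(size)
    return gsd ** rng.standard_normal(size)


def cell_concentrations(
    median: float, decay: float, n_cells: int, gsd: float, rng: np.random.Generator
) -> np.ndarray:
    """Cells ranked nearshore -> offshore: median x decay^rank x lognormal noise."""
    if decay <= 0:
        raise ConfigError("offshore decay must be > 0")
    if gsd < 1:
        raise ConfigError("concentration GSD must be >= 1")
    ranks = np.arange(n_cells)
    return median * decay**ranks * _lognormal(rng, gsd, n_cells)


def _province_names(n: int) -> list[str]:
    return [f"P{i:02d}" for i in range(1, n + 1)]


def generate_environment(config: WorldConfig) -> pd.DataFrame:
    """Per-coastal-region grid of water and sediment concentrations.

    Region medians are lognormal around ``water_median``; within a region,
    concentration decays away from shore (cell rank) with multiplicative
    lognormal cell noise.  Sediment sits above water equilibrium by the
    configured enrichment, with the same cell noise structure.
    """
    rng = config.rng("environment")
    regions = _province_names(config.n_provinces)[: config.n_coastal]
    kd = 0.35 * 10.0**config.logkow * config.f_oc  # L/kg
    rows = []
    for region in regions:
        median = config.water_median * float(_lognormal(rng, config.region_gsd, ()))
        water = cell_concentrations(
            median, config.offshore_decay, config.grid_cells_per_region,
            config.conc_gsd, rng,
        )
        sed_noise = _lognormal(rng, config.conc_gsd, config.grid_cells_per_region)
        sediment = water * kd / 1000.0 * config.sediment_enrichment * sed_noise
        for k in range(config.grid_cells_per_region):
            rows.append(
                {"region": region, "cell": k, "c_water": water[k],
                 "c_sediment": sediment[k], "f_oc": config.f_oc,
                 "temperature": config.temperature}
            )
    return pd.DataFrame(rows)


def generate_provinces(config: WorldConfig) -> World:
    """Provinces with coordinates, populations, consumption, supply, demand.

    Coastal provinces sit along the western edge of the domain (the
    "coast"); distances are Euclidean between province points.  Consumption
    rates are lognormal with a coastal multiplier and scaled so national
    demand equals ``total_demand``; coastal supply comes from lognormal
    fishery weights normalized to ``total_supply``.  Demand is defined as
    consumption_rate x population x 365 x 1e-9 kilotons yr^-1.
    """
    rng = config.rng("provinces")
    n, nc = config.n_provinces, config.n_coastal
    names = _province_names(n)
    coastal = np.zeros(n, dtype=bool)
    coastal[:nc] = True
    x = np.empty(n)
    y = rng.uniform(0.0, config.domain_km, n)
    x[:nc] = rng.uniform(0.0, 0.05 * config.domain_km, nc)
    x[nc:] = rng.uniform(0.1 * config.domain_km, config.domain_km, n - nc)
    coords = np.column_stack([x, y])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    population = config.mean_population * _lognormal(rng, config.population_gsd, n)

    base_rate = 15.0 * _lognormal(rng, config.consumption_gsd, n)
    base_rate[coastal] *= config.coastal_consumption_factor
    species = list(config.intake_shares)
    shares = np.array([config.intake_shares[s] for s in species])
    jitter = _lognormal(rng, config.share_jitter_gsd, (n, len(species)))
    share_matrix = shares[None, :] * jitter
    share_matrix /= share_matrix.sum(axis=1, keepdims=True)
    rate = base_rate[:, None] * share_matrix  # g/day per species
    demand = rate * population[:, None] * 365.0 * 1e-9  # kilotons/yr
    scale = config.total_demand / demand.sum()
    rate *= scale
    demand *= scale

    fishery = _lognormal(rng, 1.5, nc)
    fishery /= fishery.sum()
    supply_jitter = _lognormal(rng, config.share_jitter_gsd, (nc, len(species)))
    supply_shares = shares[None, :] * supply_jitter
    supply_shares /= supply_shares.sum(axis=1, keepdims=True)
    supply = np.zeros((n, len(species)))
    supply[:nc] = config.total_supply * fishery[:, None] * supply_shares

    provinces = pd.DataFrame(
        {"coastal": coastal, "population": population, "x": x, "y": y}, index=names
    )
    provinces.index.name = "province"
    return World(
        config=config,
        provinces=provinces,
        distance=pd.DataFrame(dist, index=names, columns=names),
        consumption=pd.DataFrame(rate, index=names, columns=species),
        supply=pd.DataFrame(supply, index=names, columns=species),
        demand=pd.DataFrame(demand, index=names, columns=species),
        environment=generate_environment(config),
    )


def generate_world(config: WorldConfig | None = None) -> World:
    """The default synthetic world (convenience wrapper)."""
    return generate_provinces(config or WorldConfig())


def generate_observed_flows(
    world: World,
    beta_true: float | None = None,
    noise_gsd: float | None = None,
    params: GravityParams | None = None,
) -> TradeMatrix:
    """Noisy gravity flows of total seafood, rebalanced to the true margins.

    Flows are generated at ``beta_true``, perturbed by multiplicative
    median-1 lognormal noise, and re-balanced by IPF so the supply and
    demand margins hold again.  With noise_gsd=1 the gravity flows are
    returned unchanged.
    """
    config = world.config
    beta = config.beta_true if beta_true is None else beta_true
    gsd = config.flow_noise_gsd if noise_gsd is None else noise_gsd
    if gsd < 1:
        raise ConfigError("flow noise GSD must be >= 1")
    params = params or GravityParams()
    params = replace(params, beta=beta)
    supply = world.supply.sum(axis=1).values
    demand = world.demand.sum(axis=1).values
    clean = gravity_flows(supply, demand, world.distance.values, params,
                          labels=world.names)
    rng = config.rng("flows")
    noisy = clean.values * _lognormal(rng, gsd, clean.values.shape)
    noisy_slack = clean.slack.values * _lognormal(rng, gsd, len(clean.slack))
    return rebalance_flows(
        noisy, supply, demand, params, labels=world.names, slack_seed=noisy_slack
    )


def generate_measurements(
    true_conc: pd.DataFrame, meas_gsd: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Paired modeled/measured table: measured = true x lognormal(1, gsd)."""
    if meas_gsd < 1:
        raise ConfigError("measurement GSD must be >= 1")
    if (true_conc["mean"] <= 0).any():
        raise ConfigError("true concentrations must be positive")
    out = true_conc[["region", "species"]].copy()
    out["modeled"] = true_conc["mean"].values
    out["measured"] = true_conc["mean"].values * _lognormal(
        rng, meas_gsd, len(true_conc)
    )
    return out
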