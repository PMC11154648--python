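"""Steady-state food-web bioaccumulation of a hydrophobic contaminant.

The model propagates dissolved-water and sediment concentrations of a
persistent hydrophobic chemical (here short-chain chlorinated paraffins,
SCCPs, treated as a single compound with one representative logKow) into
tissue concentrations of marine species.  Each species obeys a steady-state
mass balance

    C_i * (k2 + kE + kG + kM)_i
        = k1_i * [(1 - phi_i) * C_wd + phi_i * C_pw]
          + kD_i * sum_j P_ij * C_j
          + kD_i * (p_phyto_i * C_phyto + p_zoo_i * C_zoo + p_sed_i * C_sed)

with gill uptake (k1, L kg^-1 d^-1), elimination to water (k2, d^-1),
dietary uptake (kD, kg kg^-1 d^-1), faecal egestion (kE), growth dilution
(kG) and metabolic transformation (kM).  Base compartments — phytoplankton,
zooplankton and sediment/detritus — are in equilibrium with the abiotic
environment; all species concentrations are solved simultaneously as one
linear system, so cyclic predator-prey structures are legal whenever the
system is nonsingular.

Rate constants follow the standard kinetic bioaccumulation formulation
(Arnot-Gobas style allometric ventilation and feeding), with every
coefficient exposed on :class:`SpeciesParams` so a species table fully
determines the model.

Units: water ng L^-1; sediment ng g^-1 dry; biota ng g^-1 wet weight.
Internally biota are carried in ng kg^-1 and converted on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, FoodWebError

__all__ = [
    "EnvironmentCell",
    "SpeciesParams",
    "FoodWeb",
    "rate_constants",
    "phytoplankton_concentration",
    "plankton_concentration",
    "porewater_concentration",
    "steady_state_concentrations",
    "regional_concentrations",
    "default_species",
    "default_foodweb",
]

#: K_oc / K_ow proportionality for organic-carbon partitioning.
KOC_KOW_RATIO = 0.35
#: Dissolved oxygen used in the ventilation allometry (mg L^-1).
DISSOLVED_OXYGEN = 8.0
#: Lipid (sorbing-phase) fraction of phytoplankton / zooplankton.
PHYTO_LIPID = 0.005
ZOO_LIPID = 0.008

GRAMS_PER_KG = 1000.0

#: Names of the base diet compartments, in the order stored on SpeciesParams.
DIET_COMPARTMENTS = ("phytoplankton", "zooplankton", "fish", "sediment")


@dataclass(frozen=True)
class EnvironmentCell:
    """Abiotic state of one grid cell of a fishing region.

    c_water is the freely dissolved concentration (ng L^-1); c_sediment is
    bulk dry-weight sediment (ng g^-1 dry) with organic-carbon fraction
    f_oc.
    """

    c_water: float
    c_sediment: float
    f_oc: float = 0.02
    temperature: float = 15.0

    def __post_init__(self) -> None:
        if self.c_water < 0 or self.c_sediment < 0:
            raise ConfigError("environmental concentrations must be >= 0")
        if not 0.0 < self.f_oc < 1.0:
            raise ConfigError(f"f_oc must be in (0, 1), got {self.f_oc}")


@dataclass(frozen=True)
class SpeciesParams:
    """Physiology and diet of one modelled species.

    diet_* fractions cover {phytoplankton, zooplankton, other species,
    sediment/detritus} and must sum to 1.  phi_sed is the fraction of
    respired water drawn from sediment pore water (benthic exposure).
    k1 may be given explicitly; otherwise it is derived from the
    ventilation allometry.
    """

    name: str
    body_weight: float  # kg wet
    lipid_fraction: float
    logkow: float = 6.2
    diet_phytoplankton: float = 0.0
    diet_zooplankton: float = 0.0
    diet_fish: float = 0.0
    diet_sediment: float = 0.0
    phi_sed: float = 0.0
    k_m: float = 0.0  # metabolic transformation, d^-1
    k_g: float = 0.003  # growth dilution, d^-1
    k1: float | None = None  # explicit gill uptake override, L kg^-1 d^-1
    egestion_ratio: float = 0.125  # kE as a fraction of kD
    benthic: bool = False

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ConfigError(f"{self.name}: body_weight must be > 0")
        if not 0 < self.lipid_fraction < 1:
            raise ConfigError(f"{self.name}: lipid_fraction must be in (0, 1)")
        if not 1.0 <= self.logkow <= 9.0:
            raise ConfigError(
                f"{self.name}: logKow {self.logkow} outside validity range [1, 9]"
            )
        d = self.diet_fractions
        if np.any(d < 0) or abs(float(d.sum()) - 1.0) > 1e-12:
            raise ConfigError(f"{self.name}: diet fractions must be >= 0 and sum to 1")
        if not 0.0 <= self.phi_sed <= 1.0:
            raise ConfigError(f"{self.name}: phi_sed must be in [0, 1]")
        if min(self.k_m, self.k_g, self.egestion_ratio) < 0:
            raise ConfigError(f"{self.name}: rates must be >= 0")

    @property
    def diet_fractions(self) -> np.ndarray:
        return np.array(
            [
                self.diet_phytoplankton,
                self.diet_zooplankton,
                self.diet_fish,
                self.diet_sediment,
            ]
        )


def rate_constants(species: SpeciesParams, cell: EnvironmentCell) -> dict[str, float]:
    """Kinetic rate constants for one species in one cell.

    Returns {k1, k2, kD, kE}: gill uptake (L kg^-1 d^-1), elimination to
    water (d^-1), dietary uptake (kg kg^-1 d^-1) and faecal egestion
    (d^-1).  k2 honours the lipid-partitioning relation
    k2 = k1 / (lipid_fraction * Kow).
    """
    kow = 10.0 ** species.logkow
    if species.k1 is not None:
        k1 = species.k1
    else:
        # gill uptake efficiency and ventilation allometry
        e_w = 1.0 / (1.85 + 155.0 / kow)
        g_v = 1400.0 * species.body_weight**0.65 / DISSOLVED_OXYGEN
        k1 = e_w * g_v / species.body_weight
    k2 = k1 / (species.lipid_fraction * kow)
    # dietary assimilation and feeding allometry
    e_d = 1.0 / (3.0e-7 * kow + 2.0)
    g_d = 0.022 * species.body_weight**0.85 * math.exp(0.06 * cell.temperature)
    k_d = e_d * g_d / species.body_weight
    k_e = species.egestion_ratio * k_d
    rates = {"k1": k1, "k2": k2, "kD": k_d, "kE": k_e}
    for name, value in rates.items():
        if not math.isfinite(value) or value < 0 or (value == 0 and name != "kE"):
            raise FoodWebError(f"{species.name}: rate {name}={value} not positive finite")
    return rates


def plankton_concentration(cell: EnvironmentCell, logkow: float, lipid: float) -> float:
    """Equilibrium-partitioning plankton concentration, ng g^-1 wet weight.

    C = lipid * Kow * C_water with the L -> g unit conversion 1e-3.
    """
    return lipid * 10.0**logkow * cell.c_water / GRAMS_PER_KG


def phytoplankton_concentration(
    cell: EnvironmentCell, logkow: float, lipid: float = PHYTO_LIPID
) -> float:
    """Phytoplankton tissue concentration (ng g^-1 ww) at equilibrium with water."""
    return plankton_concentration(cell, logkow, lipid)


def porewater_concentration(cell: EnvironmentCell, logkow: float) -> float:
    """Sediment pore-water concentration (ng L^-1) via organic-carbon partitioning.

    C_pw = C_sed / (f_oc * K_oc), K_oc = 0.35 * K_ow; the factor 1000
    converts ng g^-1 dry to ng kg^-1 against K_oc in L kg^-1.
    """
    koc = KOC_KOW_RATIO * 10.0**logkow
    return cell.c_sediment * GRAMS_PER_KG / (cell.f_oc * koc)


class FoodWeb:
    """A species list plus predator->prey diet matrix.

    ``prey`` is a square DataFrame (predator rows, prey columns) whose row
    sums equal each predator's "other species" diet share.  At build time
    the web must either be acyclic or yield a diagonally dominant
    steady-state system, otherwise construction fails.
    """

    def __init__(
        self,
        species: list[SpeciesParams],
        prey: pd.DataFrame | None = None,
        phyto_lipid: float = PHYTO_LIPID,
        zoo_lipid: float = ZOO_LIPID,
    ):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate species names")
        if prey is None:
            prey = pd.DataFrame(0.0, index=names, columns=names)
        prey = prey.reindex(index=names, columns=names, fill_value=0.0)
        for s in species:
            row_sum = float(prey.loc[s.name].sum())
            if abs(row_sum - s.diet_fish) > 1e-9:
                raise ConfigError(
                    f"{s.name}: prey-matrix row sum {row_sum} != other-species "
                    f"diet share {s.diet_fish}"
                )
        if (prey.values < 0).any():
            raise ConfigError("prey fractions must be >= 0")
        self.species = list(species)
        self.names = names
        self.prey = prey
        self.phyto_lipid = phyto_lipid
        self.zoo_lipid = zoo_lipid
        self._check_solvable()

    def _check_solvable(self) -> None:
        graph = nx.DiGraph(
            (pred, pr)
            for pred in self.names
            for pr in self.names
            if self.prey.loc[pred, pr] > 0
        )
        graph.add_nodes_from(self.names)
        if nx.is_directed_acyclic_graph(graph):
            return
        # cyclic web: demand diagonal dominance of the steady-state matrix
        cell = EnvironmentCell(c_water=1.0, c_sediment=1.0)
        a = self._system_matrix(cell)
        diag = np.abs(np.diag(a))
        off = np.abs(a).sum(axis=1) - diag
        if np.any(diag <= off):
            cycle = nx.find_cycle(graph)
            raise FoodWebError(
                "cyclic diet without diagonal dominance; cycle: "
                + " -> ".join(edge[0] for edge in cycle)
            )

    def _rates(self, cell: EnvironmentCell) -> pd.DataFrame:
        rows = {}
        for s in self.species:
            r = rate_constants(s, cell)
            r["kG"] = s.k_g
            r["kM"] = s.k_m
            rows[s.name] = r
        return pd.DataFrame(rows).T

    def _system_matrix(self, cell: EnvironmentCell) -> np.ndarray:
        rates = self._rates(cell)
        k_tot = (rates.k2 + rates.kE + rates.kG + rates.kM).values
        a = np.diag(k_tot) - rates.kD.values[:, None] * self.prey.values
        return a

    def __len__(self) -> int:
        return len(self.species)


def steady_state_concentrations(web: FoodWeb, cell: EnvironmentCell) -> pd.Series:
    """Solve the coupled steady-state system for one cell.

    Returns per-species concentrations in ng g^-1 wet weight.  The linear
    system residual is verified to < 1e-10 relative and all concentrations
    must be non-negative.
    """
    rates = web._rates(cell)
    a = web._system_matrix(cell)
    # base compartments, ng kg^-1
    b = np.empty(len(web))
    for i, s in enumerate(web.species):
        c_phyto = plankton_concentration(cell, s.logkow, web.phyto_lipid) * GRAMS_PER_KG
        c_zoo = plankton_concentration(cell, s.logkow, web.zoo_lipid) * GRAMS_PER_KG
        c_sed = cell.c_sediment * GRAMS_PER_KG  # ng g^-1 dry -> ng kg^-1 dry
        respired = (1.0 - s.phi_sed) * cell.c_water + s.phi_sed * porewater_concentration(
            cell, s.logkow
        )
        k = rates.loc[s.name]
        b[i] = k.k1 * respired + k.kD * (
            s.diet_phytoplankton * c_phyto
            + s.diet_zooplankton * c_zoo
            + s.diet_sediment * c_sed
        )
    try:
        c = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise FoodWebError(f"singular steady-state system: {exc}") from exc
    scale = max(float(np.abs(b).max()), 1e-300)
    residual = float(np.abs(a @ c - b).max()) / scale
    if residual > 1e-10:
        raise FoodWebError(f"steady-state residual {residual:.2e} above 1e-10")
    if np.any(c < -1e-9 * scale):
        raise FoodWebError("negative steady-state concentration")
    return pd.Series(np.maximum(c, 0.0) / GRAMS_PER_KG, index=web.names, name="c_biota")


def regional_concentrations(web: FoodWeb, field: pd.DataFrame) -> pd.DataFrame:
    """Aggregate cell-level solutions into per-(region, species) statistics.

    ``field`` has one row per grid cell with columns region, c_water,
    c_sediment, f_oc, temperature.  The regional concentration is the mean
    over cells; 2.5/50/97.5 % spatial quantiles are recorded alongside.
    """
    if field.empty:
        raise ConfigError("environment field is empty")
    records = []
    for region, cells in field.groupby("region", sort=True):
        if cells.empty:
            raise ConfigError(f"region {region} has no cells")
        per_cell = np.vstack(
            [
                steady_state_concentrations(
                    web,
                    EnvironmentCell(
                        c_water=row.c_water,
                        c_sediment=row.c_sediment,
                        f_oc=row.f_oc,
                        temperature=row.temperature,
                    ),
                ).values
                for row in cells.itertuples()
            ]
        )
        q = np.quantile(per_cell, [0.025, 0.5, 0.975], axis=0)
        for j, name in enumerate(web.names):
            records.append(
                {
                    "region": region,
                    "species": name,
                    "mean": per_cell[:, j].mean(),
                    "q2_5": q[0, j],
                    "q50": q[1, j],
                    "q97_5": q[2, j],
                }
            )
    return pd.DataFrame.from_records(records)


def default_species(logkow: float = 6.2) -> list[SpeciesParams]:
    """Eight-species preset: five fish, one crustacean, two bivalves.

    Benthic taxa (prawn, clam, oyster) draw part of their respired water
    from pore water and ingest sediment/detritus.  Fish carry a nonzero
    metabolic transformation rate, reflecting the faster biotransformation
    of chlorinated paraffins in fish than in filter-feeding invertebrates;
    invertebrate metabolism is kept near zero.
    """
    fish_km = 0.02
    inv_km = 0.002
    return [
        SpeciesParams(
            "hairtail", 1.0, 0.045, logkow,
            diet_zooplankton=0.3, diet_fish=0.7, k_m=fish_km, k_g=0.002,
        ),
        SpeciesParams(
            "large_yellow_croaker", 0.6, 0.06, logkow,
            diet_zooplankton=0.5, diet_fish=0.5, k_m=fish_km, k_g=0.0025,
        ),
        SpeciesParams(
            "small_yellow_croaker", 0.15, 0.05, logkow,
            diet_phytoplankton=0.1, diet_zooplankton=0.8, diet_fish=0.1,
            k_m=fish_km, k_g=0.004,
        ),
        SpeciesParams(
            "sea_bass", 1.5, 0.04, logkow,
            diet_zooplankton=0.25, diet_fish=0.75, k_m=fish_km, k_g=0.002,
        ),
        SpeciesParams(
            "pomfret", 0.3, 0.05, logkow,
            diet_phytoplankton=0.2, diet_zooplankton=0.8, k_m=fish_km, k_g=0.003,
        ),
        SpeciesParams(
            "prawn", 0.02, 0.012, logkow,
            diet_phytoplankton=0.2, diet_zooplankton=0.3, diet_sediment=0.5,
            phi_sed=0.5, k_m=inv_km, k_g=0.008, benthic=True,
        ),
        SpeciesParams(
            "clam", 0.015, 0.012, logkow,
            diet_phytoplankton=0.5, diet_sediment=0.5,
            phi_sed=0.9, k_m=inv_km, k_g=0.005, benthic=True,
        ),
        SpeciesParams(
            "oyster", 0.05, 0.015, logkow,
            diet_phytoplankton=0.55, diet_sediment=0.45,
            phi_sed=0.8, k_m=inv_km, k_g=0.004, benthic=True,
        ),
    ]


#: predator -> {prey: diet fraction}; row sums equal each diet_fish share.
DEFAULT_PREY = {
    "hairtail": {"small_yellow_croaker": 0.5, "prawn": 0.2},
    "large_yellow_croaker": {"small_yellow_croaker": 0.2, "prawn": 0.3},
    "small_yellow_croaker": {"prawn": 0.1},
    "sea_bass": {"small_yellow_croaker": 0.6, "prawn": 0.15},
}


def default_foodweb(logkow: float = 6.2) -> FoodWeb:
    """The default eight-species web with its acyclic predation structure."""
    species = default_species(logkow)
    names = [s.name for s in species]
    prey = pd.DataFrame(0.0, index=names, columns=names)
    for pred, d in DEFAULT_PREY.items():
        for pr, frac in d.items():
            prey.loc[pred, pr] = frac
    return FoodWeb(species, prey)
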