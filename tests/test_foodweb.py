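"""Food-web solver: kinetics, closed forms, oracles, structural properties."""

import numpy as np
import pandas as pd
import pytest

from seatrade._reference import fixed_point_concentrations
from seatrade.errors import ConfigError, FoodWebError
from seatrade.foodweb import (
    EnvironmentCell,
    FoodWeb,
    SpeciesParams,
    default_foodweb,
    phytoplankton_concentration,
    rate_constants,
    regional_concentrations,
    steady_state_concentrations,
)


def bcf_species(**overrides):
    """Single species in the pure-bioconcentration limit: its only diet
    route is sediment/detritus, so a sediment-free cell leaves gill uptake
    and respiratory elimination as the only exchange."""
    kwargs = dict(
        name="solo", body_weight=0.5, lipid_fraction=0.05, logkow=6.0,
        diet_sediment=1.0, phi_sed=0.0, k_m=0.0, k_g=0.0, egestion_ratio=0.0,
    )
    kwargs.update(overrides)
    return SpeciesParams(**kwargs)


class TestRateConstants:
    def test_lipid_partitioning_relation_with_explicit_k1(self, cell):
        s = bcf_species(k1=500.0)
        r = rate_constants(s, cell)
        assert r["k2"] == pytest.approx(500.0 / (0.05 * 10**6.0), rel=1e-12)
        assert r["k2"] == pytest.approx(0.01, rel=1e-12)

    def test_logkow_outside_validity_range_rejected(self):
        with pytest.raises(ConfigError):
            bcf_species(logkow=0.0)
        with pytest.raises(ConfigError):
            bcf_species(logkow=9.5)

    def test_k2_strictly_decreasing_in_logkow(self, cell):
        k2 = [
            rate_constants(bcf_species(logkow=lk), cell)["k2"]
            for lk in np.linspace(4.0, 8.5, 10)
        ]
        assert np.all(np.diff(k2) < 0)

    def test_all_rates_positive_finite(self, cell):
        r = rate_constants(bcf_species(egestion_ratio=0.125), cell)
        assert all(np.isfinite(v) and v > 0 for v in r.values())


class TestPhytoplankton:
    def test_zero_water_gives_zero(self):
        c = EnvironmentCell(c_water=0.0, c_sediment=0.0)
        assert phytoplankton_concentration(c, 6.0) == 0.0

    def test_linear_in_water_concentration(self):
        c1 = EnvironmentCell(c_water=1.0, c_sediment=0.0)
        c2 = EnvironmentCell(c_water=2.0, c_sediment=0.0)
        assert phytoplankton_concentration(c2, 6.2) == pytest.approx(
            2 * phytoplankton_concentration(c1, 6.2), rel=1e-15
        )

    def test_unit_traced_value(self):
        # lipid 0.01, logKow 5, 1 ng/L -> 0.01 * 1e5 * 1 * 1e-3 = 1.0 ng/g
        c = EnvironmentCell(c_water=1.0, c_sediment=0.0)
        assert phytoplankton_concentration(c, 5.0, lipid=0.01) == pytest.approx(
            1.0, rel=1e-15
        )


class TestSteadyState:
    def test_bioconcentration_closed_form(self):
        s = bcf_species()
        web = FoodWeb([s])
        cell = EnvironmentCell(c_water=2.5, c_sediment=0.0)
        r = rate_constants(s, cell)
        expected = r["k1"] / r["k2"] * cell.c_water / 1000.0  # ng/g ww
        got = steady_state_concentrations(web, cell)["solo"]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_two_species_chain_matches_hand_solution(self):
        prey = bcf_species(name="prey", body_weight=0.1, egestion_ratio=0.125,
                           k_g=0.002)
        pred = SpeciesParams(
            name="pred", body_weight=1.0, lipid_fraction=0.04, logkow=6.0,
            diet_fish=1.0, k_g=0.002, egestion_ratio=0.125,
        )
        prey_matrix = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0]], index=["prey", "pred"],
            columns=["prey", "pred"],
        )
        web = FoodWeb([prey, pred], prey_matrix)
        cell = EnvironmentCell(c_water=1.5, c_sediment=0.0)
        rp = rate_constants(prey, cell)
        rq = rate_constants(pred, cell)
        # hand-derived two-equation solution, in ng/kg
        c_prey = rp["k1"] * cell.c_water / (rp["k2"] + rp["kE"] + prey.k_g)
        c_pred = (rq["k1"] * cell.c_water + rq["kD"] * c_prey) / (
            rq["k2"] + rq["kE"] + pred.k_g
        )
        got = steady_state_concentrations(web, cell)
        assert got["prey"] == pytest.approx(c_prey / 1000.0, rel=1e-12)
        assert got["pred"] == pytest.approx(c_pred / 1000.0, rel=1e-12)

    def test_matches_fixed_point_oracle_on_random_webs(self, web):
        rng = np.random.default_rng(21)
        for _ in range(5):
            cell = EnvironmentCell(
                c_water=float(rng.uniform(0.1, 5.0)),
                c_sediment=float(rng.uniform(1.0, 80.0)),
                temperature=float(rng.uniform(5.0, 25.0)),
            )
            direct = steady_state_concentrations(web, cell).values
            iterated = fixed_point_concentrations(web, cell)
            np.testing.assert_allclose(direct, iterated, rtol=1e-10)

    def test_linearity_in_environmental_concentrations(self, web):
        lam = 3.7
        base = EnvironmentCell(c_water=1.0, c_sediment=15.0)
        scaled = EnvironmentCell(c_water=lam, c_sediment=15.0 * lam)
        np.testing.assert_allclose(
            steady_state_concentrations(web, scaled).values,
            lam * steady_state_concentrations(web, base).values,
            rtol=1e-12,
        )

    def test_trophic_amplification_in_metabolism_free_chain(self):
        # with no metabolic loss and dietary assimilation exceeding
        # egestion, the predator's lipid-normalized burden tops its prey's
        prey = bcf_species(name="prey", body_weight=0.1, lipid_fraction=0.05,
                           egestion_ratio=0.125, k_g=0.002)
        pred = SpeciesParams(
            name="pred", body_weight=1.0, lipid_fraction=0.04, logkow=6.0,
            diet_fish=1.0, k_m=0.0, k_g=0.002, egestion_ratio=0.125,
        )
        prey_matrix = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0]], index=["prey", "pred"],
            columns=["prey", "pred"],
        )
        web = FoodWeb([prey, pred], prey_matrix)
        c = steady_state_concentrations(web, EnvironmentCell(1.0, 0.0))
        assert c["pred"] / pred.lipid_fraction >= c["prey"] / prey.lipid_fraction

    def test_cyclic_web_without_dominance_rejected(self):
        a = SpeciesParams("a", 1.0, 0.05, 6.0, diet_fish=1.0, k_m=0.0,
                          k_g=0.0, egestion_ratio=0.0)
        b = SpeciesParams("b", 1.0, 0.05, 6.0, diet_fish=1.0, k_m=0.0,
                          k_g=0.0, egestion_ratio=0.0)
        prey = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"],
                            columns=["a", "b"])
        with pytest.raises(FoodWebError, match="cycl"):
            FoodWeb([a, b], prey)


class TestRegional:
    def _field(self, waters, sediments, region="R1"):
        return pd.DataFrame(
            {
                "region": region,
                "cell": range(len(waters)),
                "c_water": waters,
                "c_sediment": sediments,
                "f_oc": 0.02,
                "temperature": 15.0,
            }
        )

    def test_uniform_field_collapses_quantiles(self, web):
        field = self._field([2.0] * 3, [30.0] * 3)
        out = regional_concentrations(web, field)
        np.testing.assert_allclose(out["q2_5"], out["mean"], rtol=1e-12)
        np.testing.assert_allclose(out["q97_5"], out["mean"], rtol=1e-12)

    def test_mean_over_cells_is_hand_average(self, web):
        waters, seds = [1.0, 2.0, 4.0], [10.0, 20.0, 40.0]
        out = regional_concentrations(web, self._field(waters, seds))
        per_cell = np.vstack(
            [
                steady_state_concentrations(
                    web, EnvironmentCell(w, s, 0.02, 15.0)
                ).values
                for w, s in zip(waters, seds)
            ]
        )
        np.testing.assert_allclose(
            out.set_index("species").loc[web.names, "mean"].values,
            per_cell.mean(axis=0),
            rtol=1e-12,
        )

    def test_sediment_increase_moves_benthics_only(self, web):
        low = steady_state_concentrations(web, EnvironmentCell(1.0, 10.0))
        high = steady_state_concentrations(web, EnvironmentCell(1.0, 50.0))
        assert high["clam"] > low["clam"]
        assert high["oyster"] > low["oyster"]
        # pomfret has no sediment diet, no benthic respiration, and no prey
        # touching sediment, so it is structurally insensitive
        assert high["pomfret"] == pytest.approx(low["pomfret"], rel=1e-12)

    def test_empty_field_rejected(self, web):
        with pytest.raises(ConfigError):
            regional_concentrations(web, pd.DataFrame(columns=["region"]))


class TestDefaultWeb:
    def test_benthic_exceed_pelagic_with_elevated_sediment(self, default_world):
        conc = regional_concentrations(
            default_world.foodweb(), default_world.environment
        )
        national = conc.groupby("species")["mean"].mean()
        benthic = {"prawn", "clam", "oyster"}
        worst_fish = max(v for s, v in national.items() if s not in benthic)
        assert all(national[s] > worst_fish for s in benthic)
        assert national.idxmin() == "pomfret"
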