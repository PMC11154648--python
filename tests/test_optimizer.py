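"""Transportation LP: optimality, scalarization, frontier, comparisons."""

import numpy as np
import pandas as pd
import pytest

from seatrade._reference import transport_vertex_optimum
from seatrade.errors import ConfigError, InfeasibleError
from seatrade.optimizer import (
    OptimizationProblem,
    build_problem,
    compare_scenarios,
    pareto_sweep,
    solve,
    solve_epsilon,
)
from seatrade.trade import TradeMatrix, gravity_flows


def tm(values):
    labels = [f"P{i}" for i in range(len(values))]
    return TradeMatrix(
        flows=pd.DataFrame(np.asarray(values, dtype=float), index=labels,
                           columns=labels),
        slack=pd.Series(0.0, index=labels),
    )


def raw_problem(supply, demand, cost, health, w_cost=1.0, w_health=0.0):
    """Unnormalized problem for hand-algebra checks."""
    n = len(supply)
    return OptimizationProblem(
        species="s",
        supply=np.asarray(supply, dtype=float),
        demand=np.asarray(demand, dtype=float),
        cost=np.asarray(cost, dtype=float),
        health=np.asarray(health, dtype=float),
        w_cost=w_cost,
        w_health=w_health,
        cost_norm=1.0,
        health_norm=1.0,
        labels=[f"P{i}" for i in range(n)],
    )


def random_instance(rng, n, balanced=True):
    supply = rng.uniform(1.0, 10.0, n)
    demand = rng.dirichlet(np.ones(n)) * supply.sum()
    if not balanced:
        demand *= rng.uniform(0.5, 0.95)
    cost = rng.uniform(0.5, 20.0, (n, n))
    return supply, demand, cost


class TestBuildProblem:
    def _world(self):
        supply = np.array([4.0, 3.0])
        demand = np.array([2.0, 3.0])
        dist = np.array([[10.0, 50.0], [50.0, 10.0]])
        conc = np.array([8.0, 2.0])
        baseline = gravity_flows(supply, demand, np.array([[0.0, 50.0], [50.0, 0.0]]))
        return supply, demand, dist, conc, baseline

    def test_baseline_normalization_makes_both_terms_one(self):
        supply, demand, dist, conc, baseline = self._world()
        p = build_problem(supply, demand, dist, conc, baseline)
        t0 = baseline.values
        assert (p.cost * t0).sum() / p.cost_norm == pytest.approx(1.0, rel=1e-12)
        assert (p.health * t0).sum() / p.health_norm == pytest.approx(1.0, rel=1e-12)

    def test_pure_cost_and_pure_health_modes(self):
        supply, demand, dist, conc, baseline = self._world()
        p_cost = build_problem(supply, demand, dist, conc, baseline, w_health=0.0)
        p_health = build_problem(supply, demand, dist, conc, baseline, w_cost=0.0)
        assert (p_cost.objective_coefficients ==
                p_cost.cost / p_cost.cost_norm).all()
        assert (p_health.objective_coefficients ==
                p_health.health / p_health.health_norm).all()

    def test_both_weights_zero_rejected(self):
        supply, demand, dist, conc, baseline = self._world()
        with pytest.raises(ConfigError):
            build_problem(supply, demand, dist, conc, baseline,
                          w_cost=0.0, w_health=0.0)

    def test_demand_exceeding_supply_rejected(self):
        supply, demand, dist, conc, baseline = self._world()
        with pytest.raises(InfeasibleError):
            build_problem(supply, demand * 10, dist, conc, baseline)


class TestSolve:
    def test_single_pair_unique_flow(self):
        p = raw_problem([5.0], [3.0], [[2.0]], [[1.0]])
        res = solve(p)
        assert res.flows.values[0, 0] == pytest.approx(3.0)
        assert res.status == 0

    def test_cheap_diagonal_wins_and_matches_enumeration(self):
        cost = [[1.0, 2.0], [2.0, 1.0]]
        p = raw_problem([1.0, 1.0], [1.0, 1.0], cost, [[0.0] * 2] * 2)
        res = solve(p)
        np.testing.assert_allclose(res.flows.values, np.eye(2), atol=1e-10)
        oracle = transport_vertex_optimum(
            np.array([1.0, 1.0]), np.array([1.0, 1.0]), np.array(cost)
        )
        assert res.objective == pytest.approx(oracle, abs=1e-9)

    def test_health_weight_crossover_matches_hand_algebra(self):
        # one unit of demand; origin 0 is near (cost 1) but dirty (h=2),
        # origin 1 is far (cost 2) but clean (h=1).  Objective of serving
        # from 0: 1 + 2w; from 1: 2 + w.  Crossover at w = 1.
        supply, demand = [1.0, 1.0], [1.0, 0.0]
        cost = [[1.0, 9.0], [2.0, 9.0]]
        health = [[2.0, 2.0], [1.0, 1.0]]
        near = solve(raw_problem(supply, demand, cost, health, w_health=0.9))
        far = solve(raw_problem(supply, demand, cost, health, w_health=1.1))
        assert near.flows.values[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert far.flows.values[1, 0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_vertex_enumeration_on_random_instances(self, rng):
        for n in (2, 3, 3, 4):
            supply, demand, cost = random_instance(rng, n)
            p = raw_problem(supply, demand, cost, np.zeros((n, n)))
            res = solve(p)
            oracle = transport_vertex_optimum(supply, demand, cost)
            assert res.objective == pytest.approx(oracle, abs=1e-9 * max(1, oracle))

    def test_feasibility_of_returned_flows(self, rng):
        supply, demand, cost = random_instance(rng, 4, balanced=False)
        p = raw_problem(supply, demand, cost, np.zeros((4, 4)))
        res = solve(p)
        t = res.flows.values
        assert (t >= -1e-12).all()
        np.testing.assert_allclose(t.sum(axis=0), demand, atol=1e-9)
        assert (t.sum(axis=1) <= supply + 1e-9).all()

    def test_optimum_never_worse_than_initial(self):
        supply = np.array([4.0, 3.0])
        demand = np.array([2.0, 3.0])
        dist = np.array([[10.0, 50.0], [50.0, 10.0]])
        conc = np.array([8.0, 2.0])
        baseline = gravity_flows(supply, demand,
                                 np.array([[0.0, 50.0], [50.0, 0.0]]))
        p = build_problem(supply, demand, dist, conc, baseline)
        res = solve(p, initial=baseline)
        assert res.objective <= p.objective_value(baseline.values) + 1e-12


class TestEpsilonConstraint:
    def test_tight_cap_forces_clean_origin(self):
        supply, demand = [1.0, 1.0], [1.0, 0.0]
        cost = [[1.0, 9.0], [2.0, 9.0]]
        health = [[2.0, 2.0], [1.0, 1.0]]
        # serving x from the dirty origin gives health 1 + x, so a cap of
        # 1.0 admits only the clean origin
        p = raw_problem(supply, demand, cost, health)
        res = solve_epsilon(p, health_cap=1.0)
        assert res.flows.values[1, 0] == pytest.approx(1.0, abs=1e-10)
        assert res.health_term <= 1.0 + 1e-9


class TestParetoSweep:
    def _instance(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        coords = rng.uniform(0, 1000, (n, 2))
        dist = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        np.fill_diagonal(dist, 30.0)
        supply = rng.uniform(1, 10, n)
        demand = rng.dirichlet(np.ones(n)) * supply.sum() * 0.9
        conc = rng.uniform(1.0, 30.0, n)
        baseline = gravity_flows(supply, demand, dist)
        return supply, demand, dist, conc, baseline

    def test_frontier_monotone_in_health_weight(self):
        grid = np.array([0.0, 0.5, 2.0, 8.0, 1e6])
        for seed in range(5):
            supply, demand, dist, conc, baseline = self._instance(seed)
            frontier = pareto_sweep(supply, demand, dist, conc, baseline, grid)
            assert (np.diff(frontier.health_term.values) <= 1e-9).all()
            assert (np.diff(frontier.total_cost.values) >= -1e-9).all()

    def test_endpoints_are_pure_optima(self):
        supply, demand, dist, conc, baseline = self._instance(1)
        frontier = pareto_sweep(supply, demand, dist, conc, baseline,
                                np.array([0.0, 1e9]))
        pure_cost = solve(build_problem(supply, demand, dist, conc, baseline,
                                        w_health=0.0))
        pure_health = solve(build_problem(supply, demand, dist, conc, baseline,
                                          w_cost=0.0))
        assert frontier.total_cost.iloc[0] == pytest.approx(
            pure_cost.total_cost, rel=1e-9
        )
        assert frontier.health_term.iloc[-1] == pytest.approx(
            pure_health.health_term, rel=1e-6
        )

    def test_no_frontier_point_dominated_by_resolve(self):
        supply, demand, dist, conc, baseline = self._instance(2)
        grid = np.array([0.1, 1.0, 10.0])
        frontier = pareto_sweep(supply, demand, dist, conc, baseline, grid)
        for _, row in frontier.iterrows():
            p = build_problem(supply, demand, dist, conc, baseline,
                              w_health=row.w_health)
            re = solve(p)
            scal = (row.total_cost / p.cost_norm
                    + row.w_health * row.health_term / p.health_norm)
            assert re.objective <= scal + 1e-9


class TestCompareScenarios:
    def test_identical_scenarios_zero_everywhere(self):
        s = pd.Series([1.0, 2.0], index=["A", "B"])
        out = compare_scenarios(s, s.copy(), s, s.copy())
        np.testing.assert_array_equal(out.edi_rd_pct.values, 0.0)
        np.testing.assert_array_equal(out.cost_df_pct.values, 0.0)

    def test_halving_is_minus_fifty_percent(self):
        out = compare_scenarios(
            pd.Series([1.0], index=["A"]), pd.Series([2.0], index=["A"])
        )
        assert out.edi_rd_pct["A"] == pytest.approx(-50.0)

    def test_hand_two_province_case_with_costs(self):
        edi_opt = pd.Series([1.0, 3.0], index=["A", "B"])
        edi_cur = pd.Series([2.0, 2.0], index=["A", "B"])
        cost_opt = pd.Series([12.0, 8.0], index=["A", "B"])
        cost_cur = pd.Series([10.0, 10.0], index=["A", "B"])
        out = compare_scenarios(edi_opt, edi_cur, cost_opt, cost_cur)
        np.testing.assert_allclose(out.edi_rd_pct.values, [-50.0, 50.0])
        np.testing.assert_allclose(out.cost_df_pct.values, [20.0, -20.0])

    def test_zero_current_flagged_undefined(self):
        out = compare_scenarios(
            pd.Series([1.0], index=["A"]), pd.Series([0.0], index=["A"])
        )
        assert np.isnan(out.edi_rd_pct["A"])
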