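import numpy as np
import pandas as pd
import pytest

from landsys.engine import (
    SimulationConfig,
    advance_speed,
    check_convergence,
    competitive_advantage,
    compute_supply,
    draw_R,
    run_simulation,
    run_time_step,
    select_type,
    transition_potential,
    update_diff,
)
from landsys.grids import Grid, LandSystemMap, RegionMask


def _lsm(values, legend, cellsize=1000.0):
    return LandSystemMap(
        Grid(np.asarray(values, dtype=np.int64), cellsize=cellsize, nodata_value=-9999), legend
    )


def two_type_fixture(demand_shift=0.10):
    """20x20 map, two types, one service; type 1 supplies twice as much."""
    vals = np.zeros((20, 20), dtype=np.int64)
    vals[:, 10:] = 1
    ls = _lsm(vals, {0: "low", 1: "high"})
    cap = np.array([[1.0], [2.0]])
    supply0 = compute_supply(ls, cap, 1.0)
    demand = supply0 * (1 + demand_shift)
    # suitability gradient so cells flip one by one, not in lumps; resistance
    # high enough that incumbents win wherever the competition is neutral
    g = np.linspace(0.01, 0.99, 400).reshape(20, 20)
    p_loc = np.stack([1 - g, g])
    p_res = np.array([1.0, 1.0])
    orders = np.array([[0], [1]])
    con = np.ones((2, 2), dtype=np.int64)
    return ls, p_loc, p_res, orders, con, demand, cap


class TestSupply:
    def test_indicator_capability_returns_type_areas(self):
        ls = _lsm([[0, 0], [1, 1]], {0: "a", 1: "b"})
        supply = compute_supply(ls, np.eye(2), 1.0)
        np.testing.assert_allclose(supply, [2.0, 2.0])

    def test_capability_scales_area(self):
        ls = _lsm([[0] * 5, [0] * 5], {0: "a"})
        supply = compute_supply(ls, np.array([[0.3]]), 1.0)
        assert supply[0] == pytest.approx(3.0)

    def test_all_nodata_map_gives_zero(self):
        g = Grid(np.full((2, 2), -9999, dtype=np.int64), nodata_value=-9999)
        ls = LandSystemMap(g, {0: "a"})
        np.testing.assert_allclose(compute_supply(ls, np.array([[1.0]]), 1.0), [0.0])


class TestCompetitiveAdvantage:
    ORDERS = np.array([[2, -1], [0, 1]])

    def test_worked_example(self):
        val = competitive_advantage(
            0, 1, self.ORDERS, np.array([1.0, 1.0]), np.array([0.5, -0.2])
        )
        assert val == pytest.approx(0.7)

    def test_same_type_is_zero(self):
        assert competitive_advantage(1, 1, self.ORDERS, np.ones(2), np.array([0.5, -0.2])) == 0.0

    def test_swapping_types_negates(self):
        w, d = np.ones(2), np.array([0.3, 0.4])
        assert competitive_advantage(0, 1, self.ORDERS, w, d) == pytest.approx(
            -competitive_advantage(1, 0, self.ORDERS, w, d)
        )


class TestTransitionPotential:
    def test_incumbent_gets_resistance(self):
        assert transition_potential(0.4, 0.3, 0.0, same_type=True) == pytest.approx(0.7)

    def test_challenger_does_not(self):
        assert transition_potential(0.4, 0.3, 0.0, same_type=False) == pytest.approx(0.4)

    def test_reduces_to_suitability(self):
        assert transition_potential(0.4, 0.0, 0.0, same_type=False) == pytest.approx(0.4)


class TestSelectType:
    CON = np.array([[1, 0, 1], [1, 1, 1], [0, 0, 1]])

    def test_restricted_cell_keeps_start_type(self):
        pot = np.array([0.1, 0.9, 0.2])
        assert select_type(pot, start_type=0, prev_type=2, restricted=True, con=self.CON) == 0

    def test_dwell_time_keeps_start_type(self):
        pot = np.array([0.1, 0.9, 0.2])
        assert (
            select_type(pot, 0, 0, False, self.CON, age=1, dwell_min=5) == 0
        )

    def test_blocked_argmax_keeps_previous_type(self):
        pot = np.array([0.1, 0.9, 0.2])  # argmax = 1 but Con[2,1] = 0
        assert select_type(pot, 2, 2, False, self.CON) == 2

    def test_allowed_argmax_wins_with_lowest_id_ties(self):
        pot = np.array([0.9, 0.9, 0.1])
        assert select_type(pot, 1, 1, False, self.CON) == 0


class TestDiffAndSpeed:
    def test_initial_diff_is_zero_vector(self):
        # Eq. 9 i=1 branch is the engine's initialisation, checked in traces
        d = update_diff(np.zeros(2), np.array([1.0, 1.0]), np.array([1.0, 1.0]), 0.05, 350)
        np.testing.assert_allclose(d, 0.0)

    def test_worked_arithmetic(self):
        d = update_diff(np.zeros(1), np.array([110.0]), np.array([100.0]), 0.05, 350)
        assert d[0] == pytest.approx(-0.1 / 17.5, abs=1e-12)

    def test_zero_demand_service_stays_zero(self):
        d = update_diff(np.zeros(2), np.array([5.0, 3.0]), np.array([10.0, 0.0]), 0.05, 350)
        assert d[1] == 0.0 and d[0] > 0

    def test_speed_increments(self):
        s = 0.05
        for _ in range(2):
            s = advance_speed(s)
        assert s == pytest.approx(0.0504)

    def test_non_finite_rejected(self):
        with pytest.raises(FloatingPointError):
            update_diff(np.zeros(1), np.array([np.inf]), np.array([1.0]), 0.05, 350)


class TestDrawR:
    def test_degenerate_bounds(self):
        rng = np.random.default_rng(0)
        assert draw_R(rng, 350, 350) == 350

    def test_uniform_mean(self):
        rng = np.random.default_rng(1)
        draws = [draw_R(rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(343.5, abs=0.5)
        assert min(draws) >= 322 and max(draws) <= 365

    def test_deterministic_given_seed(self):
        a = [draw_R(np.random.default_rng(7)) for _ in range(5)]
        b = [draw_R(np.random.default_rng(7)) for _ in range(5)]
        assert a == b


class TestConvergence:
    CFG = SimulationConfig()

    def test_exact_match_converges(self):
        assert check_convergence(np.array([5.0, 7.0]), np.array([5.0, 7.0]), self.CFG)

    def test_two_percent_deviation_fails_the_per_service_bound(self):
        assert not check_convergence(np.array([102.0, 100.0]), np.array([100.0, 100.0]), self.CFG)

    def test_mixed_small_deviations_converge(self):
        supply = np.array([100.3, 99.4])
        assert check_convergence(supply, np.array([100.0, 100.0]), self.CFG)

    def test_oversupply_cannot_fake_convergence(self):
        # without absolute values a -3% deviation would pass the mean test
        assert not check_convergence(np.array([97.0, 100.0]), np.array([100.0, 100.0]), self.CFG)


class TestRunTimeStep:
    def test_matched_demand_converges_immediately_with_no_change(self):
        ls = _lsm([[0, 1], [1, 0]], {0: "a", 1: "b"})
        cap = np.eye(2)
        demand = compute_supply(ls, cap, 1.0)
        p_loc = np.full((2, 2, 2), 0.5)
        res = run_time_step(
            ls, p_loc, np.array([0.3, 0.3]), np.array([[1, 0], [0, 1]]),
            np.ones((2, 2), dtype=int), demand, cap, SimulationConfig(rng_seed=0),
        )
        assert res.converged and res.iterations == 1
        np.testing.assert_array_equal(res.map.grid.values, ls.grid.values)

    def test_fully_restricted_map_never_changes(self):
        ls, p_loc, p_res, orders, con, demand, cap = two_type_fixture()
        mask = RegionMask(Grid(np.ones((20, 20), dtype=np.int64), cellsize=1000.0))
        res = run_time_step(
            ls, p_loc, p_res, orders, con, demand, cap,
            SimulationConfig(rng_seed=0, max_iterations=50), mask=mask,
        )
        np.testing.assert_array_equal(res.map.grid.values, ls.grid.values)

    def test_supply_moves_monotonically_toward_raised_demand(self):
        ls, p_loc, p_res, orders, con, demand, cap = two_type_fixture(0.10)
        res = run_time_step(ls, p_loc, p_res, orders, con, demand, cap, SimulationConfig(rng_seed=3))
        assert res.converged
        supply = res.trace["supply_s0"].to_numpy()
        assert (np.diff(supply) >= -1e-9).all()
        assert supply[-1] > supply[0]

    def test_diff_sign_tracks_the_gap_every_iteration(self):
        ls, p_loc, p_res, orders, con, demand, cap = two_type_fixture(0.10)
        res = run_time_step(ls, p_loc, p_res, orders, con, demand, cap, SimulationConfig(rng_seed=3))
        supply = res.trace["supply_s0"].to_numpy()
        diff = res.trace["diff_s0"].to_numpy()
        gap_sign = np.sign(demand[0] - supply[:-1])
        steps = np.diff(diff)
        nz = steps != 0
        np.testing.assert_array_equal(np.sign(steps[nz]), gap_sign[nz])

    def test_equal_orders_stagnate_with_warning(self):
        ls, p_loc, p_res, _, con, demand, cap = two_type_fixture(0.10)
        orders = np.array([[1], [1]])  # one class: competition inert
        with pytest.warns(UserWarning, match="stagnation"):
            res = run_time_step(
                ls, p_loc, p_res, orders, con, demand, cap, SimulationConfig(rng_seed=0)
            )
        assert res.stagnated and not res.converged

    def test_dwell_minimum_freezes_young_cells(self):
        ls, p_loc, p_res, orders, con, demand, cap = two_type_fixture(0.10)
        cfg = SimulationConfig(rng_seed=0, max_iterations=200, dwell_min=np.array([10, 10]))
        res = run_time_step(ls, p_loc, p_res, orders, con, demand, cap, cfg)
        np.testing.assert_array_equal(res.map.grid.values, ls.grid.values)

    def test_bit_identical_rerun_under_fixed_seed(self):
        ls, p_loc, p_res, orders, con, demand, cap = two_type_fixture(0.10)
        a = run_time_step(ls, p_loc, p_res, orders, con, demand, cap, SimulationConfig(rng_seed=9))
        b = run_time_step(ls, p_loc, p_res, orders, con, demand, cap, SimulationConfig(rng_seed=9))
        np.testing.assert_array_equal(a.map.grid.values, b.map.grid.values)
        pd.testing.assert_frame_equal(a.trace, b.trace)


class TestRunSimulation:
    def _inputs(self):
        ls, p_loc, p_res, orders, con, demand, cap = two_type_fixture(0.0)
        return ls, p_loc, p_res, orders, con, demand, cap

    def test_empty_demand_series_returns_initial_map_only(self):
        ls, p_loc, p_res, orders, con, demand, cap = self._inputs()
        table = pd.DataFrame(columns=["s0"], index=pd.Index([], name="step"))
        sim = run_simulation(ls, table, p_loc, p_res, orders, con, cap, SimulationConfig())
        assert len(sim.maps) == 1

    def test_constant_matched_demand_keeps_all_maps_identical(self):
        ls, p_loc, p_res, orders, con, demand, cap = self._inputs()
        table = pd.DataFrame({"s0": [demand[0]] * 3}, index=pd.Index([1, 2, 3], name="step"))
        sim = run_simulation(ls, table, p_loc, p_res, orders, con, cap, SimulationConfig(rng_seed=1))
        for m in sim.maps[1:]:
            np.testing.assert_array_equal(m.grid.values, ls.grid.values)
        assert all(s["converged"] for s in sim.provenance["steps"])

    def test_deterministic_sequence_under_fixed_seed(self):
        ls, p_loc, p_res, orders, con, demand, cap = two_type_fixture(0.08)
        table = pd.DataFrame({"s0": [demand[0]]}, index=pd.Index([1], name="step"))
        runs = [
            run_simulation(ls, table, p_loc, p_res, orders, con, cap, SimulationConfig(rng_seed=5))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].maps[-1].grid.values, runs[1].maps[-1].grid.values)
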