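"""Dynamics of the interdependence simulator: support, stepping, runs, invariants."""

import numpy as np
import pytest

from tissuefail.geometry import ConstructGeometry
from tissuefail.model import (
    ModelParams,
    build_interaction_graph,
    make_state,
    run,
    step_day,
    support,
    transfer_medium,
)

from conftest import small_params


def triangle_state(params, side=10.0):
    state = make_state(params, seed=0)
    state.positions[:] = np.array([[0, 0, 0], [side, 0, 0], [side / 2, side, 0]])
    return state


class TestSupport:
    def test_isolated_cell_without_medium_has_zero_support(self):
        params = small_params(n_cells=1, lambda_int=50.0)
        state = make_state(params, seed=0)
        graph = build_interaction_graph(state.positions, params.lambda_int)
        assert support(state, graph, params)[0] == 0.0

    def test_support_arithmetic(self):
        # 5 cells: center + 4 neighbours, 3 of them functional, w*G = 0.5
        params = small_params(n_cells=5, lambda_int=15.0, w_global=1.0)
        state = make_state(params, seed=0)
        state.positions[:] = [[0, 0, 0], [10, 0, 0], [-10, 0, 0], [0, 10, 0], [0, -10, 0]]
        state.alive[:] = [True, True, True, True, False]
        state.G = 0.5
        graph = build_interaction_graph(state.positions, params.lambda_int)
        s = support(state, graph, params)
        assert s[0] == pytest.approx(1.0 * (3 / 4 + 0.5))

    def test_zero_reception_blocks_all_support(self):
        params = small_params(n_cells=5, lambda_int=1000.0)
        state = make_state(params, c=0.0, seed=0)
        state.G = 7.0
        graph = build_interaction_graph(state.positions, params.lambda_int)
        assert (support(state, graph, params) == 0.0).all()


class TestStepDay:
    def test_no_dynamics_leaves_population_unchanged(self, rng):
        params = small_params(n_cells=200, d=0.0, theta=0.0)
        state = make_state(params, seed=1)
        graph = build_interaction_graph(state.positions, params.lambda_int)
        new = step_day(state, graph, params, rng)
        assert new.n_live == 200
        assert new.day == pytest.approx(1.0)
        assert new.G > 0  # production still fills the medium

    def test_cascade_kills_triangle_after_single_death(self, rng):
        """3 mutually adjacent cells, theta=0.6: one death drops survivors to
        f=1/2 < 0.6, so the cascade removes all three."""
        params = small_params(n_cells=3, d=0.0, theta=0.6, lambda_int=20.0)
        state = triangle_state(params)
        state.alive[0] = False
        graph = build_interaction_graph(state.positions, params.lambda_int)
        new = step_day(state, graph, params, rng)
        assert new.n_live == 0

    def test_below_threshold_cascade_spares_triangle(self, rng):
        params = small_params(n_cells=3, d=0.0, theta=0.4, lambda_int=20.0)
        state = triangle_state(params)
        state.alive[0] = False
        graph = build_interaction_graph(state.positions, params.lambda_int)
        new = step_day(state, graph, params, rng)
        assert new.n_live == 2  # f = 1/2 >= 0.4 for both survivors

    def test_intrinsic_deaths_match_binomial_expectation(self):
        """d=0.1, beta=0, theta=0: deaths per step are Binomial(n, 0.1)."""
        params = small_params(n_cells=10_000, d=0.1, beta=0.0, theta=0.0,
                              lambda_int=0.0, geometry=ConstructGeometry())
        state = make_state(params, seed=2)
        graph = build_interaction_graph(state.positions, params.lambda_int)
        rng = np.random.default_rng(42)
        deaths = []
        for _ in range(100):
            new = step_day(state, graph, params, rng)
            deaths.append(state.n_live - new.n_live)
        se = np.sqrt(10_000 * 0.1 * 0.9 / 100)
        assert np.mean(deaths) == pytest.approx(1000.0, abs=3 * se)


class TestRun:
    def test_survival_matches_closed_form(self):
        """Non-interacting decay: mean n(5)/n0 within 3 SE of 0.8^5."""
        params = small_params(n_cells=10_000, d=0.2, beta=0.0, theta=0.0,
                              lambda_int=0.0, geometry=ConstructGeometry(), t_max=5.0)
        fracs = []
        for rep in range(50):
            p = ModelParams(**{**params.__dict__, "seed": rep})
            traj, _ = run(p)
            assert traj.censored
            fracs.append(traj.n[5] / traj.n[0])
        expect = 0.8**5
        se = np.sqrt(expect * (1 - expect) / 10_000 / 50)
        assert np.mean(fracs) == pytest.approx(expect, abs=3 * se)

    def test_immortal_population_right_censored(self):
        params = small_params(n_cells=100, d=0.0, theta=0.0, t_max=5.0)
        traj, _ = run(params)
        assert traj.censored
        assert (traj.n == 100).all()
        assert traj.times[-1] == pytest.approx(5.0)

    def test_dense_tissue_outlives_hundredfold_dilution(self):
        """Interacting dense populations (>5 mean neighbours) live longer than
        the same cells diluted 100x, matching the density-lifetime ordering."""
        lifetimes = {"dense": [], "sparse": []}
        for rep in range(20):
            dense = ModelParams(n_cells=20_000, d=0.2, theta=0.05, beta=1.2,
                                lambda_int=70.0, w_global=0.0, seed=(50, rep))
            sparse = ModelParams(n_cells=200, d=0.2, theta=0.05, beta=1.2,
                                 lambda_int=70.0, w_global=0.0, seed=(51, rep))
            for name, p in (("dense", dense), ("sparse", sparse)):
                traj, _ = run(p, media_policy="fresh")
                assert not traj.censored
                lifetimes[name].append(traj.times[-1])
        assert np.mean(lifetimes["dense"]) > np.mean(lifetimes["sparse"])

    def test_trajectory_conservation_and_monotonicity(self):
        params = small_params(n_cells=2000, seed=9)
        traj, _ = run(params)
        assert traj.n[0] == 2000
        assert (np.diff(traj.n) <= 0).all()  # r = 0
        assert traj.new_deaths.sum() == traj.n[0] - traj.n[-1]

    def test_deterministic_given_seed(self):
        params = small_params(n_cells=1000, seed=4)
        t1, _ = run(params)
        t2, _ = run(params)
        np.testing.assert_array_equal(t1.n, t2.n)
        np.testing.assert_array_equal(t1.G, t2.G)


class TestInvariants:
    def test_cascade_fixed_point_after_each_step(self, rng):
        """After a step no functional cell with neighbours sits below theta."""
        params = small_params(n_cells=800, theta=0.5, d=0.15, seed=5)
        state = make_state(params, seed=5)
        graph = build_interaction_graph(state.positions, params.lambda_int)
        for _ in range(8):
            state = step_day(state, graph, params, rng)
            f = graph.functional_fraction(state.alive)
            bad = state.alive & (graph.degree > 0) & (f < params.theta)
            assert not bad.any()

    @pytest.mark.parametrize("field,low,high", [("theta", 0.1, 0.5), ("beta", 0.3, 2.0)])
    def test_pathwise_monotonicity(self, field, low, high):
        """Raising theta never lengthens a paired replicate's life; raising
        beta never shortens it (coupled uniform draws)."""
        diffs = []
        for rep in range(20):
            lows_high = []
            for value in (low, high):
                kw = {field: value}
                p = small_params(n_cells=400, seed=(60, rep), **kw)
                traj, _ = run(p)
                lows_high.append(traj.times[-1])
            diffs.append(lows_high[1] - lows_high[0])
        diffs = np.array(diffs)
        if field == "theta":
            assert (diffs <= 0).all()
        else:
            assert (diffs >= 0).all()

    def test_repair_bookkeeping_is_conservative(self, rng):
        """n_new = n_prev - deaths + revivals at every step when r > 0."""
        params = small_params(n_cells=500, r=0.3, seed=6)
        state = make_state(params, seed=6)
        graph = build_interaction_graph(state.positions, params.lambda_int)
        for _ in range(6):
            new = step_day(state, graph, params, rng)
            died = int((state.alive & ~new.alive).sum())
            revived = int((~state.alive & new.alive).sum())
            assert new.n_live == state.n_live - died + revived
            state = new


class TestMediumTransfer:
    def test_transfer_assigns_donor_level(self):
        params = small_params(n_cells=10)
        donor = make_state(params, seed=1)
        donor.G = 3.2
        recipient = make_state(params, seed=2)
        out = transfer_medium(donor, recipient)
        assert out.G == 3.2
        np.testing.assert_array_equal(out.alive, recipient.alive)

    def test_reception_knockout_ignores_conditioned_medium(self):
        """With c=0 everywhere, a conditioned-medium schedule changes nothing
        relative to fresh medium under the same seed."""
        params = small_params(n_cells=500, seed=8, t_max=10.0)
        out = {}
        for name, policy in (("fresh", "fresh"), ("cm", np.full(12, 5.0))):
            state = make_state(params, c=0.0, seed=8)
            traj, _ = run(params, state, media_policy=policy,
                          rng=np.random.default_rng(8))
            out[name] = traj
        np.testing.assert_array_equal(out["fresh"].n, out["cm"].n)
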