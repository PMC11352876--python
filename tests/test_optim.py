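import math

import numpy as np
import pytest

from szdetect import optim
from szdetect.errors import ConfigurationError


def sphere(x):
    return float(np.sum(x * x))


def bounds2(lo=-5.0, hi=5.0):
    return optim.Bounds(np.full(2, lo), np.full(2, hi))


class TestBounds:
    def test_rejects_inverted(self):
        with pytest.raises(ConfigurationError):
            optim.Bounds(np.array([0.0, 1.0]), np.array([1.0, 0.5]))

    def test_clip_and_sample(self, rng):
        b = bounds2()
        x = b.sample(rng, 50)
        assert np.all(x >= b.lb) and np.all(x <= b.ub)
        np.testing.assert_array_equal(b.clip(np.array([9.0, -9.0])), [5.0, -5.0])


class TestPSOInit:
    def test_paper_swarm_size_nine(self):
        state = optim.pso_init(bounds2(), n=9, seed=0)
        assert len(state.particles) == 9

    def test_positions_within_bounds(self):
        state = optim.pso_init(bounds2(), n=20, seed=1)
        for p in state.particles:
            assert np.all(p.position >= -5.0) and np.all(p.position <= 5.0)
            np.testing.assert_array_equal(p.velocity, 0.0)
            np.testing.assert_array_equal(p.best_position, p.position)

    def test_seeded_determinism(self):
        a = optim.pso_init(bounds2(), n=5, seed=7, objective=sphere)
        b = optim.pso_init(bounds2(), n=5, seed=7, objective=sphere)
        for pa, pb in zip(a.particles, b.particles):
            np.testing.assert_array_equal(pa.position, pb.position)
        assert a.best_value == b.best_value

    def test_global_best_is_best_initial(self):
        state = optim.pso_init(bounds2(), n=9, seed=3, objective=sphere)
        assert state.best_value == min(p.best_value for p in state.particles)


class TestPSOStep:
    def test_fixed_point_at_global_best(self):
        state = optim.pso_init(bounds2(), n=1, seed=0, objective=sphere)
        p = state.particles[0]
        p.position = np.zeros(2)
        p.best_position = np.zeros(2)
        p.best_value = 0.0
        state.best_position = np.zeros(2)
        state.best_value = 0.0
        optim.pso_step(state, sphere, rand_pair=(0.5, 0.5))
        np.testing.assert_array_equal(p.velocity, 0.0)
        np.testing.assert_array_equal(p.position, 0.0)

    def test_hand_case_velocity_update(self):
        # lambda=0.9, c1=c2=2, r1=r2=0.5, x=1, v=0, p=g=0 -> v'=-2, x'=-1
        b = optim.Bounds(np.array([-5.0]), np.array([5.0]))
        state = optim.pso_init(b, n=1, seed=0, inertia=0.9, c1=2.0, c2=2.0)
        p = state.particles[0]
        p.position = np.array([1.0])
        p.velocity = np.array([0.0])
        p.best_position = np.array([0.0])
        p.best_value = 0.0
        state.best_position = np.array([0.0])
        state.best_value = 0.0
        optim.pso_step(state, sphere, rand_pair=(0.5, 0.5))
        assert p.velocity[0] == pytest.approx(-2.0, abs=1e-12)
        assert p.position[0] == pytest.approx(-1.0, abs=1e-12)

    def test_pure_inertia_when_random_terms_zero(self):
        b = bounds2()
        state = optim.pso_init(b, n=1, seed=0, inertia=1.0)
        p = state.particles[0]
        p.position = np.array([0.0, 0.0])
        p.velocity = np.array([0.5, -0.25])
        before = p.position.copy()
        v = p.velocity.copy()
        optim.pso_step(state, sphere, rand_pair=(0.0, 0.0))
        np.testing.assert_allclose(p.position - before, v, atol=1e-15)

    def test_default_coefficients_are_two(self):
        state = optim.pso_init(bounds2(), n=2, seed=0)
        assert state.c1 == 2.0 and state.c2 == 2.0

    def test_nonfinite_objective_warns_and_continues(self):
        state = optim.pso_init(bounds2(), n=2, seed=0, objective=sphere)
        calls = {"n": 0}

        def nasty(x):
            calls["n"] += 1
            return math.nan

        with pytest.warns(RuntimeWarning):
            optim.pso_step(state, nasty)
        assert calls["n"] == 2
        assert math.isfinite(state.best_value)


class TestPSOOptimize:
    def test_history_non_increasing_and_eval_count(self):
        res = optim.pso_optimize(sphere, bounds2(), n=9, max_iter=50, seed=4)
        assert len(res.history) == 51
        assert all(b <= a for a, b in zip(res.history, res.history[1:]))
        assert res.evaluations == 9 * 51
        assert res.best_value == res.history[-1]

    def test_sphere_convergence_rate(self):
        hits = sum(
            optim.pso_optimize(sphere, bounds2(), n=9, max_iter=100, seed=s).best_value < 1e-3
            for s in range(20)
        )
        assert hits >= 19  # >= 95% of 20 seeded runs

    def test_seeded_determinism(self):
        a = optim.pso_optimize(sphere, bounds2(), n=9, max_iter=20, seed=11)
        b = optim.pso_optimize(sphere, bounds2(), n=9, max_iter=20, seed=11)
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.history == b.history

    def test_positions_within_bounds(self):
        res = optim.pso_optimize(sphere, bounds2(), n=9, max_iter=20, seed=2)
        assert np.all(res.best_position >= -5.0) and np.all(res.best_position <= 5.0)


class TestLevyFlight:
    def test_dimension_contract(self):
        assert optim.levy_flight(7, rng=0).shape == (7,)

    def test_deterministic_given_rng(self):
        a = optim.levy_flight(5, rng=np.random.default_rng(3))
        b = optim.levy_flight(5, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_heavy_tails(self):
        rng = np.random.default_rng(0)
        draws = np.concatenate([optim.levy_flight(10_000, rng=rng) for _ in range(10)])
        # clip extreme values so the kurtosis estimate is finite but still >> 3
        z = (draws - draws.mean()) / draws.std()
        kurt = np.mean(z**4)
        assert kurt > 3.0

    @pytest.mark.parametrize("beta", [1.0, 2.5])
    def test_beta_out_of_range(self, beta):
        with pytest.raises(ConfigurationError):
            optim.levy_flight(3, beta=beta)


class TestPOStep:
    def _state(self, positions, t=0, max_iter=10, lo=-100.0, hi=100.0):
        positions = np.asarray(positions, dtype=float)
        dim = positions.shape[1]
        b = optim.Bounds(np.full(dim, lo), np.full(dim, hi))
        state = optim.ParrotState(
            positions=positions.copy(),
            values=np.array([sphere(x) for x in positions]),
            bounds=b,
            best_position=positions[np.argmin([sphere(x) for x in positions])].copy(),
            best_value=min(sphere(x) for x in positions),
            t=t,
            max_iter=max_iter,
            rng=np.random.default_rng(0),
        )
        return state

    def test_foraging_at_best_annihilates_first_term(self):
        # Y == Y_best -> Y' = r * (1 - t/T)^(2t/T) * Y_mean
        state = self._state([[2.0, 2.0], [4.0, 4.0]], t=5, max_iter=10)
        state.best_position = state.positions[0].copy()
        y_mean = state.mean_position.copy()
        r = 0.3
        cand = optim._po_candidate(
            state.positions[0], state, "foraging",
            rand=lambda: r, levy=lambda d: np.ones(d), p_draw=lambda: 0.0,
        )
        expected = r * (1 - 0.5) ** (2 * 0.5) * y_mean
        np.testing.assert_allclose(cand, expected, atol=1e-12)

    def test_staying_identity_with_stubbed_draws(self):
        state = self._state([[1.0, -1.0], [2.0, 2.0]])
        y = state.positions[0].copy()
        cand = optim._po_candidate(
            y, state, "staying",
            rand=lambda: 0.0, levy=lambda d: np.zeros(d), p_draw=lambda: 0.0,
        )
        np.testing.assert_array_equal(cand, y)

    def test_communicating_hand_case(self):
        # P=0.4, rand=0.5, t=0: Y' = 0.1 * (Y - Y_mean); Y=(2,2), Y_mean=(1,1)
        state = self._state([[2.0, 2.0], [0.0, 0.0]], t=0, max_iter=10)
        assert np.allclose(state.mean_position, [1.0, 1.0])
        cand = optim._po_candidate(
            state.positions[0], state, "communicating",
            rand=lambda: 0.5, levy=lambda d: np.zeros(d), p_draw=lambda: 0.4,
        )
        np.testing.assert_allclose(cand, [0.1, 0.1], atol=1e-12)

    def test_fear_at_t0_keeps_position_when_rand_zero(self):
        # t=0: cos(0)*(Ybest-Y)*rand=0 when rand=0; (t/T)^(2/T) = 0 -> Y'=Y
        state = self._state([[3.0, -2.0], [1.0, 1.0]], t=0, max_iter=10)
        y = state.positions[0].copy()
        cand = optim._po_candidate(
            y, state, "fear",
            rand=lambda: 0.0, levy=lambda d: np.zeros(d), p_draw=lambda: 0.0,
        )
        np.testing.assert_allclose(cand, y, atol=1e-12)

    def test_greedy_acceptance_never_worsens(self):
        state = self._state(np.random.default_rng(5).uniform(-50, 50, (6, 3)))
        values_before = state.values.copy()
        optim.po_step(state, sphere)
        assert np.all(state.values <= values_before)

    def test_step_past_max_iter_rejected(self):
        state = self._state([[1.0, 1.0], [2.0, 2.0]], t=10, max_iter=10)
        with pytest.raises(ConfigurationError):
            optim.po_step(state, sphere)


class TestPOOptimize:
    def test_defaults_match_benchmark_settings(self):
        import inspect

        sig = inspect.signature(optim.po_optimize)
        assert sig.parameters["n_agents"].default == 30
        assert sig.parameters["max_iter"].default == 1000

    def test_history_non_increasing_and_eval_count(self):
        b = optim.Bounds(np.full(3, -100.0), np.full(3, 100.0))
        res = optim.po_optimize(sphere, b, n_agents=5, max_iter=40, seed=0)
        assert len(res.history) == 41
        assert all(y <= x for x, y in zip(res.history, res.history[1:]))
        assert res.evaluations == 5 * 41

    def test_sphere_convergence_30d(self):
        b = optim.Bounds(np.full(30, -100.0), np.full(30, 100.0))
        hits = sum(
            optim.po_optimize(sphere, b, n_agents=30, max_iter=200, seed=s).best_value < 1e-2
            for s in range(5)
        )
        assert hits >= 4

    def test_seeded_determinism(self):
        b = optim.Bounds(np.full(4, -10.0), np.full(4, 10.0))
        a = optim.po_optimize(sphere, b, n_agents=6, max_iter=30, seed=9)
        c = optim.po_optimize(sphere, b, n_agents=6, max_iter=30, seed=9)
        np.testing.assert_array_equal(a.best_position, c.best_position)
        assert a.history == c.history

    def test_single_agent_rejected(self):
        with pytest.raises(ConfigurationError):
            optim.po_init(bounds2(), n_agents=1, max_iter=10)


class TestSearchSpace:
    def test_lower_bound_decodes_to_floor_values(self):
        space = optim.SearchSpace()
        decoded = space.decode(np.zeros(3))
        assert decoded == {"learning_rate": pytest.approx(1e-5),
                           "hidden_units": 16,
                           "dropout": pytest.approx(0.1)}

    def test_midpoint_learning_rate_is_geometric_mean(self):
        space = optim.SearchSpace()
        decoded = space.decode(np.array([0.5, 0.5, 0.5]))
        assert decoded["learning_rate"] == pytest.approx(10**-3.5)

    def test_decode_encode_idempotent(self, rng):
        space = optim.SearchSpace()
        for _ in range(20):
            x = rng.uniform(-0.5, 1.5, 3)
            d1 = space.decode(x)
            d2 = space.decode(space.encode(d1))
            assert d2["hidden_units"] == d1["hidden_units"]
            assert d2["learning_rate"] == pytest.approx(d1["learning_rate"], rel=1e-12)
            assert d2["dropout"] == pytest.approx(d1["dropout"], rel=1e-12)

    def test_out_of_bounds_clipped(self):
        space = optim.SearchSpace()
        assert space.decode(np.array([2.0, 2.0, 2.0]))["hidden_units"] == 128

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            optim.SearchSpace().decode(np.zeros(4))
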