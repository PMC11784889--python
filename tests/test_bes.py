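"""Bald Eagle Search: single-step rules, polar offsets, and full runs."""

import numpy as np
import pytest

from besco import BesConfig, Bounds, bes_run
from besco.optimizers import Swarm, bes_polar_offsets, bes_select_space, bes_swoop
from besco.optimizers.bes import (
    search_candidates,
    select_candidates,
    swoop_candidates,
)


def _swarm(positions, objective, bounds):
    positions = np.asarray(positions, dtype=float)
    fitness = np.array([objective(p) for p in positions])
    return Swarm(positions, fitness, bounds)


class TestSelectPhase:
    def test_zero_draw_moves_every_agent_to_best(self, sphere3, box3, zero_rng):
        swarm = _swarm(np.array([[1.0, 1, 1], [2.0, 2, 2], [-3.0, 0, 1]]), sphere3, box3)
        best_before = swarm.best_position
        bes_select_space(swarm, BesConfig(), sphere3, zero_rng)
        # r = 0 makes every candidate exactly P_best; greedy acceptance then
        # replaces every agent that was worse than the incumbent best
        for i in range(len(swarm)):
            assert swarm.fitness[i] <= sphere3(best_before) + 1e-15

    def test_hand_example_one_dimensional(self):
        # P_best=0, P_mean=1, P_i=0, alpha=2, r=1 -> candidate 2.0
        cand = select_candidates(
            positions=np.array([[0.0]]),
            best=np.array([0.0]),
            mean=np.array([1.0]),
            alpha_ctrl=2.0,
            r=np.array([1.0]),
        )
        assert cand[0, 0] == pytest.approx(2.0)

    def test_candidates_clipped_to_box(self, sphere3):
        tight = Bounds(np.full(3, -0.5), np.full(3, 0.5))
        swarm = _swarm(np.full((4, 3), 0.5), sphere3, tight)
        rng = np.random.default_rng(0)
        bes_select_space(swarm, BesConfig(), sphere3, rng)
        assert tight.contains(swarm.positions).all()


class TestPolarOffsets:
    def test_zero_draws_give_zero_offsets(self, zero_rng):
        off = bes_polar_offsets(5, BesConfig(), "search", zero_rng)
        assert not off.raw_x.any() and not off.raw_y.any()
        assert not off.norm_x.any() and not off.norm_y.any()  # 0/0 guard

    @pytest.mark.parametrize("variant", ["search", "swoop"])
    def test_normalisation_bounds(self, variant):
        rng = np.random.default_rng(42)
        for _ in range(100):
            off = bes_polar_offsets(8, BesConfig(), variant, rng)
            assert np.max(np.abs(off.norm_x)) == pytest.approx(1.0)
            assert np.max(np.abs(off.norm_y)) == pytest.approx(1.0)
            assert (np.abs(off.norm_x) <= 1).all() and (np.abs(off.norm_y) <= 1).all()

    def test_swoop_uses_hyperbolic_spiral(self):
        # theta = 1, r = 1 -> raw_x = sinh(1), raw_y = cosh(1)
        assert np.sinh(1.0) == pytest.approx(1.1752011936)
        assert np.cosh(1.0) == pytest.approx(1.5430806348)

        class FixedRNG:
            def __init__(self):
                self.calls = 0

            def uniform(self, low=0.0, high=1.0, size=None):
                self.calls += 1
                if self.calls == 1:  # theta draw: rand * pi * a = 1
                    return np.full(size, 1.0 / (np.pi * 10.0))
                return np.full(size, 1.0 / 1.5)  # radius draw: rand * R * theta = 1

        off = bes_polar_offsets(1, BesConfig(), "swoop", FixedRNG())
        assert off.theta[0] == pytest.approx(1.0)
        assert off.radius[0] == pytest.approx(1.0)
        assert off.raw_x[0] == pytest.approx(np.sinh(1.0))
        assert off.raw_y[0] == pytest.approx(np.cosh(1.0))

    def test_canonical_radius_dialect(self):
        rng = np.random.default_rng(3)
        off = bes_polar_offsets(64, BesConfig(variant="canonical"), "search", rng)
        # canonical radius is theta + R * rand, hence always >= theta
        assert (off.radius >= off.theta).all()


class TestSearchPhase:
    def test_hand_example_two_agents(self):
        # P = (0, 4), P_mean = 2, y = 0.5, x = 1:
        # candidate_1 = 0 + 0.5*(0-4) + 1*(0-2) = -4
        cand = search_candidates(
            positions=np.array([[0.0], [4.0]]),
            mean=np.array([2.0]),
            x=np.array([1.0, 1.0]),
            y=np.array([0.5, 0.5]),
        )
        assert cand[0, 0] == pytest.approx(-4.0)

    def test_zero_offsets_keep_positions(self):
        pos = np.array([[1.0, 2.0], [3.0, -1.0]])
        cand = search_candidates(pos, pos.mean(axis=0), np.zeros(2), np.zeros(2))
        np.testing.assert_allclose(cand, pos)

    def test_single_agent_neighbour_term_is_zero(self):
        pos = np.array([[2.0, 2.0]])
        cand = search_candidates(pos, np.array([1.0, 1.0]), np.array([0.5]), np.array([9.9]))
        np.testing.assert_allclose(cand, pos + 0.5 * (pos - np.array([1.0, 1.0])))


class TestSwoopPhase:
    def test_offsets_vanish_rand_one_gives_best(self):
        pos = np.array([[3.0, 3.0], [-2.0, 1.0]])
        best = np.array([0.5, -0.5])
        cand = swoop_candidates(
            pos, best, pos.mean(axis=0),
            x1=np.zeros(2), y1=np.zeros(2), rand=np.ones(2),
            c1=np.ones(2), c2=np.ones(2),
        )
        np.testing.assert_allclose(cand, np.tile(best, (2, 1)))

    def test_offsets_vanish_rand_zero_gives_origin(self):
        pos = np.array([[3.0, 3.0]])
        cand = swoop_candidates(
            pos, np.array([1.0, 1.0]), pos.mean(axis=0),
            x1=np.zeros(1), y1=np.zeros(1), rand=np.zeros(1),
            c1=np.ones(1), c2=np.ones(1),
        )
        np.testing.assert_allclose(cand, np.zeros((1, 2)))

    def test_greedy_keeps_best_when_candidates_worse(self, sphere3, box3):
        # a swarm already at the optimum cannot be displaced
        swarm = _swarm(np.zeros((3, 3)), sphere3, box3)
        rng = np.random.default_rng(7)
        bes_swoop(swarm, BesConfig(), sphere3, rng)
        assert swarm.best_fitness == 0.0


class TestBesRun:
    def test_zero_iterations_returns_initial_best(self, sphere3, box3):
        cfg = BesConfig(pop_size=12, max_iter=0)
        res = bes_run(sphere3, box3, cfg, np.random.default_rng(1))
        assert res.trace.size == 1
        assert res.n_evaluations == 12
        assert res.best_fitness == pytest.approx(sphere3(res.best_position))

    def test_evaluation_count(self, sphere3, box3):
        cfg = BesConfig(pop_size=7, max_iter=5)
        res = bes_run(sphere3, box3, cfg, np.random.default_rng(2))
        assert res.n_evaluations == 7 * (1 + 3 * 5)
        assert res.trace.size == 5 + 1

    def test_monotone_improvement(self, sphere3, box3):
        res = bes_run(sphere3, box3, BesConfig(pop_size=20, max_iter=30),
                      np.random.default_rng(3))
        assert (np.diff(res.trace) <= 0).all()
        assert res.best_fitness <= res.trace[0]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BesConfig(alpha_ctrl=1.0)
        with pytest.raises(ValueError):
            BesConfig(a_angle=3.0)
        with pytest.raises(ValueError):
            BesConfig(R_radius=3.0)
        with pytest.raises(ValueError):
            BesConfig(variant="nope")
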