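"""IDMO optimizer: phase mechanics, schedules, convergence, determinism."""

import numpy as np
import pytest

from pdfuse import idmo
from pdfuse.idmo import IDMOConfig


def box(d, lo=-5.0, hi=5.0):
    return np.full(d, lo), np.full(d, hi)


class TestInit:
    def test_positions_within_bounds_and_deterministic(self):
        cfg = IDMOConfig(n=10, seed=4)
        p1 = idmo.init_population(cfg, idmo.sphere, box(3, 0, 1))
        p2 = idmo.init_population(cfg, idmo.sphere, box(3, 0, 1))
        assert np.all((p1.positions >= 0) & (p1.positions <= 1))
        assert np.array_equal(p1.positions, p2.positions)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower bound"):
            idmo.init_population(IDMOConfig(), idmo.sphere,
                                 (np.array([0.0, 1.0]), np.array([1.0, 1.0])))

    def test_uniform_mean_law_of_large_numbers(self):
        cfg = IDMOConfig(n=100, seed=0)
        pop = idmo.init_population(cfg, idmo.sphere, box(100, 0, 1))
        assert abs(pop.positions.mean() - 0.5) < 0.02


class TestSelectAlpha:
    def test_argmin_and_tie_rule(self):
        cfg = IDMOConfig(n=4, seed=0)
        pop = idmo.init_population(cfg, idmo.sphere, box(2, 0, 1))
        pop.fitness = np.array([3.0, 1.0, 2.0, 9.0])
        assert idmo.select_alpha(pop) == 1
        pop.fitness = np.array([5.0, 5.0, 5.0, 5.0])
        assert idmo.select_alpha(pop) == 0

    def test_matches_linear_scan(self, rng):
        cfg = IDMOConfig(n=100, seed=1)
        pop = idmo.init_population(cfg, idmo.sphere, box(2, 0, 1))
        pop.fitness = rng.random(100)
        best = 0
        for i in range(100):
            if pop.fitness[i] < pop.fitness[best]:
                best = i
        assert idmo.select_alpha(pop) == best

    def test_nan_fitness_rejected(self):
        cfg = IDMOConfig(n=4, seed=0)
        pop = idmo.init_population(cfg, idmo.sphere, box(2, 0, 1))
        pop.fitness[1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            idmo.select_alpha(pop)


class TestSchedules:
    def test_omega_endpoints(self):
        assert idmo.omega(0, 100) == 1.0
        assert np.isclose(idmo.omega(100, 100), np.exp(-4.0))

    def test_cf_endpoints(self):
        assert idmo.babysitter_cf(0, 100) == 1.0
        assert idmo.babysitter_cf(100, 100) == 0.0


class TestPhases:
    def test_collapsed_population_stays_collapsed(self):
        cfg = IDMOConfig(n=6, seed=0)
        pop = idmo.init_population(cfg, idmo.sphere, box(3))
        pop.positions[:] = pop.positions[0]
        pop.fitness[:] = idmo.sphere(pop.positions[0])
        pop.max_iter = 10
        before = pop.positions.copy()
        idmo.alpha_phase(pop, cfg, idmo.sphere)
        assert np.allclose(pop.positions, before)

    def test_greedy_acceptance_never_worsens_best(self):
        cfg = IDMOConfig(n=8, seed=3)
        pop = idmo.init_population(cfg, idmo.rastrigin, box(4))
        pop.max_iter = 10
        for phase in (idmo.alpha_phase, idmo.scout_phase):
            before = pop.fitness.min()
            phase(pop, cfg, idmo.rastrigin)
            assert pop.fitness.min() <= before + 1e-15

    def test_scout_candidate_symmetric_about_alpha(self):
        cfg = IDMOConfig(n=30, seed=9)
        pop = idmo.init_population(cfg, idmo.sphere, box(1, -1, 1))
        pop.max_iter = 10
        deltas = []
        alpha = pop.positions[pop.alpha_index].copy()
        for _ in range(10_000):
            cand = idmo._propose_scout(pop, cfg, 0)
            deltas.append(cand[0] - alpha[0])
        deltas = np.array(deltas)
        se = deltas.std() / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se

    def test_babysitter_br_zero_leaves_position(self):
        cfg = IDMOConfig(n=6, seed=1, br=0.0, babysitter_timer=1)
        pop = idmo.init_population(cfg, idmo.sphere, box(3))
        pop.max_iter = 10
        before = pop.positions.copy()
        idmo.babysitter_phase(pop, cfg, idmo.sphere)
        assert np.allclose(pop.positions, before)

    def test_exchange_schedule_timer_three(self):
        cfg = IDMOConfig(n=9, max_iter=10, seed=2, babysitter_timer=3)
        _, _, trace = idmo.optimize(idmo.sphere, box(3), cfg)
        exchanged_at = trace.loc[trace.exchanged, "iteration"].tolist()
        assert exchanged_at == [3, 6, 9]


class TestOptimize:
    def test_sphere_converges(self):
        cfg = IDMOConfig(n=30, max_iter=100, seed=1)
        _, best, trace = idmo.optimize(idmo.sphere, box(5), cfg)
        assert best < 1e-2
        assert np.all(np.diff(trace.best_fitness) <= 1e-15)

    def test_constant_objective_and_feasibility(self):
        calls = []

        def const(x):
            calls.append(x.copy())
            return 1.0

        cfg = IDMOConfig(n=6, max_iter=5, seed=0)
        best_x, best, trace = idmo.optimize(const, box(3, -2, 2), cfg)
        assert best == 1.0
        assert trace.best_fitness.nunique() == 1
        assert np.all(np.abs(best_x) <= 2)
        for x in calls:
            assert np.all((x >= -2) & (x <= 2))

    def test_evaluation_budget_and_accounting(self):
        count = {"n": 0}

        def counted(x):
            count["n"] += 1
            return idmo.sphere(x)

        cfg = IDMOConfig(n=12, max_iter=20, seed=5)
        _, _, trace = idmo.optimize(counted, box(3), cfg)
        assert trace.evaluations.iloc[-1] == count["n"]
        assert count["n"] <= cfg.n * (2 * cfg.max_iter + 1)

    def test_seed_determinism_of_full_trace(self):
        cfg = IDMOConfig(n=10, max_iter=15, seed=8)
        _, b1, t1 = idmo.optimize(idmo.rastrigin, box(3), cfg)
        _, b2, t2 = idmo.optimize(idmo.rastrigin, box(3), cfg)
        assert b1 == b2
        assert t1.equals(t2)

    def test_nan_objective_reported_with_position(self):
        def bad(x):
            return np.nan

        with pytest.raises(ValueError, match="position"):
            idmo.optimize(bad, box(2), IDMOConfig(n=4, max_iter=2, seed=0))

    def test_beats_random_search_on_rastrigin(self):
        im, rs = [], []
        for seed in range(20):
            cfg = IDMOConfig(n=30, max_iter=200, seed=seed)
            _, best, trace = idmo.optimize(idmo.rastrigin, box(2, -5.12, 5.12), cfg)
            _, rbest = idmo.random_search(
                idmo.rastrigin, box(2, -5.12, 5.12),
                int(trace.evaluations.iloc[-1]), seed=seed)
            im.append(best)
            rs.append(rbest)
        assert np.median(im) < np.median(rs)
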