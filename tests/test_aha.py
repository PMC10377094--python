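"""Hummingbird optimizer: foraging mechanics, invariants and convergence
against closed-form optima."""

import numpy as np
import pytest
from scipy import stats

from oralfuse import (
    AHAConfig,
    guided_forage,
    initialize_swarm,
    migration_forage,
    run_aha,
    sample_direction,
    territorial_forage,
)
from oralfuse.aha import EvaluationError


def sphere(x):
    return -float(np.sum(np.asarray(x) ** 2))


class _ZeroNormalRng:
    """Delegates to a real generator but forces N(0,1) draws to zero, so the
    guiding/territorial factor is pinned at a = b = 0."""

    def __init__(self, seed=0):
        self._rng = np.random.default_rng(seed)

    def standard_normal(self, *a, **k):
        return 0.0

    def __getattr__(self, name):
        return getattr(self._rng, name)


class TestInitialization:
    def test_shapes_and_zeroed_visit_table(self):
        cfg = AHAConfig(dimension=10, lower=-1, upper=1, n_birds=25, max_iter=10, seed=0)
        state = initialize_swarm(cfg, sphere)
        assert state.positions.shape == (25, 10)
        assert state.visit_table.shape == (25, 25)
        off_diag = state.visit_table[~np.eye(25, dtype=bool)]
        assert np.all(off_diag == 0)
        assert state.evaluations == 25

    def test_positions_within_bounds(self):
        cfg = AHAConfig(dimension=3, lower=2.0, upper=5.0, n_birds=6, max_iter=10, seed=1)
        state = initialize_swarm(cfg, sphere)
        assert np.all(state.positions >= 2.0) and np.all(state.positions <= 5.0)

    def test_degenerate_box_collapses_to_lower_bound(self):
        eps = 1e-12
        cfg = AHAConfig(dimension=4, lower=3.0, upper=3.0 + eps, n_birds=5, max_iter=10)
        state = initialize_swarm(cfg, sphere)
        assert np.allclose(state.positions, 3.0, atol=1e-10)

    def test_fixed_seed_reproducible(self):
        cfg = AHAConfig(dimension=5, lower=0, upper=1, n_birds=8, max_iter=10, seed=9)
        a = initialize_swarm(cfg, sphere)
        b = initialize_swarm(cfg, sphere)
        assert np.array_equal(a.positions, b.positions)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            AHAConfig(dimension=2, lower=1.0, upper=0.0)
        with pytest.raises(ValueError):
            AHAConfig(dimension=2, lower=0, upper=np.inf)
        with pytest.raises(ValueError):
            AHAConfig(dimension=2, n_birds=1)


class TestDirections:
    def test_one_dimension_collapses_to_all_ones(self, rng):
        for _ in range(10):
            d = sample_direction(1, rng)
            assert d.D.tolist() == [1.0]

    def test_omnidirectional_is_all_ones(self, rng):
        d = sample_direction(7, rng, mode="omnidirectional")
        assert np.all(d.D == 1)

    def test_axial_sets_exactly_one_uniform_coordinate(self, rng):
        """Chi-square uniformity of the active axis over 10,000 draws."""
        counts = np.zeros(5)
        for _ in range(10_000):
            d = sample_direction(5, rng, mode="axial")
            assert d.D.sum() == 1
            counts[np.argmax(d.D)] += 1
        _, p = stats.chisquare(counts)
        assert p > 1e-3

    def test_diagonal_activates_between_two_and_d_minus_one(self, rng):
        for _ in range(200):
            d = sample_direction(8, rng, mode="diagonal")
            assert 2 <= int(d.D.sum()) <= 7

    def test_mode_probabilities_respected(self, rng):
        modes = [
            sample_direction(6, rng, probabilities=(1.0, 0.0, 0.0)).mode
            for _ in range(50)
        ]
        assert set(modes) == {"axial"}


class TestForaging:
    def _state(self, cfg, seed=0):
        return initialize_swarm(cfg, sphere, np.random.default_rng(seed))

    def test_guided_with_zero_factor_lands_on_target(self):
        """a = 0 makes the candidate exactly the target source; foraging
        from the worst bird, the zeroed visit table targets the fittest
        source, which is accepted verbatim."""
        cfg = AHAConfig(dimension=3, lower=-4, upper=4, n_birds=4, max_iter=10, seed=0)
        state = self._state(cfg)
        before = state.positions.copy()
        i = int(np.argmin(state.fitness))
        tar = int(np.argmax(state.fitness))
        guided_forage(state, i, _ZeroNormalRng(), sphere, cfg)
        assert np.array_equal(state.positions[i], before[tar])
        assert state.fitness[i] == state.fitness[tar]

    def test_worse_candidate_leaves_bird_unchanged(self):
        cfg = AHAConfig(dimension=2, lower=-4, upper=4, n_birds=3, max_iter=10, seed=2)
        state = self._state(cfg, seed=2)
        # place bird 0 exactly at the optimum: every candidate is worse/equal
        state.positions[0] = np.zeros(2)
        state.fitness[0] = sphere(state.positions[0])
        rng = np.random.default_rng(5)
        for _ in range(30):
            territorial_forage(state, 0, rng, sphere, cfg)
            assert state.fitness[0] == 0.0
            # multiplicative move at the origin is a fixed point
            assert np.array_equal(state.positions[0], np.zeros(2))

    def test_territorial_zero_factor_is_identity(self):
        cfg = AHAConfig(dimension=3, lower=-4, upper=4, n_birds=4, max_iter=10, seed=3)
        state = self._state(cfg, seed=3)
        before = state.positions.copy()
        territorial_forage(state, 1, _ZeroNormalRng(), sphere, cfg)
        assert np.allclose(state.positions[1], before[1])

    def test_repeated_foraging_never_decreases_best(self):
        cfg = AHAConfig(dimension=4, lower=-3, upper=3, n_birds=5, max_iter=10, seed=4)
        state = self._state(cfg, seed=4)
        rng = np.random.default_rng(6)
        best = state.best_fitness
        for t in range(100):
            i = t % 5
            if t % 2:
                guided_forage(state, i, rng, sphere, cfg)
            else:
                territorial_forage(state, i, rng, sphere, cfg)
            assert state.best_fitness >= best
            best = state.best_fitness
            assert np.all(state.positions >= -3) and np.all(state.positions <= 3)

    def test_visit_table_protocol(self):
        cfg = AHAConfig(dimension=2, lower=-1, upper=1, n_birds=3, max_iter=10, seed=5)
        state = self._state(cfg, seed=5)
        guided_forage(state, 0, np.random.default_rng(0), sphere, cfg)
        row = state.visit_table[0]
        # one counter reset (the visited target), the other incremented
        assert sorted(row[[1, 2]].tolist()) == [0.0, 1.0]
        off_diag = state.visit_table[~np.eye(3, dtype=bool)]
        assert np.all(off_diag >= 0)


class TestMigration:
    def test_worst_bird_reseeded_within_bounds_and_best_kept(self):
        cfg = AHAConfig(dimension=2, lower=-5, upper=5, n_birds=2, max_iter=10, seed=6)
        state = initialize_swarm(cfg, sphere, np.random.default_rng(6))
        state.positions[0] = np.zeros(2)  # optimum
        state.fitness[0] = 0.0
        state.best_position = state.positions[0].copy()
        state.best_fitness = 0.0
        rng = np.random.default_rng(7)
        for _ in range(10):
            migration_forage(state, rng, sphere, cfg)
            assert state.fitness[0] == 0.0  # optimal bird never migrates
            assert np.all(np.abs(state.positions) <= 5)
            assert state.best_fitness == 0.0


class TestRunAHA:
    def test_quadratic_optimum_recovered_across_seeds(self):
        """Closed-form argmax of -(x-3)^2 on [0, 10] is 3; at least 9/10
        seeds must land within 0.05."""
        hits = 0
        for s in range(10):
            res = run_aha(
                lambda x: -((x[0] - 3.0) ** 2),
                AHAConfig(dimension=1, lower=0, upper=10, n_birds=25, max_iter=200, seed=s),
            )
            hits += abs(res.best_position[0] - 3.0) < 0.05
        assert hits >= 9

    def test_sphere_reaches_near_zero(self):
        hits = 0
        for s in range(10):
            res = run_aha(
                sphere,
                AHAConfig(dimension=2, lower=-5, upper=5, n_birds=25, max_iter=500, seed=s),
            )
            hits += res.best_fitness >= -1e-2
        assert hits >= 9

    def test_trace_monotone_and_budget_respected(self):
        for s in range(5):
            cfg = AHAConfig(dimension=3, lower=-2, upper=2, n_birds=10, max_iter=50, seed=s)
            res = run_aha(sphere, cfg)
            assert np.all(np.diff(res.trace) >= 0)
            assert len(res.trace) == 51
            assert res.evaluations <= (cfg.max_iter + 1) * cfg.n_birds

    def test_deterministic_given_seed(self):
        cfg = AHAConfig(dimension=2, lower=-1, upper=1, n_birds=5, max_iter=30, seed=11)
        a = run_aha(sphere, cfg)
        b = run_aha(sphere, cfg)
        assert np.array_equal(a.best_position, b.best_position)
        assert np.array_equal(a.trace, b.trace)

    def test_non_finite_objective_reported_with_bird_index(self):
        def bad(x):
            return float("nan")

        with pytest.raises(EvaluationError, match="bird"):
            run_aha(bad, AHAConfig(dimension=1, lower=0, upper=1, n_birds=3, max_iter=5))
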