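"""RSA-Gbest optimizer: component formulas, phases, elitism, oracle recovery."""

import numpy as np
import pytest

from rsathresh.objectives import exhaustive_search
from rsathresh.rsa import (
    OptimizerConfig,
    SearchBounds,
    decode_thresholds,
    evolutionary_sense,
    gbest_update,
    init_population,
    mean_position,
    optimize,
    percentage_difference,
    phase_of,
    phase_update,
    reduction_function,
)
from rsathresh.synthetic import delta_histogram


class _StubRng:
    """Deterministic generator stand-in for substitution checks."""

    def __init__(self, uniform_value=0.0, index=0):
        self.uniform_value = uniform_value
        self.index = index

    def random(self, n=None):
        return np.full(n, self.uniform_value) if n is not None else self.uniform_value

    def integers(self, lo, hi, size=None):
        return np.full(size, self.index, dtype=int) if size is not None else self.index

    def uniform(self, lo, hi):
        return self.uniform_value


class TestComponentFormulas:
    @pytest.mark.parametrize(
        "t, T, r3, expect",
        [(100, 100, 0.7, 0.0), (0, 100, 1.0, 2.0), (50, 100, -0.5, -0.5)],
    )
    def test_evolutionary_sense(self, t, T, r3, expect):
        assert evolutionary_sense(t, T, r3) == pytest.approx(expect)

    @pytest.mark.parametrize(
        "best, x, eps, expect",
        [(3.0, 3.0, 1e-10, 0.0), (1.0, 0.0, 1e-10, 1.0), (2.0, 5.0, 0.1, -3 / 2.1)],
    )
    def test_reduction_function(self, best, x, eps, expect):
        assert reduction_function(best, x, eps) == pytest.approx(expect, abs=1e-9)

    def test_percentage_difference(self):
        b = SearchBounds(0.0, 10.0, 2)
        # x at the candidate mean → P collapses to α
        assert percentage_difference(3.0, 3.0, 1.0, b, 0.1, 1e-10) == pytest.approx(0.1)
        assert percentage_difference(5.0, 3.0, 1.0, b, 0.1, 0.0) == pytest.approx(0.3)
        above = percentage_difference(5.0, 3.0, 1.0, b, 0.1, 0.0)
        below = percentage_difference(1.0, 3.0, 1.0, b, 0.1, 0.0)
        assert above > 0.1 > below

    def test_mean_position(self, rng):
        assert mean_position(np.array([3.0, 3.0, 3.0])) == 3.0
        assert mean_position(np.array([0.0, 10.0])) == 5.0
        v = rng.random(17)
        assert mean_position(v) == pytest.approx(sum(v) / len(v))


class TestPhases:
    def test_phase_windows(self):
        T = 100
        assert phase_of(1, T) == "high_walk"
        assert phase_of(25, T) == "high_walk"
        assert phase_of(26, T) == "belly_walk"
        assert phase_of(30, T) == "belly_walk"  # t=30 → belly-walk branch
        assert phase_of(50, T) == "belly_walk"
        assert phase_of(51, T) == "hunt_coordination"
        assert phase_of(75, T) == "hunt_coordination"
        assert phase_of(76, T) == "hunt_cooperation"
        assert phase_of(100, T) == "hunt_cooperation"

    def test_cooperation_converges_to_leader(self):
        # with η = 0 (forced via α=0 and x at the mean) and rand = 0 the
        # cooperation move lands exactly on best_j
        cfg = OptimizerConfig(population=2, iterations=4, alpha=0.0, epsilon=1e-10)
        positions = np.full((2, 3), 5.0)
        best = np.array([5.0, 100.0, 200.0])
        new = phase_update(
            0, positions, best, 4, 4, cfg, SearchBounds(1.0, 255.0, 3), _StubRng(0.0)
        )
        np.testing.assert_allclose(new, best, atol=1e-7)

    def test_positions_stay_in_bounds(self, rng):
        cfg = OptimizerConfig(population=5, iterations=8)
        b = SearchBounds(1.0, 255.0, 4)
        positions = rng.random((5, 4)) * 254 + 1
        best = positions[0]
        for t in range(1, 9):
            for i in range(5):
                new = phase_update(i, positions, best, t, 8, cfg, b, rng)
                assert (new >= b.lower).all() and (new <= b.upper).all()


class TestGbestUpdate:
    def test_fixed_point(self):
        x = np.array([10.0, 20.0])
        v, x2 = gbest_update(
            x, np.zeros(2), x, x, 0.5, 2.0, 2.0, SearchBounds(1, 255, 2), _StubRng(0.5)
        )
        np.testing.assert_array_equal(v, 0.0)
        np.testing.assert_array_equal(x2, x)

    def test_velocity_substitution(self):
        # v' = w·v + c1·r·(Pbest−x) + c2·r·(Gbest−x) = 0.5 + 2 + 4 = 6.5
        x = np.array([0.0])
        v, x2 = gbest_update(
            x,
            np.array([1.0]),
            np.array([2.0]),
            np.array([4.0]),
            0.5,
            2.0,
            2.0,
            SearchBounds(-100, 100, 1),
            _StubRng(0.5),
        )
        assert v[0] == pytest.approx(6.5)
        assert x2[0] == pytest.approx(6.5)


class TestInitPopulation:
    def test_bounds_and_shape(self, rng):
        cfg = OptimizerConfig(population=25, iterations=100)
        pop = init_population(cfg, SearchBounds(1.0, 255.0, 5), rng)
        assert pop.positions.shape == (25, 5)
        assert (pop.positions >= 1.0).all() and (pop.positions <= 255.0).all()
        np.testing.assert_array_equal(pop.velocities, 0.0)
        np.testing.assert_array_equal(pop.pbest, pop.positions)

    def test_seed_determinism(self):
        cfg = OptimizerConfig(population=10, iterations=4)
        a = init_population(cfg, SearchBounds(1, 255, 3), np.random.default_rng(42))
        b = init_population(cfg, SearchBounds(1, 255, 3), np.random.default_rng(42))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(population=1)
        with pytest.raises(ValueError):
            OptimizerConfig(iterations=3)
        with pytest.raises(ValueError):
            OptimizerConfig(epsilon=0.0)


class TestDecodeThresholds:
    @pytest.mark.parametrize(
        "pos, expect",
        [
            ((200.4, 63.7), (64, 200)),
            ((100.2, 99.8), (100, 101)),
            ((-5.0, 300.0), (1, 255)),
            ((128.0,), (128,)),
            ((255.0, 255.0, 254.8), (253, 254, 255)),  # wrap downward at the top
        ],
    )
    def test_examples(self, pos, expect):
        assert decode_thresholds(np.array(pos)).values == expect

    def test_always_valid(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 8))
            pos = rng.uniform(-50, 350, size=n)
            tv = decode_thresholds(pos)
            assert len(tv.values) == n
            assert all(1 <= v <= 255 for v in tv.values)
            assert all(a < b for a, b in zip(tv.values, tv.values[1:]))

    def test_infeasible_dimension(self):
        with pytest.raises(ValueError):
            decode_thresholds(np.ones(255))


class TestOptimize:
    def test_constant_objective(self, two_delta_hist):
        cfg = OptimizerConfig(population=5, iterations=8, seed=0)
        tv, fitness, trace = optimize(two_delta_hist, 2, lambda t: 7.0, cfg)
        assert fitness == 7.0
        assert trace.best_fitness == [7.0] * 8
        assert len(tv.values) == 2

    def test_seed_determinism(self, two_delta_hist):
        cfg = OptimizerConfig(population=10, iterations=20)
        a = optimize(two_delta_hist, 2, "otsu", cfg, seed=99)
        b = optimize(two_delta_hist, 2, "otsu", cfg, seed=99)
        assert a[0].values == b[0].values
        assert a[1] == b[1]
        assert a[2].best_fitness == b[2].best_fitness

    def test_monotone_best_so_far(self, two_delta_hist):
        cfg = OptimizerConfig(population=8, iterations=40, seed=3)
        _, _, trace = optimize(two_delta_hist, 3, "kapur", cfg)
        bf = trace.best_fitness
        assert all(x <= y for x, y in zip(bf, bf[1:]))
        assert len(trace.phase) == 40

    def test_recovers_two_delta_optimum(self):
        """Mass at 60 and 200, k=1: the stochastic search should find the
        exhaustive optimum in nearly every seeded run."""
        h = delta_histogram([60, 200], [0.5, 0.5], 100)
        _, opt = exhaustive_search(h, 1, "otsu")
        cfg = OptimizerConfig(population=15, iterations=40)
        hits = sum(
            optimize(h, 1, "otsu", cfg, seed=s)[1] >= opt - 1e-9 for s in range(30)
        )
        assert hits >= 27

    def test_trace_records_gbest(self, two_delta_hist):
        cfg = OptimizerConfig(population=5, iterations=8, seed=1)
        tv, fitness, trace = optimize(two_delta_hist, 1, "otsu", cfg)
        assert trace.gbest_fitness == fitness
        assert trace.best_fitness[-1] == fitness
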