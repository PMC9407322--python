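"""RSA/MRSA mechanics, Tent map, Gaussian random walk, GA/PSO baselines."""

import numpy as np
import pytest

from jujubespec.optimize import (
    OptimizerResult,
    Population,
    RsaParams,
    SearchSpace,
    baseline_minimize,
    gaussian_walk_step,
    mrsa_minimize,
    rsa_minimize,
    tent_initialize,
    tent_sequence,
)


def sphere(x):
    return float(np.sum(x**2))


def rastrigin(x):
    return float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))


SPACE2 = SearchSpace([-10.0, -10.0], [10.0, 10.0])


class TestTentMap:
    def test_orbit_from_0_3(self):
        z = 0.3
        expected = [0.6, 0.8, 0.4, 0.8]
        for e in expected:
            z = 2 * z if z <= 0.5 else 2 * (1 - z)
            assert z == pytest.approx(e)

    def test_absorbing_state_reseeded(self):
        # a deterministic sequence never collapses onto the 0.5 -> 1 -> 0 orbit
        Z = tent_sequence(200, 3, seed=0)
        assert not np.any(np.isin(Z[1:], [0.0, 0.5, 1.0]))

    def test_range_and_shape(self):
        Z = tent_sequence(50, 4, seed=1)
        assert Z.shape == (50, 4)
        assert np.all((Z >= 0) & (Z <= 1))

    def test_map_applied_rowwise(self):
        Z = tent_sequence(10, 2, seed=2)
        for i in range(1, 10):
            prev = Z[i - 1]
            stepped = np.where(prev <= 0.5, 2 * prev, 2 * (1 - prev))
            # equal unless the entry hit an absorbing state and was re-seeded
            hit = np.isin(stepped, [0.0, 0.5, 1.0])
            assert np.allclose(Z[i][~hit], stepped[~hit])


class TestTentInitialize:
    def test_unit_box_is_raw_tent(self):
        space = SearchSpace([0.0, 0.0], [1.0, 1.0])
        pop = tent_initialize(space, 8, seed=5)
        assert np.array_equal(pop.positions, tent_sequence(8, 2, seed=5))

    def test_bounds_respected(self):
        space = SearchSpace([-5.0, 0.25], [5.0, 256.0])
        pop = tent_initialize(space, 30, seed=6)
        assert np.all(pop.positions >= space.lower)
        assert np.all(pop.positions <= space.upper)

    def test_seeded_determinism(self):
        space = SearchSpace([-1.0], [1.0])
        a = tent_initialize(space, 5, seed=7).positions
        b = tent_initialize(space, 5, seed=7).positions
        assert np.array_equal(a, b)


class TestRsa:
    def test_constant_objective(self):
        res = rsa_minimize(lambda x: 3.0, SPACE2, RsaParams(seed=0, max_iters=12))
        assert res.best_fitness == 3.0
        assert np.all(res.trace == 3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("fn", [sphere, rastrigin])
    def test_trace_non_increasing_and_bounds(self, seed, fn):
        res = rsa_minimize(fn, SPACE2, RsaParams(seed=seed, max_iters=20))
        assert np.all(np.diff(res.trace) <= 0)
        assert np.all(res.best_position >= SPACE2.lower)
        assert np.all(res.best_position <= SPACE2.upper)

    def test_evaluation_budget(self):
        p = RsaParams(n_candidates=7, max_iters=10, seed=0)
        res = rsa_minimize(sphere, SPACE2, p)
        assert res.evaluations == 7 * 11  # init + one batch per iteration
        res_m = mrsa_minimize(sphere, SPACE2, p)
        assert res_m.evaluations == 7 * 21  # plus one walk batch per iteration

    def test_seeded_determinism(self):
        p = RsaParams(seed=3, max_iters=15)
        a = rsa_minimize(rastrigin, SPACE2, p)
        b = rsa_minimize(rastrigin, SPACE2, p)
        assert np.array_equal(a.trace, b.trace)
        assert np.array_equal(a.best_position, b.best_position)

    def test_non_finite_objective_warns(self):
        def nasty(x):
            return np.nan if x[0] > 0 else sphere(x)

        with pytest.warns(UserWarning, match="non-finite"):
            res = rsa_minimize(nasty, SPACE2, RsaParams(seed=1, max_iters=8))
        assert np.isfinite(res.best_fitness)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            RsaParams(n_candidates=1)
        with pytest.raises(ValueError):
            RsaParams(max_iters=3)
        with pytest.raises(ValueError):
            RsaParams(alpha=0.0)


class TestGaussianWalk:
    def _pop(self, rng):
        X = rng.random((6, 2)) * 4 - 2
        fit = np.array([sphere(x) for x in X])
        i = int(np.argmin(fit))
        return Population(X, fit, X[i].copy(), float(fit[i]))

    def test_tau_zero_at_best_and_iteration_one(self):
        rng = np.random.default_rng(0)
        pop = self._pop(rng)
        # G = 1 -> log 1 = 0 -> pure deterministic attraction step
        scale = np.log(1) / 1
        assert scale == 0.0
        tau = np.abs(scale * (pop.positions - pop.best_position))
        assert np.all(tau == 0.0)
        # the best individual's own tau is zero at any iteration
        i = int(np.argmin(pop.fitness))
        tau5 = np.abs(np.log(5) / 5 * (pop.positions[i] - pop.best_position))
        assert np.all(tau5 == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_greedy_acceptance_never_worsens(self, seed):
        rng = np.random.default_rng(seed)
        pop = self._pop(rng)
        before = pop.best_fitness
        walked, n_eval = gaussian_walk_step(pop, sphere, iteration=3, rng=rng)
        assert walked.best_fitness <= before
        assert np.all(walked.fitness <= pop.fitness)
        assert n_eval == pop.positions.shape[0]


class TestMrsa:
    def test_switch_off_equivalence_with_rsa(self):
        p = RsaParams(seed=7)
        a = rsa_minimize(sphere, SPACE2, p)
        b = mrsa_minimize(sphere, SPACE2, p, use_tent=False, use_grw=False)
        assert np.array_equal(a.trace, b.trace)
        assert np.array_equal(a.best_position, b.best_position)

    def test_trace_non_increasing(self):
        res = mrsa_minimize(rastrigin, SPACE2, RsaParams(seed=2, max_iters=25))
        assert np.all(np.diff(res.trace) <= 0)

    def test_printed_es_variant_runs(self):
        p = RsaParams(seed=1, max_iters=8, es_printed=True, es_integer_r3=True)
        res = mrsa_minimize(sphere, SPACE2, p)
        assert np.isfinite(res.best_fitness)


class TestBaselines:
    def test_pso_constant_objective_never_worsens(self):
        res = baseline_minimize("pso", lambda x: 1.0, SPACE2, n=10, iters=10, seed=0)
        assert res.best_fitness == 1.0
        assert np.all(res.trace == 1.0)

    @pytest.mark.parametrize("method", ["ga", "pso"])
    def test_elitism_monotone_trace(self, method):
        res = baseline_minimize(method, rastrigin, SPACE2, seed=4)
        assert np.all(np.diff(res.trace) <= 0)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown baseline"):
            baseline_minimize("annealing", sphere, SPACE2)


class TestSearchSpace:
    def test_validation(self):
        with pytest.raises(ValueError):
            SearchSpace([1.0], [1.0])
        with pytest.raises(ValueError):
            SearchSpace([0.0, 0.0], [1.0])

    def test_clip(self):
        s = SearchSpace([0.0, 0.0], [1.0, 2.0])
        out = s.clip(np.array([[-1.0, 5.0], [0.5, 0.5]]))
        assert np.array_equal(out, [[0.0, 2.0], [0.5, 0.5]])
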