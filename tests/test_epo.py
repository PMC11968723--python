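"""Unit and property tests for the continuous EPO optimizer."""

import math

import numpy as np
import pytest
from scipy.special import gamma as sp_gamma

from epofs.epo import (EpoConfig, exploration_factor, expanded_exploration,
                       exploitation, init_population, levy_flight, levy_scale,
                       narrowed_exploitation, narrowed_exploration, run_epo,
                       select_search_space, spiral_coefficients)


def sphere(x):
    return -float(np.sum(x**2))


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n_pop": 1},
        {"alpha": 0.0},
        {"alpha": 1.0},
        {"gamma": 1.5},
        {"b": 1.0},
        {"search_cycle": 5.0},
        {"rotation_a": 2.0},
        {"w_max": 0.3, "w_min": 0.4},
        {"phase_split": 0.0},
        {"n_iter": -1},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EpoConfig(**kwargs)


class TestInitPopulation:
    def test_degenerate_bounds_force_unique_point(self):
        pop = init_population(EpoConfig(n_pop=3, seed=0), 2, (0.0, 0.0))
        assert np.all(pop.positions == 0.0)

    def test_identical_seed_identical_matrix(self):
        cfg = EpoConfig(n_pop=30, seed=1)
        a = init_population(cfg, 10, (-1.0, 1.0)).positions
        b = init_population(cfg, 10, (-1.0, 1.0)).positions
        assert np.array_equal(a, b)

    def test_uniform_sampling_mean(self):
        pop = init_population(EpoConfig(n_pop=1000, seed=7), 1, (-1.0, 1.0))
        assert abs(pop.positions.mean()) < 0.05
        assert pop.positions.min() >= -1.0 and pop.positions.max() <= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            init_population(EpoConfig(), 0, (-1, 1))
        with pytest.raises(ValueError):
            init_population(EpoConfig(), 2, (-np.inf, 1))


class TestUpdateRules:
    """Single-step hand traces with all stochastic draws pinned."""

    def test_search_space_fixed_point(self, rng):
        v = np.array([1.0, -2.0])
        out = select_search_space(v, v, v, 0.5, rng)
        assert np.allclose(out, v)

    def test_search_space_hand_value(self, rng):
        out = select_search_space(np.zeros(2), np.full(2, 2.0), np.zeros(2),
                                  0.5, rng, beta=1.0)
        assert np.allclose(out, [1.0, 1.0])

    def test_expanded_exploration_fixed_point(self, rng):
        v = np.array([3.0])
        assert np.allclose(expanded_exploration(v, v, 1.0, rng), v)

    def test_expanded_exploration_term_isolation(self, rng):
        out = expanded_exploration(np.array([4.0]), np.array([2.0]), 0.0, rng,
                                   beta=1.0)
        assert np.allclose(out, [-2.0])

    def test_expanded_exploration_hand_value(self, rng):
        out = expanded_exploration(np.array([4.0]), np.array([2.0]), 0.5, rng,
                                   beta=0.5)
        assert np.allclose(out, [1.0])

    def test_narrowed_exploration_term_isolation(self, rng):
        out = narrowed_exploration(np.array([5.0]), np.array([1.0]),
                                   EpoConfig(), rng,
                                   levy=np.array([0.0]), beta=0.0)
        assert np.allclose(out, [1.0])

    def test_narrowed_exploration_hand_value(self, rng):
        out = narrowed_exploration(
            np.array([2.0]), np.array([1.0]), EpoConfig(), rng,
            levy=np.array([0.5]),
            coeffs=(np.array([0.0]), np.array([1.0])),  # Y - X = 1
            beta=0.5,
        )
        assert np.allclose(out, [2.5])

    def test_exploitation_fixed_point(self, rng):
        v = np.array([2.0, 2.0])
        assert np.allclose(exploitation(v, v, v, rng), v)

    def test_exploitation_hand_value(self, rng):
        out = exploitation(np.array([10.0]), np.array([0.0]), np.array([0.0]),
                           rng, beta=1.0)
        assert np.allclose(out, [1.0])

    def test_exploitation_beta_zero(self, rng):
        best, mean, pos = np.array([4.0]), np.array([2.0]), np.array([1.0])
        out = exploitation(best, mean, pos, rng, beta=0.0)
        assert np.allclose(out, pos + 0.1 * (best - mean))

    def test_narrowed_exploitation_pinned_trace(self, rng):
        # beta = 0.5 zeroes the quality-function exponent, so QF = 1 and the
        # rule reduces to best - pos_i - 2*gamma*F + 1
        cfg = EpoConfig(gamma=0.5)
        out = narrowed_exploitation(np.array([3.0]), np.array([2.0]), 5, cfg,
                                    rng, beta=0.5, levy=np.array([1.0]))
        assert np.allclose(out, [3.0 - 2.0 - 1.0 + 1.0])

    def test_narrowed_exploitation_no_levy(self, rng):
        out = narrowed_exploitation(np.array([3.0]), np.array([2.0]), 5,
                                    EpoConfig(), rng, beta=0.5,
                                    levy=np.array([0.0]))
        assert np.allclose(out, [2.0])

    def test_narrowed_exploitation_requires_positive_t(self, rng):
        with pytest.raises(ValueError):
            narrowed_exploitation(np.ones(1), np.ones(1), 0, EpoConfig(), rng)

    def test_rules_respect_bounds(self, rng):
        bounds = (np.array([-1.0]), np.array([1.0]))
        out = exploitation(np.array([10.0]), np.array([0.0]), np.array([0.0]),
                           rng, beta=1.0, bounds=bounds)
        assert np.all(out <= 1.0) and np.all(out >= -1.0)


class TestLevyFlight:
    def test_scale_matches_independent_gamma_formula(self):
        b = 1.5
        expected = (sp_gamma(1 + b) * math.sin(math.pi * b / 2)
                    / (sp_gamma((1 + b) / 2) * b * 2 ** ((b - 1) / 2))) ** (1 / b)
        assert abs(levy_scale(b) - expected) / expected < 1e-12

    def test_zero_u_gives_zero_step(self, rng):
        out = levy_flight(4, 1.5, rng, u=np.zeros(4))
        assert np.all(out == 0.0)

    def test_heavy_tail(self):
        rng = np.random.default_rng(0)
        draws = levy_flight(100_000, 1.5, rng)
        # excess kurtosis of a Gaussian is ~0; Levy steps are far heavier
        z = (draws - draws.mean()) / draws.std()
        assert np.mean(z**4) > 20.0

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            levy_scale(1.0)


class TestSpiralCoefficients:
    @pytest.mark.parametrize("seed", range(10))
    def test_unit_max_normalization(self, seed):
        rng = np.random.default_rng(seed)
        x, y = spiral_coefficients(8, 5.0, 2.5, rng)
        assert np.isclose(np.max(np.abs(x)), 1.0)
        assert np.isclose(np.max(np.abs(y)), 1.0)

    def test_single_dimension_is_sign(self, rng):
        x, y = spiral_coefficients(1, 5.0, 2.5, rng)
        assert abs(x[0]) == pytest.approx(1.0)
        assert abs(y[0]) == pytest.approx(1.0)

    def test_degenerate_pinned_angle_rejected(self, rng):
        # beta=0.5, a=4 puts every angle at 2*pi where sin vanishes for all
        # dimensions, hitting the redraw guard
        with pytest.raises(ValueError):
            spiral_coefficients(2, 4.0, 2.5, rng, beta=np.array([0.5, 0.5]))


class TestExplorationFactor:
    def test_endpoints(self):
        assert exploration_factor(0, 100) == pytest.approx(0.9)
        assert exploration_factor(100, 100) == pytest.approx(0.4)

    def test_midpoint(self):
        assert exploration_factor(50, 100, 0.9, 0.4) == pytest.approx(0.65)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            exploration_factor(0, 0)


class TestRunEpo:
    def test_sphere_convergence_single_seed(self):
        state = run_epo(sphere, EpoConfig(seed=11), (-5, 5), 5)
        assert state.best_fitness >= -0.1

    def test_constant_objective_history_constant(self):
        state = run_epo(lambda x: 1.0, EpoConfig(n_iter=20, seed=0), (-1, 1), 3)
        assert all(h == 1.0 for h in state.history)

    def test_history_monotone_and_bounded(self):
        state = run_epo(sphere, EpoConfig(n_iter=50, seed=5), (-5, 5), 4)
        assert all(b >= a for a, b in zip(state.history, state.history[1:]))
        assert np.all(np.abs(state.best_position) <= 5.0)

    def test_bitwise_determinism(self):
        cfg = EpoConfig(n_iter=30, seed=9)
        a = run_epo(sphere, cfg, (-5, 5), 4)
        b = run_epo(sphere, cfg, (-5, 5), 4)
        assert a.history == b.history
        assert np.array_equal(a.best_position, b.best_position)

    def test_zero_iterations_returns_initial_best(self):
        cfg = EpoConfig(n_iter=0, seed=2)
        state = run_epo(sphere, cfg, (-5, 5), 3)
        pop = init_population(cfg, 3, (-5, 5))
        expected = max(sphere(x) for x in pop.positions)
        assert state.best_fitness == pytest.approx(expected)

    def test_non_finite_objective_aborts(self):
        with pytest.raises(ValueError, match="non-finite"):
            run_epo(lambda x: float("nan"), EpoConfig(n_iter=5, seed=0), (-1, 1), 2)

    def test_mutator_preserves_elitism(self):
        # a hostile mutator can never degrade the best-so-far
        def mutator(pos, t, rng):
            return pos + rng.normal(size=pos.shape)

        state = run_epo(sphere, EpoConfig(n_iter=30, seed=3), (-5, 5), 4,
                        mutator=mutator)
        assert all(b >= a for a, b in zip(state.history, state.history[1:]))
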