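import numpy as np
import pytest

from aquaforecast.iwoa import (ConvergenceSchedule, IWOAConfig, MoveContext,
                               SearchSpace, Whale, convergence_factor, optimize,
                               update_position)


def box(dim, lo, hi, **kw):
    return SearchSpace(lower=np.full(dim, float(lo)), upper=np.full(dim, float(hi)), **kw)


class TestConvergenceFactor:
    def test_boundary_and_midpoint_values(self):
        cfg = IWOAConfig(t_max=200)
        assert convergence_factor(0, cfg) == pytest.approx(2.0)
        assert convergence_factor(200, cfg) == pytest.approx(0.0)
        assert convergence_factor(100, cfg) == pytest.approx(0.25)

    def test_cubic_below_linear_in_interior(self):
        cub = IWOAConfig(t_max=200, convergence=ConvergenceSchedule.CUBIC)
        lin = IWOAConfig(t_max=200, convergence=ConvergenceSchedule.LINEAR)
        a_cub = np.array([convergence_factor(t, cub) for t in range(201)])
        a_lin = np.array([convergence_factor(t, lin) for t in range(201)])
        assert np.all(a_cub[1:-1] < a_lin[1:-1])
        assert a_cub[0] == a_lin[0] and a_cub[-1] == a_lin[-1]
        assert np.all(np.diff(a_cub) <= 0)

    def test_out_of_range_iteration_errors(self):
        with pytest.raises(ValueError):
            convergence_factor(201, IWOAConfig(t_max=200))


class TestUpdatePosition:
    def setup_method(self):
        self.cfg = IWOAConfig()
        self.lo, self.hi = np.full(1, -10.0), np.full(1, 10.0)

    def test_zero_A_encircle_lands_on_best(self):
        ctx = MoveContext(a=1.0, A=np.zeros(1), C=np.ones(1), l=0.0, p=0.2)
        new = update_position(Whale(np.array([3.0])), Whale(np.array([1.5])),
                              Whale(np.array([-2.0])), ctx, self.cfg, self.lo, self.hi)
        assert new[0] == pytest.approx(1.5)

    def test_spiral_hand_value(self):
        # |X* - X| e^{b l} cos(2 pi l) + X* with X*=0, X=1, b=1, l=-1
        ctx = MoveContext(a=0.0, A=np.zeros(1), C=np.ones(1), l=-1.0, p=0.9)
        new = update_position(Whale(np.array([1.0])), Whale(np.array([0.0])),
                              Whale(np.array([5.0])), ctx, self.cfg, self.lo, self.hi)
        assert new[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_large_A_references_random_whale(self):
        ctx = MoveContext(a=2.0, A=np.array([2.0]), C=np.ones(1), l=0.0, p=0.2)
        best, rand = Whale(np.array([0.0])), Whale(np.array([4.0]))
        new = update_position(Whale(np.array([4.0])), best, rand, ctx, self.cfg,
                              self.lo, self.hi)
        # Eq. with X^r = X = 4: Xr - A|C Xr - X| = 4 - 2*0 = 4 (not best's 0)
        assert new[0] == pytest.approx(4.0)

    def test_result_clipped_to_bounds(self):
        ctx = MoveContext(a=2.0, A=np.array([2.0]), C=np.array([2.0]), l=0.0, p=0.2)
        new = update_position(Whale(np.array([-9.0])), Whale(np.array([9.0])),
                              Whale(np.array([9.0])), ctx, self.cfg, self.lo, self.hi)
        assert self.lo[0] <= new[0] <= self.hi[0]

    def test_dimension_mismatch_errors(self):
        ctx = MoveContext(a=1.0, A=np.zeros(2), C=np.ones(2), l=0.0, p=0.2)
        with pytest.raises(ValueError):
            update_position(Whale(np.zeros(2)), Whale(np.zeros(3)), Whale(np.zeros(2)),
                            ctx, self.cfg, np.zeros(2), np.ones(2))


class TestOptimize:
    def test_sphere_2d_converges(self):
        res = optimize(lambda x: float(np.sum(x ** 2)), box(2, -10, 10),
                       IWOAConfig(pop_size=20, t_max=100, seed=0))
        assert res.best_fitness < 1e-2

    def test_history_monotone_non_increasing(self):
        res = optimize(lambda x: float(np.sum(x ** 2)), box(3, -5, 5),
                       IWOAConfig(pop_size=10, t_max=50, seed=1))
        assert len(res.history) == 50
        assert np.all(np.diff(res.history) <= 0)

    def test_constant_fitness_returns_in_bounds(self):
        res = optimize(lambda x: 7.0, box(2, -1, 1), IWOAConfig(pop_size=5, t_max=10, seed=2))
        assert res.best_fitness == 7.0
        assert np.all((res.best_position >= -1) & (res.best_position <= 1))

    def test_seed_reproducibility(self):
        f = lambda x: float(np.sum((x - 1.0) ** 2))
        r1 = optimize(f, box(4, -5, 5), IWOAConfig(pop_size=8, t_max=30, seed=3))
        r2 = optimize(f, box(4, -5, 5), IWOAConfig(pop_size=8, t_max=30, seed=3))
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        np.testing.assert_array_equal(r1.history, r2.history)

    def test_integer_dims_integral_at_evaluation(self):
        seen = []
        space = box(2, 1, 9, integer_mask=np.array([True, False]))
        optimize(lambda x: seen.append(x.copy()) or float(x[1] ** 2), space,
                 IWOAConfig(pop_size=5, t_max=5, seed=0))
        assert all(v[0] == round(v[0]) for v in seen)

    def test_log_scale_dim_decoded_to_original_scale(self):
        seen = []
        space = SearchSpace(lower=np.array([1e-4]), upper=np.array([1e-1]),
                            log_scale_mask=np.array([True]))
        optimize(lambda x: seen.append(x.copy()) or 0.0, space,
                 IWOAConfig(pop_size=5, t_max=3, seed=0))
        vals = np.array(seen).ravel()
        assert np.all((vals >= 1e-4 - 1e-12) & (vals <= 1e-1 + 1e-12))

    def test_non_finite_fitness_treated_as_inf(self):
        def f(x):
            return float("nan") if x[0] > 0 else float(x[0] ** 2)
        res = optimize(f, box(1, -1, 1), IWOAConfig(pop_size=6, t_max=20, seed=4))
        assert np.isfinite(res.best_fitness)

    def test_reported_best_matches_reevaluation(self):
        """best_fitness is exactly the fitness of the returned position."""
        f = lambda x: float(np.sum((x - 0.3) ** 2))
        space = box(3, -2, 2, integer_mask=np.array([True, False, False]))
        res = optimize(f, space, IWOAConfig(pop_size=8, t_max=20, seed=6))
        assert res.best_fitness == f(res.best_position)

    def test_warm_start_never_worse_than_guess(self):
        """A seeded initial guess bounds the final fitness from above."""
        f = lambda x: float(np.sum((x - 0.25) ** 2))
        space = box(4, -5, 5)
        guess = np.full(4, 0.3)
        res = optimize(f, space, IWOAConfig(pop_size=5, t_max=5, seed=7),
                       initial_guesses=[guess])
        assert res.best_fitness <= f(guess)

    def test_warm_start_guess_clipped_into_bounds(self):
        space = box(2, 0, 1)
        res = optimize(lambda x: float(np.sum(x)), space,
                       IWOAConfig(pop_size=3, t_max=2, seed=0),
                       initial_guesses=[np.array([5.0, -5.0])])
        assert np.all((res.best_position >= 0) & (res.best_position <= 1))

    def test_early_stop_on_fitness_tol(self):
        res = optimize(lambda x: float(np.sum(x ** 2)), box(2, -1, 1),
                       IWOAConfig(pop_size=10, t_max=500, seed=5, fitness_tol=1e-3))
        assert len(res.history) < 500


class TestSearchSpace:
    def test_invalid_bounds_error(self):
        with pytest.raises(ValueError):
            SearchSpace(lower=np.array([0.0, 1.0]), upper=np.array([1.0, 1.0]))

    def test_log_dim_requires_positive_lower(self):
        with pytest.raises(ValueError):
            SearchSpace(lower=np.array([0.0]), upper=np.array([1.0]),
                        log_scale_mask=np.array([True]))
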