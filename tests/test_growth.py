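"""Growth-model unit and property tests.

The numerical solver is checked against two independent oracles: the
closed-form constant-parameter logistic and a fixed-step RK4 integrator
written here with no shared code.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ozotox import (
    GrowthTrajectory,
    LogisticParams,
    NoDoubling,
    RISchedule,
    doubling_time,
    fit_lgm,
    logistic_closed_form,
    simulate_treated,
    solve_lgm,
)

GRID = np.array([0.0, 24.0, 48.0, 72.0])


def rk4_lgm(params: LogisticParams, times, dt=0.001):
    """Independent fixed-step RK4 oracle for the time-varying logistic ODE."""

    def f(t, n):
        a = params.alpha0 * np.exp(params.beta * t)
        k = params.k0 * np.exp(-params.gamma * t)
        return a * (1 - n / k) * n

    out, n, t = [], params.n0, 0.0
    times = list(times)
    for target in times:
        while t < target - 1e-12:
            h = min(dt, target - t)
            k1 = f(t, n)
            k2 = f(t + h / 2, n + h / 2 * k1)
            k3 = f(t + h / 2, n + h / 2 * k2)
            k4 = f(t + h, n + h * k3)
            n += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out.append(n)
    return np.array(out)


class TestClosedForm:
    def test_equilibrium_and_zero_growth(self):
        p_eq = LogisticParams(alpha0=0.3, k0=100, n0=100)
        assert logistic_closed_form(p_eq, 50.0) == 100.0
        p_zero = LogisticParams(alpha0=0.0, k0=100, n0=10)
        assert logistic_closed_form(p_zero, 72.0) == 10.0

    def test_matches_high_precision_evaluation(self):
        # frozen from an arbitrary-precision evaluation of
        # k0 / (1 + (k0/n0 - 1) exp(-alpha0 t)) at these parameters
        p = LogisticParams(alpha0=0.1, k0=100, n0=1)
        expected = 10.0189584988032680982779171373
        assert logistic_closed_form(p, 24.0) == pytest.approx(expected, rel=1e-12)

    def test_rejects_time_varying_params(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_closed_form(LogisticParams(alpha0=0.1, beta=0.01), 1.0)

    def test_rejects_negative_time(self):
        with pytest.raises(ValueError):
            logistic_closed_form(LogisticParams(alpha0=0.1, k0=2.0), -1.0)


class TestSolveLgm:
    def test_matches_closed_form(self):
        p = LogisticParams(alpha0=0.1, k0=100, n0=1)
        traj = solve_lgm(p, GRID)
        exact = logistic_closed_form(p, GRID)
        np.testing.assert_allclose(traj.values, exact, rtol=1e-6)

    def test_equilibrium_constant(self):
        p = LogisticParams(alpha0=0.2, k0=100, n0=100)
        traj = solve_lgm(p, GRID)
        np.testing.assert_allclose(traj.values, 100.0, rtol=1e-9)

    def test_decaying_capacity_tracks_k_against_rk4(self):
        # population seeded near capacity must eventually decrease,
        # following k(t) downward; cross-checked against fixed-step RK4
        p = LogisticParams(alpha0=0.1, k0=100, gamma=0.02, n0=95)
        traj = solve_lgm(p, GRID)
        assert traj.values[-1] < traj.values[0]
        assert traj.values[-1] < p.k(48.0)
        oracle = rk4_lgm(p, GRID[1:])
        np.testing.assert_allclose(traj.values[1:], oracle, rtol=1e-6)

    def test_time_varying_against_rk4(self):
        p = LogisticParams(alpha0=0.03, beta=0.02, k0=10, gamma=0.03, n0=1)
        traj = solve_lgm(p, GRID)
        oracle = rk4_lgm(p, GRID[1:])
        np.testing.assert_allclose(traj.values[1:], oracle, rtol=1e-6)

    @pytest.mark.parametrize("bad_grid", [[], [24.0, 0.0], [0.0, 10.0, 10.0]])
    def test_rejects_bad_grids(self, bad_grid):
        with pytest.raises(ValueError):
            solve_lgm(LogisticParams(alpha0=0.1, k0=10), bad_grid)

    @settings(max_examples=20, deadline=None)
    @given(
        a=st.floats(0.01, 0.08),
        boost=st.floats(1.1, 3.0),
    )
    def test_larger_growth_rate_dominates(self, a, boost):
        # with k0 >> n0 (no capacity limitation in the window) a larger
        # alpha0 gives a pointwise larger trajectory
        slow = solve_lgm(LogisticParams(alpha0=a, k0=1e6, n0=1.0), GRID)
        fast = solve_lgm(LogisticParams(alpha0=a * boost, k0=1e6, n0=1.0), GRID)
        assert np.all(fast.values[1:] > slow.values[1:])


class TestTrajectoryType:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GrowthTrajectory([0.0, 1.0], [1.0])
        with pytest.raises(ValueError):
            GrowthTrajectory([0.0, 1.0], [1.0, -2.0])
        with pytest.raises(ValueError):
            GrowthTrajectory([1.0, 0.0], [1.0, 2.0])

    def test_params_invariants(self):
        with pytest.raises(ValueError):
            LogisticParams(alpha0=0.1, k0=-1.0)
        with pytest.raises(ValueError):
            LogisticParams(alpha0=0.1, k0=1.0, n0=0.0)


class TestSchedule:
    def test_gap_and_overlap_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            RISchedule([(0, 24, 0.1), (30, 72, 0.1)])
        with pytest.raises(ValueError, match="overlap"):
            RISchedule([(0, 48, 0.1), (24, 72, 0.1)])

    def test_reduction_bounds(self):
        with pytest.raises(ValueError):
            RISchedule([(0, 72, 1.5)])
        with pytest.raises(ValueError):
            RISchedule([(0, 72, -0.1)])

    def test_lookup_half_open(self):
        s = RISchedule([(0, 48, 0.11), (48, 72, 0.06)])
        assert s.reduction_at(47.999) == 0.11
        assert s.reduction_at(48.0) == 0.06
        assert s.reduction_at(72.0) == 0.06


class TestSimulateTreated:
    def test_null_schedule_identity(self):
        p = LogisticParams(alpha0=0.05, beta=0.01, k0=10, gamma=0.02, n0=1)
        control = solve_lgm(p, GRID)
        treated = simulate_treated(p, RISchedule.null(72.0), GRID)
        np.testing.assert_array_equal(treated.values, control.values)

    def test_full_suppression_freezes_population(self):
        p = LogisticParams(alpha0=0.1, k0=100, n0=5)
        treated = simulate_treated(p, RISchedule([(0, 72, 1.0)]), GRID)
        np.testing.assert_allclose(treated.values, 5.0, rtol=1e-9)

    def test_study_schedule_slows_growth(self, fitted_control):
        p = fitted_control.params
        sched = RISchedule([(0, 48, 0.11), (48, 72, 0.06)])
        control = solve_lgm(p, GRID)
        treated = simulate_treated(p, sched, GRID)
        assert treated.value_at(24) < control.value_at(24)
        assert treated.value_at(48) < control.value_at(48)
        assert doubling_time(p, schedule=sched) > doubling_time(p)

    def test_continuity_at_segment_boundary(self):
        p = LogisticParams(alpha0=0.06, beta=0.01, k0=8, gamma=0.03, n0=1)
        sched = RISchedule([(0, 48, 0.11), (48, 72, 0.06)])
        grid = np.array([0.0, 48.0 - 1e-6, 48.0, 48.0 + 1e-6, 72.0])
        vals = simulate_treated(p, sched, grid).values
        assert abs(vals[2] - vals[1]) < 1e-6
        assert abs(vals[3] - vals[2]) < 1e-6

    @settings(max_examples=15, deadline=None)
    @given(f1=st.floats(0.0, 0.9), bump=st.floats(0.01, 0.1))
    def test_monotone_damage_response_without_capacity_decay(self, f1, bump):
        # with gamma = 0 a larger reduction can never raise the population
        p = LogisticParams(alpha0=0.08, k0=50, n0=1)
        weak = simulate_treated(p, RISchedule([(0, 72, f1)]), GRID)
        strong = simulate_treated(p, RISchedule([(0, 72, min(1.0, f1 + bump))]), GRID)
        assert np.all(strong.values <= weak.values + 1e-9)

    def test_uncovered_grid_rejected(self):
        p = LogisticParams(alpha0=0.1, k0=10)
        with pytest.raises(ValueError, match="cover"):
            simulate_treated(p, RISchedule([(0, 48, 0.1)]), GRID)


class TestFit:
    def test_noise_free_recovery(self):
        true = LogisticParams(alpha0=0.05, beta=0.01, k0=2e6, gamma=0.015, n0=1e5)
        grid = np.arange(0.0, 73.0, 6.0)
        obs = solve_lgm(true, grid)
        fit = fit_lgm(obs, scenario="time_varying", seed=1)
        for name in ("alpha0", "beta", "k0", "gamma"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(true, name), rel=0.01
            )
        assert fit.converged

    def test_nested_model_consistency(self):
        # data from a constant-parameter model: the time-varying fit must
        # drive beta and gamma to (essentially) zero
        true = LogisticParams(alpha0=0.06, k0=8.0, n0=1.0)
        grid = np.arange(0.0, 73.0, 6.0)
        obs = solve_lgm(true, grid)
        fit = fit_lgm(obs, scenario="time_varying", seed=2)
        assert abs(fit.params.beta) < 1e-3
        assert abs(fit.params.gamma) < 1e-3

    def test_scenario_discrimination_on_rise_fall(self, rise_fall_control):
        const = fit_lgm(rise_fall_control, scenario="constant", seed=0)
        tv = fit_lgm(rise_fall_control, scenario="time_varying", seed=0)
        assert const.residual_sum_of_squares > tv.residual_sum_of_squares

    def test_constant_scenario_pins_beta_gamma(self, rise_fall_control):
        fit = fit_lgm(rise_fall_control, scenario="constant", seed=0)
        assert fit.params.beta == 0.0 and fit.params.gamma == 0.0
        assert set(fit.bounds_used) == {"alpha0", "k0"}

    def test_fitted_params_within_bounds(self, fitted_control):
        for name, (lo, hi) in fitted_control.bounds_used.items():
            assert lo <= getattr(fitted_control.params, name) <= hi

    def test_too_few_observations_rejected(self):
        obs = GrowthTrajectory([0.0, 24.0, 48.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="observations"):
            fit_lgm(obs, scenario="time_varying")

    def test_degenerate_observations_rejected(self):
        obs = GrowthTrajectory(GRID, [2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_lgm(obs, scenario="constant")

    def test_bad_bounds_rejected(self):
        obs = GrowthTrajectory(GRID, [1.0, 2.0, 3.0, 3.5])
        with pytest.raises(ValueError, match="bounds"):
            fit_lgm(obs, scenario="constant", bounds={"alpha0": (0.5, 0.1)})


class TestDoublingTime:
    def test_exponential_limit(self):
        # k0 >> n0: logistic ~ exponential, doubling time ~ ln 2 / alpha0
        p = LogisticParams(alpha0=0.05, k0=1e9, n0=1.0)
        assert doubling_time(p, horizon=72.0) == pytest.approx(
            np.log(2) / 0.05, rel=0.01
        )

    def test_no_doubling_at_equilibrium(self):
        p = LogisticParams(alpha0=0.1, k0=10, n0=10)
        with pytest.raises(NoDoubling):
            doubling_time(p)
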