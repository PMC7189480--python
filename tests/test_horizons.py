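import numpy as np
import pytest
from scipy import linalg

from reachofc.finite_horizon import TerminalCostWeights, terminal_cost_matrix
from reachofc.horizons import (
    InfiniteParams,
    NeverInterceptedError,
    NonTerminationError,
    PerturbationSpec,
    RecedingParams,
    calibrate_infinite_duration,
    horizon_intensity_profile,
    horizon_time_to_target,
    receding_first_step_gain,
    run_infinite_horizon,
    run_receding_horizon,
    solve_infinite_horizon,
)
from reachofc.lqg import CostSchedule, Trajectory, solve_finite_horizon

LOCATIONS = [0.042, 0.083, 0.125, 0.167, 0.208]


def toy_trajectory(speed=0.1, dt=0.01, n=280):
    """Straight line along +y at constant speed, target state fixed."""
    states = np.zeros((n + 1, 8))
    states[:, 1] = speed * dt * np.arange(n + 1)
    states[:, 7] = 0.25
    return Trajectory(
        states=states, controls=np.zeros((n, 2)), times=dt * np.arange(n + 1), dt=dt
    )


class TestTimeToTarget:
    def test_already_inside_radius_gives_zero(self):
        from reachofc.horizons import time_to_target_from_trajectory

        traj = toy_trajectory()
        # onset just when the cursor is at the target
        t_hit = (0.25 - 0.004 / 2) / 0.1
        assert (
            time_to_target_from_trajectory(traj, t_hit, (0.0, 0.25), 0.004) == 0.0
        )

    def test_constant_speed_closed_form(self):
        """Distance over speed, up to one-sample quantization."""
        from reachofc.horizons import time_to_target_from_trajectory

        traj = toy_trajectory(speed=0.1)
        expected_ms = (0.25 - 0.004) / 0.1 * 1e3
        got = time_to_target_from_trajectory(traj, 0.0, (0.0, 0.25), 0.004)
        assert abs(got - expected_ms) <= 10.0

    def test_never_intercepting_raises(self):
        from reachofc.horizons import time_to_target_from_trajectory

        traj = toy_trajectory(speed=0.0)
        with pytest.raises(NeverInterceptedError):
            time_to_target_from_trajectory(traj, 0.0, (0.0, 0.25), 0.004)


class TestRecedingHorizon:
    def test_single_iteration_equals_finite_horizon_first_step(self, system):
        """A receding-horizon iteration is exactly the first step of a
        500 ms finite-horizon problem from the same state."""
        params = RecedingParams()
        n_h = 50
        Q = np.zeros((n_h + 1, 8, 8))
        Q[n_h] = terminal_cost_matrix(params.weights)
        costs = CostSchedule(Q=Q, R=np.full(n_h, params.r_cost))
        from dataclasses import replace

        ce = replace(system, c_scale=0.0)
        expected = solve_finite_horizon(ce, costs, tol=1e-9).L[0]
        np.testing.assert_allclose(
            receding_first_step_gain(system, params), expected, atol=1e-9
        )

    def test_unperturbed_profile_is_positively_skewed(self, system, x0):
        """The receding controller always plans to arrive 500 ms from now,
        so its velocity peaks early in the movement."""
        run = run_receding_horizon(system, RecedingParams(), x0)
        vy = run.trajectory.states[:, 3]
        peak_pos = run.trajectory.states[int(np.argmax(vy)), 1]
        assert peak_pos < 0.5 * 0.25

    def test_zero_amplitude_perturbation_keeps_duration(self, system, x0):
        base = run_receding_horizon(system, RecedingParams(), x0)
        pert = run_receding_horizon(
            system, RecedingParams(), x0, PerturbationSpec(location=0.125, jump=0.0)
        )
        assert pert.duration_ms == base.duration_ms

    def test_durations_increase_with_onset_location(self, system, x0):
        """Later perturbations force larger detours, hence longer trials."""
        durs = [
            run_receding_horizon(
                system, RecedingParams(), x0, PerturbationSpec(location=loc)
            ).duration_ms
            for loc in LOCATIONS
        ]
        assert all(b >= a for a, b in zip(durs, durs[1:]))
        assert durs[-1] > durs[0]

    def test_times_to_target_decrease_with_onset_location(self, system, x0):
        tts = [
            horizon_time_to_target(
                run_receding_horizon(
                    system, RecedingParams(), x0, PerturbationSpec(location=loc)
                )
            )
            for loc in LOCATIONS
        ]
        assert all(b <= a for a, b in zip(tts, tts[1:]))

    def test_non_termination_raises(self, system, x0):
        with pytest.raises(NonTerminationError):
            run_receding_horizon(system, RecedingParams(), x0, cap_s=0.3)


class TestInfiniteHorizon:
    def test_stationary_gain_matches_algebraic_riccati(self, system_ce):
        """On the controllable per-axis error subspace the stationary gain
        must solve the discrete algebraic Riccati equation (scipy oracle)."""
        params = InfiniteParams(
            weights=TerminalCostWeights(wp=(1.0, 1.0), wv=0.02, wf=0.1), r_cost=0.002
        )
        stat = solve_infinite_horizon(system_ce, params)
        assert stat.converged
        # per-axis error system [p - p*, v, f]
        dt, b, m, tau = 0.01, 7.0, 1.1, 0.05
        A = np.array([[1, dt, 0], [0, 1 - dt * b / m, dt / m], [0, 0, 1 - dt / tau]])
        B = np.array([[0.0], [0.0], [dt / tau]])
        s = 100.0
        Q = np.diag([(1.0 * s) ** 2, 0.02 * s**2, 0.1])
        R = np.array([[0.002]])
        P = linalg.solve_discrete_are(A, B, Q, R)
        L_are = np.linalg.solve(R + B.T @ P @ B, B.T @ P @ A)
        # x-axis rows of the full gain act on [px, vx, fx] and -[tx]
        got = np.array([stat.L[0, 0], stat.L[0, 2], stat.L[0, 4]])
        np.testing.assert_allclose(got, L_are[0], rtol=1e-6)
        assert stat.L[0, 6] == pytest.approx(-stat.L[0, 0], rel=1e-6)

    def test_no_noise_means_no_filter_correction(self, system_ce):
        stat = solve_infinite_horizon(system_ce, InfiniteParams())
        np.testing.assert_allclose(stat.K, 0.0, atol=1e-12)

    def test_duration_calibration_hits_target(self, system, x0):
        """The calibrated cost scale reproduces the behavioral baseline
        movement duration on the 10 ms simulation grid."""
        params = calibrate_infinite_duration(system, InfiniteParams(), x0)
        stat = solve_infinite_horizon(system, params)
        run = run_infinite_horizon(system, stat, x0)
        assert abs(run.duration_ms - 932.0) <= 10.0

    def test_times_to_target_decrease_with_location(self, system, x0):
        params = calibrate_infinite_duration(system, InfiniteParams(), x0)
        stat = solve_infinite_horizon(system, params)
        tts = [
            horizon_time_to_target(
                run_infinite_horizon(system, stat, x0, PerturbationSpec(location=loc))
            )
            for loc in LOCATIONS
        ]
        assert all(b <= a for a, b in zip(tts, tts[1:]))


class TestHorizonIntensities:
    @pytest.fixture(scope="class")
    def profiles(self, system, x0):
        inf_params = calibrate_infinite_duration(system, InfiniteParams(), x0)
        _, rec, _ = horizon_intensity_profile("receding", system, x0, LOCATIONS)
        _, inf, _ = horizon_intensity_profile(
            "infinite", system, x0, LOCATIONS, infinite_params=inf_params
        )
        return rec, inf

    def test_profiles_are_location_invariant(self, profiles):
        """Neither non-finite controller varies its response with the
        perturbation onset location: spread below 10% of the mean."""
        for intens in profiles:
            assert (intens.max() - intens.min()) <= 0.10 * intens.mean()

    def test_intensities_point_toward_the_jump(self, profiles):
        for intens in profiles:
            assert np.all(intens > 0)

    def test_zero_jump_gives_zero(self, system, x0):
        _, intens, _ = horizon_intensity_profile(
            "receding", system, x0, LOCATIONS, jump=0.0
        )
        np.testing.assert_array_equal(intens, 0.0)

    def test_unknown_model_rejected(self, system, x0):
        with pytest.raises(ValueError):
            horizon_intensity_profile("sliding", system, x0, LOCATIONS)
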