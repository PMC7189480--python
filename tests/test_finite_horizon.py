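import numpy as np
import pytest

from reachofc.finite_horizon import (
    ActivationSchedule,
    TerminalCostWeights,
    build_activation_schedule,
    build_terminal_cost,
    classical_intensity_profile,
    crossing_step,
    instruction_variant,
    make_cost_schedule,
    remap_to_time_to_target,
    terminal_cost_matrix,
    ttt_intensity_at_location,
)
from reachofc.lqg import simulate_mean_trajectory, solve_finite_horizon
from reachofc.plant import reach_start_state


class TestTerminalCost:
    def test_zero_before_final_step(self):
        Q = build_terminal_cost(TerminalCostWeights(), 20)
        assert np.all(Q[:20] == 0)
        assert np.any(Q[20] != 0)

    def test_quadratic_form_values(self):
        """Unit (1 cm) position error on one axis with unit weight costs 1;
        the exact terminal state costs 0."""
        Q = terminal_cost_matrix(TerminalCostWeights(wp=(1.0, 1.0), wv=0.0, wf=0.0))
        x = np.zeros(8)
        x[0] = 0.01  # 1 cm lateral error, target at origin
        assert x @ Q @ x == pytest.approx(1.0)
        x_on_target = np.array([0.0, 0.25, 0, 0, 0, 0, 0.0, 0.25])
        assert x_on_target @ Q @ x_on_target == pytest.approx(0.0)

    def test_asymmetric_position_weights(self):
        Q = terminal_cost_matrix(TerminalCostWeights(wp=(0.5, 1.0), wv=0.0, wf=0.0))
        ex = np.zeros(8); ex[0] = 0.01
        ey = np.zeros(8); ey[1] = 0.01
        assert (ex @ Q @ ex) == pytest.approx(0.25)
        assert (ey @ Q @ ey) == pytest.approx(1.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            TerminalCostWeights(wp=(-1.0, 1.0))
        with pytest.raises(ValueError):
            build_terminal_cost(TerminalCostWeights(), 0)


class TestActivationSchedule:
    def test_flat_when_untilted(self):
        R = build_activation_schedule(ActivationSchedule(), 50)
        np.testing.assert_allclose(R, 1e-5)

    @pytest.mark.parametrize("p,q,r", [(2.0, 0.3, 1.0), (-5.0, 0.0, 1.3), (9.0, -1.0, 0.8)])
    def test_mean_equals_base_exactly(self, p, q, r):
        """The normalization pins the mean activation cost to the base value
        regardless of tilt, so every condition is equally effortful."""
        R = build_activation_schedule(ActivationSchedule(p=p, q=q, r=r), 80)
        assert R.mean() == pytest.approx(1e-5, rel=1e-12)
        assert np.all(R > 0)

    def test_positive_tilt_is_increasing(self):
        R = build_activation_schedule(ActivationSchedule(p=3.0), 60)
        assert np.all(np.diff(R) > 0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ActivationSchedule(r=0.0)
        with pytest.raises(ValueError):
            ActivationSchedule(base=0.0)


class TestClassicalIntensity:
    def test_zero_jump_gives_zero_profile(self, system, baseline_fit):
        prof = classical_intensity_profile(system, baseline_fit, jump=0.0)
        np.testing.assert_array_equal(prof.intensities, 0.0)

    def test_left_right_antisymmetry(self, system, baseline_fit):
        """Leftward and rightward jumps produce mirror-image lateral forces,
        so the signed intensities coincide after rectification."""
        left = classical_intensity_profile(system, baseline_fit, jump=-0.02)
        right = classical_intensity_profile(system, baseline_fit, jump=+0.02)
        np.testing.assert_allclose(left.intensities, right.intensities, atol=1e-10)

    def test_scaling_linearity(self, system, baseline_fit):
        """Linear plant + quadratic cost: doubling the jump doubles the
        response everywhere."""
        one = classical_intensity_profile(system, baseline_fit, jump=0.02)
        two = classical_intensity_profile(system, baseline_fit, jump=0.04)
        nz = one.intensities != 0
        np.testing.assert_allclose(
            two.intensities[nz], 2 * one.intensities[nz], rtol=1e-6
        )

    def test_window_zeroing_near_movement_end(self, system, baseline_fit):
        """Perturbations whose measurement window outlasts the movement get
        intensity exactly 0."""
        prof = classical_intensity_profile(system, baseline_fit)
        n = baseline_fit.n_steps
        assert np.all(prof.intensities[n - 17 :] == 0.0)
        assert prof.intensities[n - 18] != 0.0

    def test_profile_rises_and_falls(self, system, baseline_fit):
        """Baseline intensity increases from movement start, peaks
        mid-movement, and falls off toward the end."""
        prof = classical_intensity_profile(system, baseline_fit)
        iv = prof.intensities
        nz = np.nonzero(iv)[0]
        peak = iv.argmax()
        assert nz[0] < peak < nz[-1]
        assert iv[peak] > 3 * iv[nz[0]]
        assert iv[peak] > 3 * iv[nz[-1]]


class TestTimeToTargetModel:
    def test_window_shorter_than_ttt_required(self, system, baseline_fit):
        with pytest.raises(ValueError):
            ttt_intensity_at_location(system, baseline_fit, 0.125, 50.0)

    def test_matches_classical_when_time_matches(self, system_ce, x0):
        """Supplying the classical model's own remaining time reproduces the
        classical intensity: the re-planned problem is the original one's
        tail.  Checked on the certainty-equivalent plant, where gains do not
        depend on the state the problem starts from."""
        from reachofc.finite_horizon import fit_kinematic_condition

        fit = fit_kinematic_condition(system_ce, 0.5, 50.0, seed=5)
        ctrl = solve_finite_horizon(system_ce, fit.cost_schedule(), x0=x0)
        base = simulate_mean_trajectory(system_ce, ctrl, x0)
        t_p = crossing_step(base, 0.125)
        remaining_ms = (fit.n_steps - t_p - 12) * 10.0
        v = ttt_intensity_at_location(system_ce, fit, 0.125, remaining_ms)
        classical = classical_intensity_profile(system_ce, fit)
        assert v == pytest.approx(classical.intensities[t_p], rel=1e-6)

    def test_longer_time_to_target_weakens_response(self, system, baseline_fit):
        """On the long-time limb, more time to correct means a gentler
        correction."""
        vals = [
            ttt_intensity_at_location(system, baseline_fit, 0.083, ttt)
            for ttt in (400.0, 600.0, 800.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(v > 0 for v in vals)


class TestInstructionVariants:
    def test_stop_is_identity(self):
        w = TerminalCostWeights()
        assert instruction_variant(w, "stop") == (w, None)

    def test_hit_and_fast_hit_scalings(self):
        w = TerminalCostWeights(wv=0.02, wf=2.0)
        hit, n_hit = instruction_variant(w, "hit")
        assert (hit.wv, hit.wf, n_hit) == (0.005, 0.5, 800.0)
        fast, n_fast = instruction_variant(w, "fast-hit")
        assert (fast.wv, fast.wf, n_fast) == (0.002, 0.2, 750.0)
        with pytest.raises(ValueError):
            instruction_variant(w, "sprint")


def test_baseline_reach_arrives_and_peaks_mid_movement(system, x0, baseline_fit):
    """The fitted baseline movement ends within the 0.4 cm model radius of
    the 25 cm target, with its forward velocity peak between 45% and 55% of
    the movement distance."""
    from reachofc.finite_horizon import peak_speed_and_location

    ctrl = solve_finite_horizon(system, baseline_fit.cost_schedule(), x0=x0)
    traj = simulate_mean_trajectory(system, ctrl, x0)
    end_gap = np.linalg.norm(traj.states[-1, :2] - [0.0, 0.25])
    assert end_gap < 0.004
    speed, loc = peak_speed_and_location(traj, 0.25)
    assert 45.0 <= loc <= 55.0
    assert speed == pytest.approx(0.5, abs=0.08)


def test_fitted_conditions_hit_their_kinematic_targets(system, x0, condition_fits):
    """Each fitted condition's rollout peaks near its target speed and
    location (the quantities the likelihood scores)."""
    from reachofc.finite_horizon import peak_speed_and_location

    targets = {"baseline": 50.0, "late": 66.0, "early": 33.0}
    for label, fit in condition_fits.items():
        ctrl = solve_finite_horizon(system, fit.cost_schedule(), x0=x0)
        traj = simulate_mean_trajectory(system, ctrl, x0)
        speed, loc = peak_speed_and_location(traj, 0.25)
        assert abs(loc - targets[label]) <= 5.0, label
        assert abs(speed - 0.5) <= 0.08, label


def test_fitted_conditions_share_mean_activation_cost(condition_fits):
    """The schedule normalization keeps every fitted condition equally
    effortful: identical mean activation cost."""
    means = []
    for fit in condition_fits.values():
        costs = fit.cost_schedule()
        means.append(costs.R.mean())
    np.testing.assert_allclose(means, means[0], rtol=1e-12)


def test_remap_drops_zeroed_onsets(system, baseline_fit):
    prof = classical_intensity_profile(system, baseline_fit)
    ttt, intens = remap_to_time_to_target(prof, baseline_fit.n_steps, 0.01)
    assert intens.size < prof.intensities.size
    assert np.all(intens != 0)
    assert np.all(ttt > 0)
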