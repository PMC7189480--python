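import numpy as np
import pytest

from reachofc.behavior import (
    NeverInterceptedError,
    TrialRecord,
    aroc_onset,
    condition_summary,
    feedback_intensity,
    lowpass_filter,
    movement_duration_and_ttt,
)


def make_channel_trial(force, direction, onset=300, participant=1, condition="baseline",
                       block=1, location=8.3):
    n = force.size
    zeros = np.zeros((n, 2))
    return TrialRecord(
        participant=participant,
        condition=condition,
        block=block,
        trial_type="channel",
        location_cm=location,
        direction=direction,
        t_ms=np.arange(n, dtype=float),
        hand_pos=zeros,
        hand_vel=zeros,
        cursor_pos=zeros,
        pert_onset_ms=onset,
        channel_force=force,
    )


class TestLowpassFilter:
    def test_dc_gain_is_one(self):
        x = np.full(2000, 3.7)
        np.testing.assert_allclose(lowpass_filter(x), 3.7, atol=1e-9)

    def test_passband_kept_stopband_killed(self):
        """A 5 Hz component passes within 1%; a 100 Hz component is cut by
        more than 40 dB."""
        t = np.arange(4000) / 1000.0
        low = np.sin(2 * np.pi * 5 * t)
        high = np.sin(2 * np.pi * 100 * t)
        mid = slice(1000, 3000)  # avoid edge transients
        low_f = lowpass_filter(low)
        high_f = lowpass_filter(high)
        assert np.abs(low_f[mid] - low[mid]).max() < 0.01
        assert np.abs(high_f[mid]).max() < 10 ** (-40 / 20)

    def test_zero_phase_time_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(3000)
        fwd = lowpass_filter(x)
        rev = lowpass_filter(x[::-1])[::-1]
        # edge padding breaks exact symmetry only within the warm-up region
        np.testing.assert_allclose(fwd[500:-500], rev[500:-500], atol=1e-9)

    def test_idempotent_within_passband(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 5 * t)
        once = lowpass_filter(x)
        twice = lowpass_filter(once)
        mid = slice(1000, 3000)
        assert np.abs(twice[mid] - once[mid]).max() < 1e-3 * np.abs(once[mid]).max()

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(2000), order=5)
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(10))


class TestFeedbackIntensity:
    def test_identical_traces_give_zero(self):
        f = np.zeros(800)
        assert feedback_intensity(
            make_channel_trial(f, "left"), make_channel_trial(f, "right")
        ) == 0.0

    def test_symmetric_unit_forces_give_one(self):
        """+1 N on left trials and -1 N on right trials is a 1 N corrective
        response under the per-perturbation convention."""
        left = make_channel_trial(np.full(800, +1.0), "left")
        right = make_channel_trial(np.full(800, -1.0), "right")
        assert feedback_intensity(left, right) == pytest.approx(1.0)

    def test_pair_validation(self):
        left = make_channel_trial(np.zeros(800), "left")
        with pytest.raises(ValueError):
            feedback_intensity(left, left)
        other = make_channel_trial(np.zeros(800), "right", block=2)
        with pytest.raises(ValueError):
            feedback_intensity(left, other)


class TestArocOnset:
    def _trials(self, onset_true=140, noise=0.3, n_trials=12, seed=0):
        rng = np.random.default_rng(seed)
        lefts, rights = [], []
        n = 900
        for i in range(n_trials):
            base = rng.standard_normal(n) * noise
            sep = np.zeros(n)
            sep[300 + onset_true :] = 1.0
            lefts.append(make_channel_trial(base + sep, "left"))
            base2 = rng.standard_normal(n) * noise
            rights.append(make_channel_trial(base2 - sep, "right"))
        return lefts, rights

    def test_identical_distributions_give_no_onset(self):
        rng = np.random.default_rng(2)
        lefts = [make_channel_trial(rng.standard_normal(900) * 0.3, "left") for _ in range(8)]
        rights = [make_channel_trial(rng.standard_normal(900) * 0.3, "right") for _ in range(8)]
        est = aroc_onset(lefts, rights)
        assert not est.detected
        assert est.onset_ms is None

    def test_recovers_scripted_divergence_time(self):
        """Force traces separating at 140 ms are time-stamped within
        +-10 ms."""
        lefts, rights = self._trials(onset_true=140)
        est = aroc_onset(lefts, rights)
        assert est.detected
        assert abs(est.onset_ms - 140.0) <= 10.0

    def test_invariant_to_common_monotone_transform(self):
        """The aROC uses only ranks, so a shared monotone transform of all
        forces leaves the onset unchanged."""
        lefts, rights = self._trials(onset_true=160, seed=5)

        def transform(tr):
            tr.channel_force = np.exp(0.8 * tr.channel_force) - 2.0
            return tr

        est1 = aroc_onset(lefts, rights)
        est2 = aroc_onset([transform(t) for t in lefts], [transform(t) for t in rights])
        assert est1.onset_ms == pytest.approx(est2.onset_ms, abs=1e-9)

    def test_needs_two_trials_per_side(self):
        lefts, rights = self._trials()
        with pytest.raises(ValueError):
            aroc_onset(lefts[:1], rights)


class TestDurationsAndSummary:
    def test_scripted_interception_recovered_exactly(self):
        """A synthetic maintained trial with a scripted interception time
        yields exactly that duration and time-to-target."""
        from reachofc.synthetic import GroundTruth, generate_dataset

        truth = GroundTruth(noise_sd=0.0)
        ds = generate_dataset(1, 1, seed=3, truth=truth, conditions=["baseline"])
        trial = next(
            t for t in ds.trials
            if t.trial_type == "maintained" and t.location_cm == 12.5
            and t.direction == "left"
        )
        dur, ttt = movement_duration_and_ttt(trial, (0.0, 0.25))
        want = truth.time_to_target_ms("baseline", 12.5)
        assert abs(ttt - want) <= 1.0
        assert dur == trial.pert_onset_ms + ttt

    def test_unperturbed_white_bar_construction(self):
        """For an unperturbed movement, the time-to-target at a location is
        the duration minus the crossing time of that location."""
        from reachofc.synthetic import GroundTruth, generate_dataset

        truth = GroundTruth(noise_sd=0.0)
        ds = generate_dataset(1, 1, seed=3, truth=truth, conditions=["baseline"])
        trial = next(
            t for t in ds.trials
            if t.trial_type == "maintained" and t.direction == "none"
        )
        dur, ttt = movement_duration_and_ttt(trial, (0.0, 0.25), location_cm=8.3)
        cross = truth.crossing_ms("baseline", 8.3)
        assert ttt == pytest.approx(dur - cross, abs=1.0)

    def test_never_intercepting_trial_raises(self):
        n = 500
        zeros = np.zeros((n, 2))
        trial = TrialRecord(
            participant=1, condition="baseline", block=1, trial_type="maintained",
            location_cm=8.3, direction="left", t_ms=np.arange(n, dtype=float),
            hand_pos=zeros, hand_vel=zeros, cursor_pos=zeros, pert_onset_ms=100,
        )
        with pytest.raises(NeverInterceptedError):
            movement_duration_and_ttt(trial, (0.0, 0.25))

    def test_summary_row_count_and_order_invariance(self):
        """Two participants x three conditions x five locations gives 30
        rows, independent of trial order."""
        from reachofc.synthetic import GroundTruth, generate_dataset

        ds = generate_dataset(
            2, 2, seed=9, truth=GroundTruth(noise_sd=0.0),
            conditions=["baseline", "matched-cursor-early", "matched-cursor-late"],
        )
        summ = condition_summary(ds.trials)
        assert len(summ) == 2 * 3 * 5
        shuffled = list(ds.trials)
        np.random.default_rng(0).shuffle(shuffled)
        summ2 = condition_summary(shuffled)
        np.testing.assert_allclose(
            summ.sort_values(["participant", "condition", "location_cm"]).intensity,
            summ2.sort_values(["participant", "condition", "location_cm"]).intensity,
        )

    def test_summary_intensities_positive_for_corrective_data(self):
        from reachofc.synthetic import GroundTruth, generate_dataset

        ds = generate_dataset(1, 2, seed=10, truth=GroundTruth(noise_sd=0.0),
                              conditions=["baseline"])
        summ = condition_summary(ds.trials)
        assert (summ.intensity > 0).all()
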