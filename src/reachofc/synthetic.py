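"""Synthetic-participant datasets with known ground truth.

Generates complete datasets with the experiment's structure -- five
conditions, blocks of 22 trials (five perturbation locations x two
directions + a zero-perturbation trial, as channel and as maintained
trials), 1 kHz sampling -- so every stage of the behavioral pipeline can be
tested without any recorded data.

The embedded ground truth fixes, per condition: a movement-duration and a
hand kinematic template (a time-warped minimum-jerk reach whose velocity
peak sits at the condition's location), a times-to-target table per
perturbation location, a response latency, and a tuning curve mapping
time-to-target to corrective-force intensity.  Channel-trial forces are
built as a smooth corrective pulse whose mean over the 180-230 ms window
equals the tuning curve's value at the trial's time-to-target *exactly*, so
noiseless datasets round-trip through the analysis to machine precision.

What this generator does not emulate: trial-to-trial kinematic variability,
learning or fatigue across blocks (the maintained trials of the experiment
were designed to prevent intensity decay, so stationarity is the intended
regime), biomechanical coupling between axes, and single-trial force-shape
idiosyncrasies -- only window-mean forces are matched to the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize

from .behavior import TrialRecord
from .design import CONDITIONS, TaskGeometry
from .tuning import TuningParams, eval_tuning

#: default tuning curve: hyperbolic limb pinned to point-mass physics for the
#: 2 cm jump (beta = 2 m d), logistic suppression below ~150 ms
DEFAULT_TUNING = TuningParams(beta=2 * 1.1 * 0.02, t1=0.0, alpha=2.0, t0=0.15, tau_l=0.04)

#: movement durations per condition, ms (matched-hand conditions share the
#: baseline hand kinematics)
DEFAULT_DURATIONS = {
    "baseline": 930.0,
    "matched-cursor-late": 1050.0,
    "matched-cursor-early": 1130.0,
    "matched-hand-early": 930.0,
    "matched-hand-late": 930.0,
}

#: post-perturbation extension of the time-to-target, ms per location index
#: (largest for perturbations close to the target)
DEFAULT_EXTENSIONS_MS = (50.0, 80.0, 120.0, 180.0, 260.0)


def minimum_jerk(s):
    """Minimum-jerk position profile on normalized time s in [0, 1]."""
    s = np.clip(s, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


@lru_cache(maxsize=None)
def _warp_gamma_for_peak(peak_frac: float) -> float:
    """Exponent of the time warp s = u**gamma placing the velocity peak of a
    warped minimum-jerk reach at ``peak_frac`` of the distance."""

    def peak_loc(gamma: float) -> float:
        u = np.linspace(1e-5, 1.0, 20001)
        pos = minimum_jerk(u**gamma)
        vel = np.gradient(pos, u)
        return float(pos[int(np.argmax(vel))])

    if not 0.01 < peak_frac < 0.675:
        raise ValueError(f"velocity-peak fraction {peak_frac} outside warpable range")
    return float(optimize.brentq(lambda g: peak_loc(g) - peak_frac, 0.3, 20.0))


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator commits to; the target of round-trip tests."""

    tuning: dict = field(default_factory=dict)  # condition -> TuningParams
    durations_ms: dict = field(default_factory=lambda: dict(DEFAULT_DURATIONS))
    extensions_ms: tuple = DEFAULT_EXTENSIONS_MS
    latency_ms: float = 140.0
    noise_sd: float = 0.05  # N, white noise on channel force
    geometry: TaskGeometry = TaskGeometry()
    seed: int | None = None  # filled in by generate_dataset

    def tuning_for(self, condition: str) -> TuningParams:
        return self.tuning.get(condition, DEFAULT_TUNING)

    def hand_profile(self, condition: str, n_ms: int) -> np.ndarray:
        """Forward hand position (m) at 1 kHz over the condition's movement.

        Early-peak profiles are time-warped minimum-jerk reaches; a
        late-peak profile is the time-mirror of the corresponding
        early-peak one (velocity profile reflected about mid-movement),
        which keeps the early part of the movement realistically brisk.
        """
        spec = CONDITIONS[condition]
        return _hand_profile_cached(
            spec.hand_peak_pct,
            float(self.durations_ms[condition]),
            self.geometry.movement_distance_cm,
            int(n_ms),
        )

    def crossing_ms(self, condition: str, location_cm: float) -> int:
        """Time (ms) the condition's hand template passes a location."""
        n = int(self.durations_ms[condition]) + 1
        pos = self.hand_profile(condition, n)
        idx = np.nonzero(pos >= location_cm / 100.0)[0]
        if idx.size == 0:
            raise ValueError(f"template never reaches {location_cm} cm")
        return int(idx[0])

    def time_to_target_ms(self, condition: str, location_cm: float) -> float:
        """Ground-truth post-perturbation time-to-target for a location."""
        geom = self.geometry
        i = geom.perturbation_locations_cm.index(location_cm)
        remaining = self.durations_ms[condition] - self.crossing_ms(
            condition, location_cm
        )
        return float(remaining + self.extensions_ms[i])


@lru_cache(maxsize=64)
def _hand_profile_cached(peak_pct: float, dur: float, distance_cm: float, n_ms: int):
    frac = peak_pct / 100.0
    d = distance_cm / 100.0
    mirrored = frac > 0.5
    gamma = _warp_gamma_for_peak(1.0 - frac if mirrored else frac)
    n_move = int(dur) + 1
    u = np.arange(n_move) / dur
    pos = d * minimum_jerk(u**gamma)
    if mirrored:
        pos = d - pos[::-1]
    out = np.full(n_ms, d)
    out[: min(n_move, n_ms)] = pos[: min(n_move, n_ms)]
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class SyntheticDataset:
    trials: list
    truth: GroundTruth


def truth_report(dataset) -> GroundTruth:
    """The ground truth embedded in a generated dataset (read-only)."""
    if not isinstance(dataset, SyntheticDataset) or dataset.truth.seed is None:
        raise ValueError("not a dataset produced by this generator")
    return dataset.truth


def _corrective_pulse(n_ms: int, onset_ms: int, latency_ms: float, target_mean: float,
                      window_ms=(180, 230), width_ms: float = 250.0) -> np.ndarray:
    """Zero force until onset+latency, then a minimum-jerk-velocity bump
    scaled so its mean over the intensity window equals ``target_mean``."""
    t = np.arange(n_ms, dtype=float)
    start = onset_ms + latency_ms
    s = np.clip((t - start) / width_ms, 0.0, 1.0)
    bump = 30 * s**2 - 60 * s**3 + 30 * s**4  # minimum-jerk velocity shape
    lo, hi = onset_ms + window_ms[0], onset_ms + window_ms[1]
    ref = bump[lo : hi + 1].mean()
    if ref <= 0:
        raise ValueError("intensity window precedes the response")
    return bump * (target_mean / ref)


def _maintained_paths(truth: GroundTruth, condition: str, location_cm, sign: float,
                      n_ms: int):
    """Cursor and hand paths of a maintained trial.

    Up to the perturbation the cursor follows the condition's hand template.
    The jump displaces the cursor laterally; from onset the cursor re-plans
    a straight minimum-jerk approach to the target whose duration is set so
    that the first entry into the behavioral radius lands exactly at the
    ground-truth time-to-target.  The hand is the cursor minus the
    maintained offset.
    """
    geom = truth.geometry
    d = geom.movement_distance_cm / 100.0
    target = np.array([0.0, d])
    forward = truth.hand_profile(condition, n_ms)
    cursor = np.column_stack([np.zeros(n_ms), forward])
    offset = np.zeros(n_ms)
    if location_cm is None:
        return cursor, cursor.copy(), None
    onset = truth.crossing_ms(condition, location_cm)
    jump = sign * geom.perturbation_amplitude_cm / 100.0
    ttt = truth.time_to_target_ms(condition, location_cm)

    p0 = np.array([jump, forward[onset]])
    d_rem = float(np.linalg.norm(target - p0))
    radius = geom.target_radius_behavior_cm / 100.0
    # choose the re-plan duration so the radius crossing is at onset + ttt
    frac = 1.0 - (radius - 1e-6) / d_rem
    s_star = optimize.brentq(lambda s: minimum_jerk(s) - frac, 1e-9, 1.0)
    T = ttt / s_star
    t_rel = np.clip((np.arange(n_ms) - onset) / T, 0.0, 1.0)
    post = p0[None, :] + (target - p0)[None, :] * minimum_jerk(t_rel)[:, None]
    cursor[onset:] = post[onset:]
    offset[onset:] = jump
    hand = cursor.copy()
    hand[:, 0] -= offset
    return cursor, hand, onset


def generate_dataset(
    n_participants: int,
    blocks: int,
    seed: int,
    truth: GroundTruth | None = None,
    conditions=None,
) -> SyntheticDataset:
    """Generate a complete synthetic dataset; byte-identical given the seed.

    Each (participant, condition, block) yields 22 trials: for every
    perturbation location and direction one channel and one maintained
    trial, plus one of each with zero perturbation.
    """
    truth = truth if truth is not None else GroundTruth()
    if truth.latency_ms < 0 or truth.noise_sd < 0:
        raise ValueError("latency and noise sd must be non-negative")
    for cond in truth.durations_ms:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r} in truth tables")
    truth = replace(truth, seed=seed)
    conditions = list(conditions or CONDITIONS)
    rng = np.random.default_rng(seed)
    geom = truth.geometry
    locations = geom.perturbation_locations_cm
    trials: list[TrialRecord] = []

    for part in range(1, n_participants + 1):
        for cond in conditions:
            dur = truth.durations_ms[cond]
            n_ms = int(dur + max(truth.extensions_ms) + 700)
            t_ms = np.arange(n_ms, dtype=float)
            forward = truth.hand_profile(cond, n_ms)
            hand_vel = np.column_stack(
                [np.zeros(n_ms), np.gradient(forward, 1e-3)]
            )
            for block in range(1, blocks + 1):
                probe_specs = [(loc, s) for loc in locations for s in ("left", "right")]
                probe_specs.append((None, "none"))
                for loc, side in probe_specs:
                    sign = {"left": -1.0, "right": +1.0, "none": 0.0}[side]
                    # channel trial: hand laterally constrained
                    hand_pos = np.column_stack([np.zeros(n_ms), forward])
                    force = np.zeros(n_ms)
                    onset = None
                    if loc is not None:
                        onset = truth.crossing_ms(cond, loc)
                        g = eval_tuning(
                            truth.time_to_target_ms(cond, loc) / 1e3,
                            truth.tuning_for(cond),
                        )
                        # corrective force opposes the jump
                        force = -sign * _corrective_pulse(
                            n_ms, onset, truth.latency_ms, g
                        )
                    force = force + truth.noise_sd * rng.standard_normal(n_ms)
                    trials.append(
                        TrialRecord(
                            participant=part,
                            condition=cond,
                            block=block,
                            trial_type="channel",
                            location_cm=loc,
                            direction=side,
                            t_ms=t_ms.copy(),
                            hand_pos=hand_pos,
                            hand_vel=hand_vel.copy(),
                            cursor_pos=hand_pos.copy(),
                            pert_onset_ms=onset,
                            channel_force=force,
                        )
                    )
                    # maintained trial: free hand, active correction
                    cursor, hand, onset_m = _maintained_paths(
                        truth, cond, loc, sign, n_ms
                    )
                    vel = np.gradient(hand, 1e-3, axis=0)
                    trials.append(
                        TrialRecord(
                            participant=part,
                            condition=cond,
                            block=block,
                            trial_type="maintained",
                            location_cm=loc,
                            direction=side,
                            t_ms=t_ms.copy(),
                            hand_pos=hand,
                            hand_vel=vel,
                            cursor_pos=cursor,
                            pert_onset_ms=onset_m,
                            channel_force=None,
                        )
                    )
    return SyntheticDataset(trials=trials, truth=truth)
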