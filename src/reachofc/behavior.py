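"""Extraction of feedback intensities, onsets and times-to-target from trials.

Works on per-trial time series sampled at 1 kHz, either recorded or produced
by the synthetic-participant generator.  Probe (channel) trials constrain the
hand laterally in a stiff simulated channel, so the lateral channel force is
a clean readout of the corrective response to a cursor jump; maintained
perturbation trials leave the hand free and must be actively corrected,
yielding movement durations and times-to-target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

FS_HZ = 1000.0  # trial sampling rate

#: behavioral window for feedback intensity, ms after perturbation onset
INTENSITY_WINDOW_MS = (180, 230)


@dataclass
class TrialRecord:
    """One behavioral trial at 1 kHz.

    ``t_ms`` is the time axis in ms from the go signal; ``pert_onset_ms`` the
    perturbation (cursor jump) instant on that axis, or ``None`` for
    zero-perturbation trials.  ``channel_force`` (lateral, N) is present iff
    the trial is a channel trial.  Sign conventions: leftward = -x.
    """

    participant: int
    condition: str
    block: int
    trial_type: str  # 'channel' | 'maintained'
    location_cm: float | None
    direction: str  # 'left' | 'right' | 'none'
    t_ms: np.ndarray
    hand_pos: np.ndarray  # (n, 2) m
    hand_vel: np.ndarray  # (n, 2) m/s
    cursor_pos: np.ndarray  # (n, 2) m
    pert_onset_ms: int | None
    channel_force: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.allclose(np.diff(self.t_ms), 1.0):
            raise ValueError("trials must be uniformly sampled at 1 kHz")
        if (self.trial_type == "channel") != (self.channel_force is not None):
            raise ValueError("channel force present iff trial type is channel")


class NeverInterceptedError(RuntimeError):
    pass


def lowpass_filter(series, cutoff_hz: float = 40.0, order: int = 10, fs: float = FS_HZ):
    """Zero-phase low-pass Butterworth filter.

    ``order`` is the total (two-pass) order: a half-order filter applied
    forward and backward, the standard zero-phase construction.  DC gain is
    exactly 1 and the impulse response is symmetric, so timing of response
    onsets is not biased.
    """
    if order % 2 != 0 or order < 2:
        raise ValueError("total filter order must be even and >= 2")
    series = np.asarray(series, dtype=float)
    sos = signal.butter(order // 2, cutoff_hz, fs=fs, output="sos")
    padlen = 3 * (2 * (order // 2) + 1)
    if series.shape[-1] <= padlen:
        raise ValueError(f"series too short for filter warm-up ({padlen} samples)")
    return signal.sosfiltfilt(sos, series, axis=-1)


def feedback_intensity(
    left: TrialRecord,
    right: TrialRecord,
    window_ms: tuple[int, int] = INTENSITY_WINDOW_MS,
    divisor: float = 2.0,
) -> float:
    """Visuomotor feedback intensity from a left/right channel-trial pair.

    Mean of (force_left - force_right) / divisor over the window after the
    perturbation onset.  A leftward cursor jump elicits a rightward (+x)
    corrective push and vice versa, so the difference is positive for
    corrective responses.  The divisor (default 2) makes the value the mean
    corrective force per single perturbation.
    """
    for tr, expect in ((left, "left"), (right, "right")):
        if tr.trial_type != "channel":
            raise ValueError("feedback intensity needs channel trials")
        if tr.direction != expect:
            raise ValueError(f"expected a {expect}-perturbation trial")
    if (left.block, left.location_cm) != (right.block, right.location_cm):
        raise ValueError("trials must share block and perturbation location")
    lo, hi = window_ms
    vals = []
    for tr in (left, right):
        i0 = int(tr.pert_onset_ms) + lo
        i1 = int(tr.pert_onset_ms) + hi
        if i1 >= tr.t_ms.size:
            raise ValueError("trial ends before the intensity window closes")
        vals.append(tr.channel_force[i0 : i1 + 1])
    return float(np.mean(vals[0] - vals[1]) / divisor)


@dataclass(frozen=True)
class OnsetEstimate:
    """Feedback-response onset from the aROC scan.

    ``onset_ms`` is the fitted breakpoint (ms after perturbation onset), or
    ``None`` when the discrimination criterion was never met -- distinct
    from an onset at 0 ms.
    """

    onset_ms: float | None
    criterion_ms: float | None
    slope: float | None

    @property
    def detected(self) -> bool:
        return self.onset_ms is not None


def _aroc(a: np.ndarray, b: np.ndarray) -> float:
    """Area under the ROC curve for samples a vs b: P(a > b) + 0.5 P(a = b)."""
    diff = a[:, None] - b[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def aroc_onset(
    left_trials,
    right_trials,
    start_ms: int = -50,
    threshold: float = 0.75,
    consecutive_ms: int = 10,
    max_scan_ms: int = 600,
) -> OnsetEstimate:
    """Time-stamp the divergence of left- and right-perturbation forces.

    Builds the ROC area between the two per-trial force distributions at
    every millisecond from ``start_ms`` before the perturbation, scans until
    the aROC exceeds the threshold for ``consecutive_ms`` running
    milliseconds, then fits ``max(0.5, k*(t - tau))`` to the aROC series up
    to that criterion time; the onset is the breakpoint where the linear
    component first overtakes the constant one.  The aROC depends only on
    the ranks of the samples, so it is invariant to any common monotone
    transform of the forces.
    """
    lefts = list(left_trials)
    rights = list(right_trials)
    if len(lefts) < 2 or len(rights) < 2:
        raise ValueError("need at least two trials per perturbation direction")

    def aligned(trials, sign):
        rows = []
        for tr in trials:
            i0 = int(tr.pert_onset_ms)
            rows.append(sign * tr.channel_force[i0 + start_ms : i0 + max_scan_ms])
        n = min(len(r) for r in rows)
        return np.asarray([r[:n] for r in rows])

    # orient so the expected corrective difference (left minus right) is +
    fl = aligned(lefts, +1.0)
    fr = aligned(rights, +1.0)
    n_t = min(fl.shape[1], fr.shape[1])
    times = np.arange(n_t) + start_ms
    aroc = np.array([_aroc(fl[:, i], fr[:, i]) for i in range(n_t)])

    above = aroc > threshold
    crit_idx = None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= consecutive_ms:
            crit_idx = i
            break
    if crit_idx is None:
        return OnsetEstimate(onset_ms=None, criterion_ms=None, slope=None)

    seg_t = times[: crit_idx + 1].astype(float)
    seg_a = aroc[: crit_idx + 1]

    def sse_for(tb: float):
        ramp = np.clip(seg_t - tb, 0.0, None)
        denom = float(ramp @ ramp)
        if denom == 0.0:
            return np.inf, 0.0
        k = float(ramp @ (seg_a - 0.5)) / denom
        if k <= 0:
            return np.inf, k
        resid = seg_a - np.maximum(0.5, 0.5 + k * (seg_t - tb))
        return float(resid @ resid), k

    # coarse 1 ms grid, then 0.1 ms refinement around the best breakpoint
    coarse = np.arange(seg_t[0], seg_t[-1], 1.0)
    sses = [sse_for(tb)[0] for tb in coarse]
    tb0 = coarse[int(np.argmin(sses))]
    fine = np.arange(tb0 - 1.0, tb0 + 1.0 + 1e-9, 0.1)
    sses = [sse_for(tb)[0] for tb in fine]
    tb = float(fine[int(np.argmin(sses))])
    _, k = sse_for(tb)
    return OnsetEstimate(onset_ms=tb, criterion_ms=float(times[crit_idx]), slope=k)


def movement_duration_and_ttt(
    trial: TrialRecord,
    target,
    radius_m: float = 0.006,
    location_cm: float | None = None,
) -> tuple[float, float]:
    """Movement duration and time-to-target of a maintained trial (ms).

    Duration: go to first interception (cursor-target distance below the
    behavioral radius).  Time-to-target: perturbation onset to first
    interception.  For unperturbed trials a ``location_cm`` must be given;
    the onset is then the instant the hand crossed that location, yielding
    the time-to-target a perturbation there would have faced.
    """
    if trial.trial_type != "maintained":
        raise ValueError("durations are measured on maintained trials")
    dist = np.linalg.norm(trial.cursor_pos - np.asarray(target), axis=1)
    hits = np.nonzero(dist < radius_m)[0]
    if hits.size == 0:
        raise NeverInterceptedError("trial never intercepts the target")
    arrival_ms = float(trial.t_ms[hits[0]])
    if trial.pert_onset_ms is not None:
        onset_ms = float(trial.pert_onset_ms)
    else:
        if location_cm is None:
            raise ValueError("unperturbed trials need a location for time-to-target")
        crossed = np.nonzero(trial.hand_pos[:, 1] >= location_cm / 100.0)[0]
        if crossed.size == 0:
            raise NeverInterceptedError("hand never crossed the requested location")
        onset_ms = float(trial.t_ms[crossed[0]])
    return arrival_ms, arrival_ms - onset_ms


def condition_summary(
    trials,
    target=(0.0, 0.25),
    window_ms: tuple[int, int] = INTENSITY_WINDOW_MS,
    radius_m: float = 0.006,
    divisor: float = 2.0,
) -> pd.DataFrame:
    """Per-(participant, condition, location) mean intensities and
    times-to-target.

    Channel-trial left/right pairs are formed within a block; leftward and
    rightward corrections are thereby collapsed into one (positive)
    intensity per pair.  Maintained trials contribute times-to-target.
    Trials that never intercept, and blocks missing one side of a pair, are
    skipped with a log entry.  The result is order-invariant.
    """
    channel: dict = {}
    ttts: dict = {}
    for tr in trials:
        if tr.location_cm is None or tr.direction == "none":
            continue
        key = (tr.participant, tr.condition, tr.location_cm)
        if tr.trial_type == "channel":
            channel.setdefault(key, {}).setdefault(tr.block, {})[tr.direction] = tr
        else:
            try:
                _, ttt = movement_duration_and_ttt(tr, target, radius_m)
            except NeverInterceptedError:
                log.info("skipping timed-out trial %s", key)
                continue
            ttts.setdefault(key, []).append(ttt)

    rows = []
    for key in sorted(set(channel) | set(ttts)):
        intensities = []
        for block, sides in sorted(channel.get(key, {}).items()):
            if "left" not in sides or "right" not in sides:
                log.info("block %s of %s missing a perturbation side", block, key)
                continue
            intensities.append(
                feedback_intensity(
                    sides["left"], sides["right"], window_ms, divisor
                )
            )
        rows.append(
            {
                "participant": key[0],
                "condition": key[1],
                "location_cm": key[2],
                "intensity": np.mean(intensities) if intensities else np.nan,
                "n_pairs": len(intensities),
                "time_to_target_ms": np.mean(ttts[key]) if key in ttts else np.nan,
            }
        )
    return pd.DataFrame(rows)
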