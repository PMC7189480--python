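"""Task geometry and the cursor-to-hand velocity mappings.

The experiment dissociates visual (cursor) from physical (hand) kinematics by
scaling the cursor's forward velocity relative to the hand's as a linear
function of the distance travelled.  In the *cursor-leads* map the cursor
moves at 160% of hand velocity at the start, falling linearly to 40% at the
target; the *cursor-lags* map is its mirror (40% rising to 160%).  Both maps
integrate to the identity over the full movement, so cursor and hand coincide
at the start and end of every reach.

Five conditions result: baseline (no scaling), two matched-cursor conditions
(cursor velocity looks like baseline, hand velocity peaks early or late) and
two matched-hand conditions (hand moves like baseline, cursor peaks early or
late).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: scaling modes
MODE_NONE = "none"
MODE_LEADS = "cursor-leads"
MODE_LAGS = "cursor-lags"


@dataclass(frozen=True)
class TaskGeometry:
    """Geometry of the reaching task (distances in cm, times in ms)."""

    movement_distance_cm: float = 25.0
    perturbation_locations_cm: tuple[float, ...] = (4.2, 8.3, 12.5, 16.7, 20.8)
    perturbation_amplitude_cm: float = 2.0
    probe_duration_ms: float = 250.0
    target_radius_behavior_cm: float = 0.6
    target_radius_model_cm: float = 0.4
    hold_ms: float = 600.0

    def __post_init__(self) -> None:
        locs = self.perturbation_locations_cm
        if any(b <= a for a, b in zip(locs, locs[1:])):
            raise ValueError("perturbation locations must be strictly increasing")
        if locs and locs[-1] >= self.movement_distance_cm:
            raise ValueError("perturbation locations must lie within the movement")


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: a label and the cursor scaling it uses."""

    label: str
    mode: str
    hand_peak_pct: float  # where the *hand* velocity peaks, % of distance

    def __post_init__(self) -> None:
        if (self.label == "baseline") != (self.mode == MODE_NONE):
            raise ValueError("baseline if and only if scaling mode is none")


#: The five conditions.  In matched-cursor conditions the hand is skewed and
#: the cursor looks like baseline; in matched-hand conditions the reverse.
CONDITIONS: dict[str, ConditionSpec] = {
    "baseline": ConditionSpec("baseline", MODE_NONE, 50.0),
    "matched-cursor-late": ConditionSpec("matched-cursor-late", MODE_LEADS, 66.0),
    "matched-cursor-early": ConditionSpec("matched-cursor-early", MODE_LAGS, 33.0),
    "matched-hand-early": ConditionSpec("matched-hand-early", MODE_LEADS, 50.0),
    "matched-hand-late": ConditionSpec("matched-hand-late", MODE_LAGS, 50.0),
}


def cursor_gain(d, mode: str):
    """Cursor/hand forward velocity ratio at distance ``d`` (% of movement).

    Accepts scalars or arrays; raises on ``d`` outside [0, 100] or an unknown
    mode.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > 100):
        raise ValueError("distance must lie in [0, 100] percent")
    if mode == MODE_NONE:
        out = np.ones_like(d)
    elif mode == MODE_LEADS:
        out = -0.012 * d + 1.6
    elif mode == MODE_LAGS:
        out = 0.012 * d + 0.4
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return out if out.ndim else float(out)


def apply_cursor_mapping(
    hand_pos: np.ndarray, mode: str, lateral_offsets: np.ndarray | None = None
) -> np.ndarray:
    """Map a hand trajectory to the cursor trajectory for a scaling mode.

    ``hand_pos`` is (n, 2) with columns (lateral x, forward y); the forward
    component must rise monotonically from 0 to the movement distance.  The
    cursor's forward velocity is ``gain(d) * hand forward velocity`` and is
    integrated on the same sample grid (trapezoid rule); the lateral cursor
    position equals the lateral hand position plus any commanded perturbation
    offsets.
    """
    hand_pos = np.asarray(hand_pos, dtype=float)
    y = hand_pos[:, 1]
    if np.any(np.diff(y) < -1e-12):
        raise ValueError("hand forward position must be monotone non-decreasing")
    distance = y[-1]
    if distance <= 0:
        raise ValueError("hand trajectory must cover a positive forward distance")
    if mode == MODE_NONE:
        cursor_y = y.copy()
    else:
        d_pct = np.clip(100.0 * y / distance, 0.0, 100.0)
        gain = cursor_gain(d_pct, mode)
        # v_c dt = gain * v_h dt = gain * dy, integrated by trapezoid in y-steps
        dy = np.diff(y)
        mid_gain = 0.5 * (gain[:-1] + gain[1:])
        cursor_y = np.concatenate([[y[0]], y[0] + np.cumsum(mid_gain * dy)])
    cursor = np.column_stack([hand_pos[:, 0], cursor_y])
    if lateral_offsets is not None:
        cursor[:, 0] = cursor[:, 0] + np.asarray(lateral_offsets, dtype=float)
    return cursor
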