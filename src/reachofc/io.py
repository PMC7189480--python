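"""Columnar text export/import for trajectories, trials and configuration."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import TrialRecord
from .lqg import Trajectory
from .plant import PlantParams

TRAJ_COLUMNS = ["time", "px", "py", "vx", "vy", "fx", "fy", "ux", "uy", "tx", "ty"]


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """A trajectory as a tidy table (controls padded with NaN at the final
    state, which has no control)."""
    n = traj.states.shape[0]
    controls = np.full((n, 2), np.nan)
    controls[:-1] = traj.controls
    data = np.column_stack(
        [traj.times, traj.states[:, :2], traj.states[:, 2:4], traj.states[:, 4:6],
         controls, traj.states[:, 6:8]]
    )
    return pd.DataFrame(data, columns=TRAJ_COLUMNS)


def write_trajectory(traj: Trajectory, path) -> None:
    trajectory_frame(traj).to_csv(path, index=False)


def save_config(params: PlantParams, path, **extra) -> None:
    """Flat key-value config with the plant parameters plus solver extras."""
    cfg = {
        "m": params.m,
        "b": params.b,
        "tau": params.tau,
        "dt": params.dt,
        "c_scale": params.c_scale,
        "d_scale": list(params.d_scale),
    }
    cfg.update(extra)
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def load_config(path) -> tuple[PlantParams, dict]:
    """Read a config file; returns the plant parameters and any extras."""
    cfg = yaml.safe_load(Path(path).read_text())
    params = PlantParams(
        m=cfg.pop("m"),
        b=cfg.pop("b"),
        tau=cfg.pop("tau"),
        dt=cfg.pop("dt"),
        c_scale=cfg.pop("c_scale", 0.5),
        d_scale=tuple(cfg.pop("d_scale")),
    )
    return params, cfg


def trials_frame(trials) -> pd.DataFrame:
    """Long-format table of trial time series (one row per sample)."""
    parts = []
    for i, tr in enumerate(trials):
        n = tr.t_ms.size
        parts.append(
            pd.DataFrame(
                {
                    "trial_id": i,
                    "participant": tr.participant,
                    "condition": tr.condition,
                    "block": tr.block,
                    "trial_type": tr.trial_type,
                    "location_cm": np.nan if tr.location_cm is None else tr.location_cm,
                    "direction": tr.direction,
                    "pert_onset_ms": np.nan
                    if tr.pert_onset_ms is None
                    else tr.pert_onset_ms,
                    "t_ms": tr.t_ms,
                    "hand_x": tr.hand_pos[:, 0],
                    "hand_y": tr.hand_pos[:, 1],
                    "vel_x": tr.hand_vel[:, 0],
                    "vel_y": tr.hand_vel[:, 1],
                    "cursor_x": tr.cursor_pos[:, 0],
                    "cursor_y": tr.cursor_pos[:, 1],
                    "channel_force": np.full(n, np.nan)
                    if tr.channel_force is None
                    else tr.channel_force,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_trials(trials, path) -> None:
    trials_frame(trials).to_csv(path, index=False)


def read_trials(path) -> list[TrialRecord]:
    """Rebuild TrialRecords from a long-format trial table."""
    df = pd.read_csv(path)
    trials = []
    for _, g in df.groupby("trial_id", sort=True):
        loc = g["location_cm"].iloc[0]
        onset = g["pert_onset_ms"].iloc[0]
        force = g["channel_force"].to_numpy()
        trials.append(
            TrialRecord(
                participant=int(g["participant"].iloc[0]),
                condition=str(g["condition"].iloc[0]),
                block=int(g["block"].iloc[0]),
                trial_type=str(g["trial_type"].iloc[0]),
                location_cm=None if np.isnan(loc) else float(loc),
                direction=str(g["direction"].iloc[0]),
                t_ms=g["t_ms"].to_numpy(dtype=float),
                hand_pos=g[["hand_x", "hand_y"]].to_numpy(),
                hand_vel=g[["vel_x", "vel_y"]].to_numpy(),
                cursor_pos=g[["cursor_x", "cursor_y"]].to_numpy(),
                pert_onset_ms=None if np.isnan(onset) else int(onset),
                channel_force=None if np.isnan(force).all() else force,
            )
        )
    return trials
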