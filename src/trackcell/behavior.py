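"""Position linearization, lap segmentation, speed, and the running mask.

Everything downstream (rate curves, information measures, pair analyses)
consumes only the output of this module: a linearized sample table with a
per-sample ``running`` flag and a lap table.  The conventions are

* position is expressed as cm along the track in the direction of running,
  so the two opposite trajectories have mirrored coordinates;
* a lap runs from the last sample inside the departure food-well zone to
  the first sample inside the opposite zone; traversals that turn around
  mid-track without reaching the far well are discarded;
* samples are flagged not-running inside the ~10-cm food-well zones and
  inside any stopping interval (speed below a floor for a minimum time).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import TrackGeometry

__all__ = [
    "linearize_and_segment",
    "compute_speed_and_mask",
    "behavior_metrics",
]

#: linearized-sample table columns produced here
LINEARIZED_COLUMNS = [
    "t_s",
    "s_cm",
    "pos_cm",
    "speed_cms",
    "hd_deg",
    "trajectory",
    "lap",
    "running",
]


def linearize_and_segment(
    positions: pd.DataFrame,
    geometry: TrackGeometry,
    well_margin_cm: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project tracked positions onto the track path and segment laps.

    Parameters
    ----------
    positions : DataFrame
        Columns ``t_s, x_cm, y_cm, hd_deg``; timestamps strictly increasing.
    geometry : TrackGeometry
        The track path; trajectory 1 runs from its first vertex to its
        last, trajectory 2 the opposite way.
    well_margin_cm : float
        Extent of the food-well zone at each end used to delimit laps.

    Returns
    -------
    linearized : DataFrame
        One row per tracking sample with columns ``t_s, s_cm`` (arclength
        from the trajectory-1 start), ``pos_cm`` (cm along the lap's
        running direction), ``speed_cms`` (NaN until
        :func:`compute_speed_and_mask`), ``hd_deg``, ``trajectory``
        (1, 2, or 0 outside any lap), ``lap`` (1-based per trajectory, 0
        outside), ``running`` (False until masked).
    laps : DataFrame
        Columns ``trajectory, lap_index, t_start, t_end``.
    """
    if len(positions) < 2:
        raise ValueError("need at least 2 position samples")
    t = positions["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("position timestamps must be strictly increasing")
    L = geometry.length_cm
    s = geometry.project(positions[["x_cm", "y_cm"]].to_numpy(dtype=float))

    in_a = s < well_margin_cm
    in_b = s > L - well_margin_cm

    # walk the well-zone visits; a lap is a zone-A..zone-B (or B..A)
    # crossing with no intermediate return to the departure zone
    trajectory = np.zeros(len(t), dtype=np.int8)
    lap = np.zeros(len(t), dtype=np.int32)
    laps_out: list[tuple[int, int, float, float]] = []
    lap_counter = {1: 0, 2: 0}
    last_zone = 0  # 0 none, 1 = well A (s=0 end), 2 = well B
    last_idx = -1
    zone_idx = np.flatnonzero(in_a | in_b)
    for i in zone_idx:
        z = 1 if in_a[i] else 2
        if last_zone and z != last_zone:
            traj = 1 if last_zone == 1 else 2
            lap_counter[traj] += 1
            trajectory[last_idx : i + 1] = traj
            lap[last_idx : i + 1] = lap_counter[traj]
            laps_out.append((traj, lap_counter[traj], t[last_idx], t[i]))
        last_zone = z
        last_idx = i

    pos = np.where(trajectory == 2, L - s, s)
    linearized = pd.DataFrame(
        {
            "t_s": t,
            "s_cm": s,
            "pos_cm": pos,
            "speed_cms": np.nan,
            "hd_deg": positions["hd_deg"].to_numpy(dtype=float),
            "trajectory": trajectory,
            "lap": lap,
            "running": False,
        }
    )
    laps = pd.DataFrame(
        laps_out, columns=["trajectory", "lap_index", "t_start", "t_end"]
    )
    return linearized, laps


def compute_speed_and_mask(
    linearized: pd.DataFrame,
    track_length_cm: float,
    well_margin_cm: float = 10.0,
    speed_floor_cms: float = 6.0,
    stop_min_s: float = 0.5,
) -> pd.DataFrame:
    """Fill per-sample speed and the active-running mask.

    Speed is the forward difference of linearized distance,
    ``|s[i+1] - s[i]| / (t[i+1] - t[i])``; the last sample copies its
    predecessor.  A sample is ``running`` iff it belongs to a lap, lies
    outside the two food-well zones (within ``well_margin_cm`` of either
    track end), and is not inside a stopping interval — a maximal run of
    samples with speed below ``speed_floor_cms`` spanning at least
    ``stop_min_s`` seconds.  The operation is idempotent.
    """
    out = linearized.copy()
    t = out["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    s = out["s_cm"].to_numpy(dtype=float)
    dt = np.diff(t)
    speed = np.empty_like(s)
    speed[:-1] = np.abs(np.diff(s)) / dt
    speed[-1] = speed[-2] if len(speed) > 1 else 0.0
    out["speed_cms"] = speed

    in_well = (s < well_margin_cm) | (s > track_length_cm - well_margin_cm)

    # stopping intervals: forward-looking speed below the floor for long
    # enough; the run i0..i1 covers the time span [t[i0], t[i1 + 1]]
    slow = speed < speed_floor_cms
    stopped = np.zeros(len(t), dtype=bool)
    if slow.any():
        edges = np.diff(slow.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if slow[0]:
            starts.insert(0, 0)
        if slow[-1]:
            ends.append(len(t))
        for i0, i1 in zip(starts, ends):
            t_end = t[i1] if i1 < len(t) else t[-1]
            if t_end - t[i0] >= stop_min_s:
                stopped[i0:i1] = True

    out["running"] = (out["lap"].to_numpy() > 0) & ~in_well & ~stopped
    return out


def behavior_metrics(laps: pd.DataFrame, linearized: pd.DataFrame) -> pd.DataFrame:
    """Per-trajectory laps per minute and mean running speed.

    Laps/min uses the whole session duration; mean speed averages over
    running samples of the trajectory only.
    """
    if len(laps) == 0:
        warnings.warn("no laps found; behavior metrics empty")
        return pd.DataFrame(columns=["trajectory", "n_laps", "laps_per_min", "mean_speed_cms"])
    t = linearized["t_s"].to_numpy()
    session_min = (t[-1] - t[0]) / 60.0
    rows = []
    for traj, grp in laps.groupby("trajectory"):
        run = linearized[(linearized["trajectory"] == traj) & linearized["running"]]
        rows.append(
            {
                "trajectory": int(traj),
                "n_laps": int(len(grp)),
                "laps_per_min": len(grp) / session_min,
                "mean_speed_cms": float(run["speed_cms"].mean()) if len(run) else np.nan,
            }
        )
    return pd.DataFrame(rows)
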