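import numpy as np
import pandas as pd
import pytest

import trackcell as tc
from trackcell import behavior
from trackcell.geometry import TrackGeometry

SAMPLING_HZ = 33.0
DT = 1.0 / SAMPLING_HZ


def positions_from_arclength(s, track_length_cm=300.0, hd=None):
    """Build a noiseless positions table from an arclength series."""
    s = np.asarray(s, dtype=float)
    t = np.arange(len(s)) * DT
    if hd is None:
        hd = np.zeros(len(s))
    return pd.DataFrame({"t_s": t, "x_cm": s, "y_cm": 0.0, "hd_deg": hd})


def make_linearized(pos_per_lap, dt=0.1, trajectory=1, speed=None, hd=None):
    """Hand-built linearized table: one sub-list of positions per lap,
    all samples flagged running.  Gives full control over occupancy and
    spike placement for rate-curve and pair tests."""
    rows = []
    laps = []
    t = 0.0
    for k, lap_pos in enumerate(pos_per_lap, start=1):
        t0 = t
        for p in lap_pos:
            rows.append(
                {
                    "t_s": t,
                    "s_cm": p,
                    "pos_cm": p,
                    "speed_cms": speed if speed is not None else 30.0,
                    "hd_deg": hd if hd is not None else 0.0,
                    "trajectory": trajectory,
                    "lap": k,
                    "running": True,
                }
            )
            t += dt
        laps.append(
            {"trajectory": trajectory, "lap_index": k, "t_start": t0, "t_end": t - dt}
        )
    lin = pd.DataFrame(rows)
    return lin, pd.DataFrame(laps)


@pytest.fixture(scope="session")
def straight_track():
    return TrackGeometry.straight(300.0)


@pytest.fixture(scope="session")
def demo_session():
    """Small coupled V1/CA1 synthetic session plus its ground truth."""
    cfg = tc.demo_config(11)
    cfg.n_laps = 15
    return tc.generate_session(cfg)


@pytest.fixture(scope="session")
def demo_behavior(demo_session, straight_track):
    session, _ = demo_session
    lin, laps = behavior.linearize_and_segment(session.positions, straight_track)
    lin = behavior.compute_speed_and_mask(lin, session.track_length_cm)
    return lin, laps
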