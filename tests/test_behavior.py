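"""Lap segmentation, speed computation, and the active-running mask."""

import numpy as np
import pandas as pd
import pytest

import trackcell as tc
from trackcell import behavior
from trackcell.geometry import TrackGeometry

from conftest import DT, positions_from_arclength


class TestLinearizeAndSegment:
    def test_single_traverse_is_one_lap(self, straight_track):
        s = np.linspace(0, 300, 330)
        lin, laps = behavior.linearize_and_segment(
            positions_from_arclength(s), straight_track
        )
        assert len(laps) == 1
        assert laps.iloc[0]["trajectory"] == 1
        assert (laps["trajectory"] == 2).sum() == 0

    def test_midtrack_turnaround_is_no_lap(self, straight_track):
        s = np.concatenate([np.linspace(0, 150, 160), np.linspace(150, 0, 160)])
        _, laps = behavior.linearize_and_segment(
            positions_from_arclength(s), straight_track
        )
        assert len(laps) == 0

    def test_back_and_forth_gives_both_trajectories(self, straight_track):
        s = np.concatenate([np.linspace(0, 300, 330), np.linspace(300, 0, 330)])
        _, laps = behavior.linearize_and_segment(
            positions_from_arclength(s), straight_track
        )
        assert list(laps["trajectory"]) == [1, 2]
        # trajectory-2 positions run opposite to arclength
        lin, _ = behavior.linearize_and_segment(
            positions_from_arclength(s), straight_track
        )
        t2 = lin[lin["trajectory"] == 2]
        assert np.allclose(t2["pos_cm"], 300 - t2["s_cm"])

    def test_lap_boundaries_at_well_zone_edges(self, straight_track):
        s = np.linspace(0, 300, 301)  # 1 cm per sample
        lin, laps = behavior.linearize_and_segment(
            positions_from_arclength(s), straight_track
        )
        row = laps.iloc[0]
        i_start = int(round(row["t_start"] / DT))
        i_end = int(round(row["t_end"] / DT))
        assert s[i_start] < 10 <= s[i_start + 1]
        assert s[i_end] > 290 >= s[i_end - 1]

    def test_errors(self, straight_track):
        with pytest.raises(ValueError):
            behavior.linearize_and_segment(
                positions_from_arclength([0.0]), straight_track
            )
        with pytest.raises(ValueError):
            TrackGeometry([[0, 0], [0, 0]])

    def test_recovers_simulated_lap_schedule(self, demo_session, demo_behavior):
        _, truth = demo_session
        _, laps = demo_behavior
        assert len(laps) == len(truth.laps)
        merged = laps.merge(
            truth.laps, on=["trajectory", "lap_index"], suffixes=("", "_true")
        )
        assert len(merged) == len(laps)
        tol = DT + 1e-9  # one sample period
        assert (merged["t_start"] - merged["t_start_true"]).abs().max() <= tol
        assert (merged["t_end"] - merged["t_end_true"]).abs().max() <= tol

    def test_lap_intervals_disjoint_within_session(self, demo_behavior):
        _, laps = demo_behavior
        for _, grp in laps.groupby("trajectory"):
            grp = grp.sort_values("t_start")
            assert (grp["t_end"] > grp["t_start"]).all()
            assert (grp["t_start"].to_numpy()[1:] >= grp["t_end"].to_numpy()[:-1]).all()


class TestSpeedAndMask:
    def _session(self, s, L=300.0):
        lin, _ = behavior.linearize_and_segment(
            positions_from_arclength(s, L), TrackGeometry.straight(L)
        )
        return lin

    def test_constant_velocity_speed(self):
        s = np.arange(0, 300, 30 * DT)  # 30 cm/s
        lin = self._session(s)
        out = behavior.compute_speed_and_mask(lin, 300)
        assert np.allclose(out["speed_cms"], 30.0)

    def test_short_dip_below_floor_not_masked(self):
        # a 0.4-s slow dip mid-lap must survive the stop filter
        pre = np.arange(0, 150, 30 * DT)
        dip = pre[-1] + np.cumsum(np.full(int(0.4 / DT), 3.0 * DT))  # 3 cm/s
        post = dip[-1] + np.cumsum(np.full(200, 30 * DT))
        s = np.clip(np.concatenate([pre, dip, post]), 0, 300)
        out = behavior.compute_speed_and_mask(self._session(s), 300)
        dip_rows = out[(out["s_cm"] > pre[-1]) & (out["s_cm"] < dip[-1] + 1)]
        assert bool(dip_rows["running"].all())

    def test_long_stop_masked(self):
        pre = np.arange(0, 150, 30 * DT)
        stop = np.full(int(1.0 / DT), pre[-1])  # 1-s full stop
        post = pre[-1] + np.cumsum(np.full(200, 30 * DT))
        s = np.clip(np.concatenate([pre, stop, post]), 0, 300)
        out = behavior.compute_speed_and_mask(self._session(s), 300)
        # the final stationary sample's forward difference already spans
        # the resumed motion, so it may stay unmasked (one sample period)
        stopped = out.iloc[len(pre) : len(pre) + len(stop) - 1]
        assert not stopped["running"].any()

    def test_well_zones_masked_regardless_of_speed(self):
        s = np.arange(0, 300, 30 * DT)
        out = behavior.compute_speed_and_mask(self._session(s), 300)
        assert not out.loc[out["s_cm"] < 10, "running"].any()
        assert not out.loc[out["s_cm"] > 290, "running"].any()
        mid = out[(out["s_cm"] > 50) & (out["s_cm"] < 250)]
        assert mid["running"].all()

    def test_masking_is_idempotent(self, demo_behavior):
        lin, _ = demo_behavior
        again = behavior.compute_speed_and_mask(lin, 300)
        assert np.array_equal(lin["running"].to_numpy(), again["running"].to_numpy())
        assert np.allclose(lin["speed_cms"], again["speed_cms"])

    def test_scripted_pause_duration_recovered(self, straight_track):
        pause = tc.PauseSpec(trajectory=1, lap_index=2, pos_cm=150.0, duration_s=2.0)
        cfg = tc.SyntheticConfig(n_laps=3, pauses=[pause], master_seed=5)
        session, _ = tc.generate_session(cfg)
        lin, laps = behavior.linearize_and_segment(session.positions, straight_track)
        lin = behavior.compute_speed_and_mask(lin, 300)
        # masked-but-in-lap, mid-track samples are exactly the scripted stop
        midtrack = (lin["s_cm"] > 10) & (lin["s_cm"] < 290)
        masked = lin[(lin["lap"] > 0) & midtrack & ~lin["running"]]
        dur = len(masked) * DT
        assert dur == pytest.approx(2.0, abs=2 * DT)

    def test_non_monotone_timestamps_rejected(self):
        lin = self._session(np.arange(0, 300, 30 * DT))
        lin.loc[5, "t_s"] = lin.loc[4, "t_s"]
        with pytest.raises(ValueError):
            behavior.compute_speed_and_mask(lin, 300)


class TestBehaviorMetrics:
    def test_laps_per_minute_arithmetic(self):
        # 10 laps on one trajectory over a 5-minute session
        lin = pd.DataFrame(
            {
                "t_s": [0.0, 300.0],
                "s_cm": [0.0, 300.0],
                "pos_cm": [0.0, 300.0],
                "speed_cms": [35.0, 35.0],
                "hd_deg": [0.0, 0.0],
                "trajectory": [1, 1],
                "lap": [1, 1],
                "running": [True, True],
            }
        )
        laps = pd.DataFrame(
            {
                "trajectory": [1] * 10,
                "lap_index": range(1, 11),
                "t_start": np.arange(10) * 30.0,
                "t_end": np.arange(10) * 30.0 + 25.0,
            }
        )
        tbl = behavior.behavior_metrics(laps, lin)
        assert tbl.iloc[0]["laps_per_min"] == pytest.approx(2.0)
        assert tbl.iloc[0]["mean_speed_cms"] == pytest.approx(35.0)

    def test_no_laps_warns_and_returns_empty(self):
        lin = pd.DataFrame(
            {"t_s": [0.0, 1.0], "s_cm": [0, 1], "pos_cm": [0, 1],
             "speed_cms": [1, 1], "hd_deg": [0, 0], "trajectory": [0, 0],
             "lap": [0, 0], "running": [False, False]}
        )
        with pytest.warns(UserWarning):
            tbl = behavior.behavior_metrics(lin.iloc[:0].assign(), lin)
        assert len(tbl) == 0

    def test_simulated_mean_speed_near_target(self, demo_session, demo_behavior):
        lin, laps = demo_behavior
        tbl = behavior.behavior_metrics(laps, lin)
        # mean speed drawn around 35 cm/s; 3-SE band given lap-level spread
        assert np.allclose(tbl["mean_speed_cms"], 35.0, atol=1.5)
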