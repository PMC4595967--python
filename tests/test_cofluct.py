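"""Pair classification, lap-by-lap Δrate/ΔCOM, behavior regression, COM shift."""

import math

import numpy as np
import pytest

from trackcell.cofluct import (
    PairRecord,
    circular_mean_deg,
    classify_pair,
    com_shift_curve,
    lap_fluctuations,
    pair_correlation,
    regress_out_behavior,
    wrap_deg,
)
from trackcell.fields import FiringField
from trackcell.spikexcorr import SpikeXcorr

from conftest import make_linearized


def ff(start, end, peak_pos, peak, cell="c", traj=1):
    return FiringField(cell, traj, start, end, peak_pos, peak)


def xc(peak_value, peak_time):
    return SpikeXcorr("a", "b", np.array([0.0]), np.array([peak_value]),
                      peak_value, peak_time, peak_value > 8)


class TestClassifyPair:
    def test_overlapping_by_arithmetic(self):
        # [100,140) vs [110,150): overlap 30 of shorter 40 -> 75%
        rec = classify_pair(
            [ff(100, 140, 120, 10, "a")], [ff(110, 150, 130, 12, "b")],
            True, True, xc(9.0, 0.04), np.random.default_rng(0),
        )
        assert rec.pair_class == "overlapping"
        assert rec.overlap_frac == pytest.approx(0.75)
        assert rec.interval_a == (100, 140)

    def test_overlap_without_xcorr_peak_is_excluded(self):
        rec = classify_pair(
            [ff(100, 140, 120, 10, "a")], [ff(110, 150, 130, 12, "b")],
            True, True, xc(5.0, 0.04), np.random.default_rng(0),
        )
        assert rec is None

    def test_most_dominant_overlapped_pair_probed(self):
        a_fields = [ff(100, 140, 120, 4, "a"), ff(200, 240, 220, 10, "a")]
        b_fields = [ff(110, 150, 130, 5, "b"), ff(205, 245, 225, 9, "b")]
        rec = classify_pair(a_fields, b_fields, True, True, xc(9.0, 0.0),
                            np.random.default_rng(0))
        assert rec.interval_a == (200, 240)
        assert rec.interval_b == (205, 245)

    def test_disjoint_fields_non_overlapping(self):
        rec = classify_pair(
            [ff(50, 90, 70, 10, "a")], [ff(200, 240, 220, 12, "b")],
            True, True, xc(12.0, 0.0), np.random.default_rng(0),
        )
        assert rec.pair_class == "non_overlapping"
        assert rec.interval_a == (50, 90)
        assert rec.interval_b == (200, 240)

    def test_non_responsive_gets_shifted_probe(self):
        f = ff(100, 140, 120, 10, "a")
        recs = [
            classify_pair([f], [], True, False, None, np.random.default_rng(s))
            for s in range(50)
        ]
        for rec in recs:
            assert rec.pair_class == "non_responsive"
            assert rec.interval_a == (100, 140)
            lo, hi = rec.interval_b
            assert hi - lo == pytest.approx(40.0)
            overlap = max(0.0, min(hi, 140) - max(lo, 100))
            assert 0.5 - 1e-9 <= overlap / 40.0 <= 1.0
        # shifts actually vary and go both ways
        shifts = np.array([r.interval_b[0] - 100 for r in recs])
        assert (shifts > 0).any() and (shifts < 0).any()

    def test_neither_responsive_skipped(self):
        assert classify_pair([], [], False, False, None,
                             np.random.default_rng(0)) is None


def _pair_session(rates_a, rates_b, coms_a=None, coms_b=None, interval=(100.0, 110.0)):
    """Laps sweeping [95, 115); spikes per lap placed to realize the
    requested within-interval rates (in-interval time is 2 s/lap)."""
    n_laps = len(rates_a)
    pos = list(np.arange(95.0, 115.0, 0.5))  # 40 samples, dt 0.1 -> 4 s/lap
    lin, laps = make_linearized([pos] * n_laps, dt=0.1)
    lap_dur = len(pos) * 0.1

    def spikes_for(rates, coms):
        out = []
        for k, r in enumerate(rates):
            n = int(round(r * 2.0))  # 2 s inside the interval
            if n == 0:
                continue
            com = interval[0] + 5.0 if coms is None else coms[k]
            # sample times whose positions straddle the requested COM
            base = k * lap_dur
            idx = int((com - 95.0) / 0.5)
            times = [base + (idx + d) * 0.1 for d in range(-(n // 2), n - n // 2)]
            out += times
        return np.sort(out)

    return (
        spikes_for(rates_a, coms_a),
        spikes_for(rates_b, coms_b),
        laps,
        lin,
    )


class TestLapFluctuations:
    def _record(self, interval=(100.0, 110.0)):
        return PairRecord("a", "b", 1, "overlapping", interval, interval, 1.0)

    def test_identical_laps_give_zero_deltas(self):
        sa, sb, laps, lin = _pair_session([4.0] * 12, [4.0] * 12)
        rec = lap_fluctuations(self._record(), sa, sb, laps, lin)
        tab = rec.lap_table
        assert np.allclose(tab["drate_a"], 0.0, atol=1e-9)
        assert np.allclose(tab["dcom_a"], 0.0, atol=1e-9)

    def test_two_lap_mean_subtraction(self):
        sa, sb, laps, lin = _pair_session([4.0, 6.0], [5.0, 5.0])
        rec = lap_fluctuations(self._record(), sa, sb, laps, lin)
        assert np.allclose(rec.lap_table["drate_a"], [-1.0, 1.0])
        # below min_laps: correlations flagged missing
        assert math.isnan(rec.r_drate)

    def test_com_is_mean_spike_position(self):
        # spikes at 102, 104, 109 cm -> COM 105
        pos = list(np.arange(95.0, 115.0, 0.5))
        lin, laps = make_linearized([pos], dt=0.1)
        rec = self._record()
        t = {p: (p - 95.0) / 0.5 * 0.1 for p in (102.0, 104.0, 109.0)}
        sa = np.sort(list(t.values()))
        rec = lap_fluctuations(rec, sa, sa, laps, lin)
        assert rec.lap_table["com_a"].iloc[0] == pytest.approx(105.0, abs=1e-9)

    def test_zero_spike_lap_rate_zero_com_dropped(self):
        rates = [4.0, 0.0] + [4.0] * 10
        sa, sb, laps, lin = _pair_session(rates, [4.0] * 12)
        rec = lap_fluctuations(self._record(), sa, sb, laps, lin)
        tab = rec.lap_table
        assert tab["rate_a"].iloc[1] == 0.0
        assert math.isnan(tab["com_a"].iloc[1])

    def test_delta_series_sum_to_zero(self):
        rng = np.random.default_rng(2)
        rates = list(rng.uniform(2, 8, 15))
        sa, sb, laps, lin = _pair_session(rates, rates[::-1])
        rec = lap_fluctuations(self._record(), sa, sb, laps, lin)
        for col in ("drate_a", "drate_b", "dcom_a", "dcom_b"):
            s = rec.lap_table[col].to_numpy()
            assert np.nansum(s) == pytest.approx(0.0, abs=1e-9)


class TestPairCorrelation:
    def test_perfect_and_anti_correlation(self):
        d = np.arange(12, dtype=float) - 5.5
        assert pair_correlation(d, d)[0] == pytest.approx(1.0)
        assert pair_correlation(d, -d)[0] == pytest.approx(-1.0)

    def test_min_laps_enforced(self):
        d = np.arange(8, dtype=float)
        r, p = pair_correlation(d, d, min_laps=10)
        assert math.isnan(r) and math.isnan(p)

    def test_constant_series_flagged(self):
        d = np.arange(12, dtype=float)
        r, _ = pair_correlation(d, np.zeros(12))
        assert math.isnan(r)


class TestRegressOutBehavior:
    def test_pure_speed_modulation_removed(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(20, 50, 30)
        d = rng.normal(0, 10, 30)
        delta = 0.5 * v
        resid = regress_out_behavior(delta, v, d)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_residual_orthogonal_to_covariates(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(20, 50, 40)
        d = rng.normal(0, 10, 40)
        delta = 0.3 * v - 0.2 * d + rng.normal(0, 1, 40)
        resid = regress_out_behavior(delta, v, d)
        assert abs(np.corrcoef(resid, v)[0, 1]) < 1e-10
        assert abs(np.corrcoef(resid, d)[0, 1]) < 1e-10

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(5)
        n, sigma = 400, 0.5
        v = rng.uniform(20, 50, n)
        d = rng.normal(0, 10, n)
        delta = 0.3 * v - 0.2 * d + rng.normal(0, sigma, n)
        resid = regress_out_behavior(delta, v, d)
        design = np.column_stack([v, d, np.ones(n)])
        coef, *_ = np.linalg.lstsq(design, delta, rcond=None)
        se_alpha = sigma / (np.std(v) * np.sqrt(n))
        se_beta = sigma / (np.std(d) * np.sqrt(n))
        assert coef[0] == pytest.approx(0.3, abs=3 * se_alpha)
        assert coef[1] == pytest.approx(-0.2, abs=3 * se_beta)
        assert np.var(resid) < np.var(delta - delta.mean())

    def test_noise_unchanged_when_uncoupled(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(20, 50, 200)
        d = rng.normal(0, 10, 200)
        delta = rng.normal(0, 1, 200)
        resid = regress_out_behavior(delta, v, d)
        assert np.corrcoef(resid, delta - delta.mean())[0, 1] > 0.98


class TestComShiftCurve:
    def test_stationary_fields_flat(self):
        rng = np.random.default_rng(7)
        cells = [120.0 + rng.normal(0, 0.3, 30) for _ in range(50)]
        res = com_shift_curve(cells)
        assert res.n_cells == 50
        assert abs(res.slope_cm_per_lap) < 0.05
        assert np.allclose(res.mean_change_cm, 0.0, atol=0.5)

    def test_injected_backward_drift_recovered(self):
        rng = np.random.default_rng(8)
        cells = []
        for _ in range(100):
            laps = np.arange(30)
            com = 150.0 - 0.5 * laps + rng.normal(0, 1.0, 30)
            cells.append(com)
        res = com_shift_curve(cells)
        assert res.slope_cm_per_lap == pytest.approx(-0.5, abs=0.1)
        assert res.slope_p < 0.01

    def test_short_cells_excluded(self):
        rng = np.random.default_rng(9)
        long = [np.full(30, 100.0) + rng.normal(0, 0.1, 30) for _ in range(5)]
        short = [np.full(20, 100.0) for _ in range(5)]
        res = com_shift_curve(long + short)
        assert res.n_cells == 5

    def test_no_qualifying_cells_warns(self):
        with pytest.warns(UserWarning):
            assert com_shift_curve([np.full(10, 1.0)]) is None


class TestCircularHelpers:
    def test_wrap_range(self):
        assert wrap_deg(190.0) == pytest.approx(-170.0)
        assert wrap_deg(-190.0) == pytest.approx(170.0)
        assert wrap_deg(180.0) == pytest.approx(180.0)

    def test_circular_mean_across_wrap(self):
        assert circular_mean_deg([350.0, 10.0]) == pytest.approx(0.0, abs=1e-9)
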