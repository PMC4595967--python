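"""Lap-by-lap co-fluctuation ("noise correlation") of cell pairs.

For a pair of cells with spatially overlapping firing fields, each lap
yields a within-field firing rate and a spike center of mass (COM) per
cell.  The lap-wise deviations from their across-lap means (Δrate,
ΔCOM) are correlated between the two cells; a positive correlation
means the pair fluctuates together from lap to lap beyond what their
average tuning predicts.  Running speed and head direction through the
probed interval are measured per lap, and a multivariate linear
regression removes their modulation, giving modified Δ series whose
residual correlation cannot be explained by those behavioral
covariates.  Pairs are classified as overlapping, non-overlapping, or
non-responsive controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy import stats

from .fields import FiringField
from .spikexcorr import SpikeXcorr

__all__ = [
    "PairRecord",
    "classify_pair",
    "lap_fluctuations",
    "pair_correlation",
    "regress_out_behavior",
    "com_shift_curve",
    "ComShiftResult",
    "circular_mean_deg",
    "wrap_deg",
]

PAIR_CLASSES = ("overlapping", "non_overlapping", "non_responsive")


def wrap_deg(angle) -> np.ndarray | float:
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return float(w) if np.isscalar(angle) else w


def circular_mean_deg(angles_deg) -> float:
    """Circular mean of angles in degrees, in [0, 360); NaN if empty."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    mean = float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())) % 360.0)
    return 0.0 if mean >= 360.0 else mean


def overlap_fraction(a: FiringField, b: FiringField) -> float:
    """Spatial overlap as a fraction of the SHORTER field's length."""
    shorter = min(a.length_cm, b.length_cm)
    if shorter <= 0:
        return 0.0
    return a.overlap_cm(b) / shorter


@dataclass
class PairRecord:
    cell_a: str
    cell_b: str
    trajectory: int
    pair_class: str            # overlapping | non_overlapping | non_responsive
    interval_a: tuple[float, float]
    interval_b: tuple[float, float]
    overlap_frac: float
    lap_table: pd.DataFrame | None = None
    n_laps: int = 0
    r_drate: float = math.nan
    p_drate: float = math.nan
    r_dcom: float = math.nan
    p_dcom: float = math.nan
    r_drate_mod: float = math.nan
    p_drate_mod: float = math.nan
    r_dcom_mod: float = math.nan
    p_dcom_mod: float = math.nan
    notes: str = ""


def classify_pair(
    fields_a: list[FiringField],
    fields_b: list[FiringField],
    responsive_a: bool,
    responsive_b: bool,
    xcorr: SpikeXcorr | None,
    rng: np.random.Generator,
    overlap_min_frac: float = 0.5,
    xcorr_peak_threshold: float = 8.0,
    xcorr_window_s: float = 0.2,
) -> PairRecord | None:
    """Classify a cell pair and choose the probed spatial intervals.

    overlapping: some field pair overlaps by at least ``overlap_min_frac``
    of the shorter field AND the pair's spike cross-correlogram has a
    peak >= threshold within the time window (this excludes pairs firing
    mostly outside the shared interval).  The probed fields are the
    overlapped pair with the maximum sum of peak rates.

    non_overlapping: both cells have fields but none overlap enough;
    each cell is probed in its dominant field.

    non_responsive: one cell responsive with fields, the other not; the
    responsive cell's dominant field is probed, and the unresponsive
    cell gets a copy of it shifted by a random distance giving an
    overlap uniform in [overlap_min_frac, 1].

    Returns None for pairs that fit no class (e.g. overlapping fields
    but a sub-threshold correlogram, or neither cell responsive).
    """
    has_a = responsive_a and len(fields_a) > 0
    has_b = responsive_b and len(fields_b) > 0
    traj = (fields_a or fields_b)[0].trajectory if (fields_a or fields_b) else 0
    ca = fields_a[0].cell_id if fields_a else ""
    cb = fields_b[0].cell_id if fields_b else ""

    if has_a and has_b:
        candidates = [
            (fa, fb, overlap_fraction(fa, fb))
            for fa in fields_a
            for fb in fields_b
            if overlap_fraction(fa, fb) >= overlap_min_frac
        ]
        if candidates:
            xcorr_ok = (
                xcorr is not None
                and xcorr.peak_value >= xcorr_peak_threshold
                and abs(xcorr.peak_time_s) <= xcorr_window_s
            )
            if not xcorr_ok:
                return None
            fa, fb, frac = max(
                candidates, key=lambda c: c[0].peak_rate_hz + c[1].peak_rate_hz
            )
            return PairRecord(
                ca, cb, traj, "overlapping",
                (fa.start_cm, fa.end_cm), (fb.start_cm, fb.end_cm), frac,
            )
        fa = _dominant(fields_a)
        fb = _dominant(fields_b)
        return PairRecord(
            ca, cb, traj, "non_overlapping",
            (fa.start_cm, fa.end_cm), (fb.start_cm, fb.end_cm),
            overlap_fraction(fa, fb),
        )
    if has_a != has_b:
        resp_fields = fields_a if has_a else fields_b
        f = _dominant(resp_fields)
        frac = float(rng.uniform(overlap_min_frac, 1.0))
        shift = (1.0 - frac) * f.length_cm * (1 if rng.random() < 0.5 else -1)
        probe = (f.start_cm + shift, f.end_cm + shift)
        ia, ib = ((f.start_cm, f.end_cm), probe) if has_a else (probe, (f.start_cm, f.end_cm))
        return PairRecord(ca, cb, f.trajectory, "non_responsive", ia, ib, frac)
    return None


def _dominant(fields: list[FiringField]) -> FiringField:
    return max(fields, key=lambda f: f.peak_rate_hz)


def _per_lap_stats(
    spike_times: np.ndarray,
    interval: tuple[float, float],
    lap_index: np.ndarray,
    lin: dict,
) -> pd.DataFrame:
    """Per-lap within-interval rate, COM, mean speed, head direction."""
    a, b = interval
    t = lin["t"]
    pos = lin["pos"]
    st = np.asarray(spike_times, dtype=float)
    idx = np.searchsorted(t, st, side="right") - 1
    ok = (idx >= 0) & (idx < len(t) - 1)
    ok &= lin["use"][np.clip(idx, 0, len(t) - 1)]
    st, idx = st[ok], idx[ok]
    spos = np.interp(st, t, pos)
    in_int = (spos >= a) & (spos < b)
    st, idx, spos = st[in_int], idx[in_int], spos[in_int]
    spike_lap = lin["lap"][idx]

    rows = []
    for li in lap_index:
        m = lin["use"] & (lin["lap"] == li) & (pos >= a) & (pos < b)
        t_in = float(lin["dt"][m].sum())
        sp = spos[spike_lap == li]
        rows.append(
            {
                "lap_index": int(li),
                "time_s": t_in,
                "n_spikes": int(sp.size),
                "rate": sp.size / t_in if t_in > 0 else np.nan,
                "com": float(sp.mean()) if sp.size else np.nan,
                "speed": float(lin["speed"][m].mean()) if m.any() else np.nan,
                "hdir": circular_mean_deg(lin["hd"][m]) if m.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def lap_fluctuations(
    pair: PairRecord,
    spike_times_a: np.ndarray,
    spike_times_b: np.ndarray,
    laps: pd.DataFrame,
    linearized: pd.DataFrame,
    min_laps: int = 10,
) -> PairRecord:
    """Fill the pair's lap table with rates, COMs, covariates and the Δ
    series, then compute the raw and behavior-corrected correlations.

    Laps with zero in-interval spikes enter Δrate as rate 0 but are
    dropped pairwise for the COM correlation (COM undefined without
    spikes).  Pairs with fewer than ``min_laps`` usable laps get NaN
    correlations.
    """
    traj = pair.trajectory
    lap_index = laps.loc[laps["trajectory"] == traj, "lap_index"].to_numpy(dtype=int)
    lin = {
        "t": linearized["t_s"].to_numpy(dtype=float),
        "pos": linearized["pos_cm"].to_numpy(dtype=float),
        "speed": linearized["speed_cms"].to_numpy(dtype=float),
        "hd": linearized["hd_deg"].to_numpy(dtype=float),
        "lap": linearized["lap"].to_numpy(),
        "use": (
            linearized["running"].to_numpy(dtype=bool)
            & (linearized["trajectory"].to_numpy() == traj)
        ),
    }
    dt = np.empty_like(lin["t"])
    dt[:-1] = np.diff(lin["t"])
    dt[-1] = dt[-2] if len(dt) > 1 else 0.0
    lin["dt"] = dt

    ta = _per_lap_stats(spike_times_a, pair.interval_a, lap_index, lin)
    tb = _per_lap_stats(spike_times_b, pair.interval_b, lap_index, lin)
    tab = pd.DataFrame({"lap_index": lap_index})
    for name, tt in (("a", ta), ("b", tb)):
        tab[f"rate_{name}"] = tt["rate"].to_numpy()
        tab[f"com_{name}"] = tt["com"].to_numpy()
        tab[f"speed_{name}"] = tt["speed"].to_numpy()
        tab[f"hdir_{name}"] = tt["hdir"].to_numpy()
    # zero-spike laps on occupied laps count as rate 0
    for name, tt in (("a", ta), ("b", tb)):
        occupied = tt["time_s"].to_numpy() > 0
        r = tab[f"rate_{name}"].to_numpy()
        tab[f"rate_{name}"] = np.where(occupied & ~np.isfinite(r), 0.0, r)

    for name in ("a", "b"):
        r = tab[f"rate_{name}"].to_numpy(dtype=float)
        c = tab[f"com_{name}"].to_numpy(dtype=float)
        tab[f"drate_{name}"] = r - np.nanmean(r) if np.isfinite(r).any() else np.nan
        tab[f"dcom_{name}"] = c - np.nanmean(c) if np.isfinite(c).any() else np.nan
        h = tab[f"hdir_{name}"].to_numpy(dtype=float)
        tab[f"dhdir_{name}"] = wrap_deg(h - circular_mean_deg(h[np.isfinite(h)]))

    pair.lap_table = tab
    pair.n_laps = int(np.isfinite(tab["rate_a"].to_numpy() * tab["rate_b"].to_numpy()).sum())
    pair.r_drate, pair.p_drate = pair_correlation(
        tab["drate_a"], tab["drate_b"], min_laps
    )
    pair.r_dcom, pair.p_dcom = pair_correlation(tab["dcom_a"], tab["dcom_b"], min_laps)

    mods = {}
    for name in ("a", "b"):
        for q in ("drate", "dcom"):
            mods[f"{q}_{name}_mod"] = regress_out_behavior(
                tab[f"{q}_{name}"].to_numpy(dtype=float),
                tab[f"speed_{name}"].to_numpy(dtype=float),
                tab[f"dhdir_{name}"].to_numpy(dtype=float),
            )
    for k, v in mods.items():
        tab[k] = v
    pair.r_drate_mod, pair.p_drate_mod = pair_correlation(
        tab["drate_a_mod"], tab["drate_b_mod"], min_laps
    )
    pair.r_dcom_mod, pair.p_dcom_mod = pair_correlation(
        tab["dcom_a_mod"], tab["dcom_b_mod"], min_laps
    )
    return pair


def pair_correlation(da, db, min_laps: int = 10) -> tuple[float, float]:
    """Pearson correlation between two lap-wise Δ series.

    NaN laps are dropped pairwise; requires ``min_laps`` paired laps and
    non-constant series, otherwise (NaN, NaN).
    """
    x = np.asarray(da, dtype=float)
    y = np.asarray(db, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if len(x) < min_laps or x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def regress_out_behavior(delta, speeds, dhdir) -> np.ndarray:
    """Residual of Δ after multivariate OLS on lap speed and Δhdir.

    Fits ``Δ = α V + β D + intercept + x'`` by least squares and returns
    the residual x', which by construction has zero correlation with V
    and D.  Rows with any non-finite value stay NaN.  Collinear
    covariates fall back to the pseudo-inverse with a warning.
    """
    d = np.asarray(delta, dtype=float)
    v = np.asarray(speeds, dtype=float)
    h = np.asarray(dhdir, dtype=float)
    out = np.full(len(d), np.nan)
    m = np.isfinite(d) & np.isfinite(v) & np.isfinite(h)
    if m.sum() < 3:
        return out
    design = np.column_stack([v[m], h[m], np.ones(m.sum())])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("collinear behavioral covariates; using pseudo-inverse")
    coef, *_ = np.linalg.lstsq(design, d[m], rcond=None)
    out[m] = d[m] - design @ coef
    return out


@dataclass
class ComShiftResult:
    lap_numbers: np.ndarray       # 1-based lap ordinals
    mean_change_cm: np.ndarray    # population mean COM change per lap
    n_cells: int
    slope_cm_per_lap: float       # fit over the early laps
    slope_p: float
    fit_laps: tuple[int, int]


def com_shift_curve(
    com_per_cell: list[np.ndarray],
    stabilize_laps: tuple[int, int] = (21, 25),
    fit_laps: tuple[int, int] = (1, 10),
) -> ComShiftResult | None:
    """Population COM drift relative to its stabilized value.

    Each input array holds one cell's per-lap COM (NaN where undefined)
    in lap order.  Cells with fewer laps than the stabilization window
    are excluded.  Per cell the COM change at lap l is COM_l minus the
    mean COM over ``stabilize_laps``; the population mean per lap is
    returned together with the least-squares slope (and its p-value)
    over ``fit_laps``.
    """
    lo, hi = stabilize_laps
    usable = []
    for com in com_per_cell:
        com = np.asarray(com, dtype=float)
        if len(com) < hi:
            continue
        ref = np.nanmean(com[lo - 1 : hi])
        if not np.isfinite(ref):
            continue
        usable.append(com - ref)
    if not usable:
        warnings.warn("no cells with enough laps for COM-shift analysis")
        return None
    max_laps = max(len(c) for c in usable)
    mat = np.full((len(usable), max_laps), np.nan)
    for i, c in enumerate(usable):
        mat[i, : len(c)] = c
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_change = np.nanmean(mat, axis=0)
    laps = np.arange(1, max_laps + 1)
    f0, f1 = fit_laps
    sel = (laps >= f0) & (laps <= f1) & np.isfinite(mean_change)
    if sel.sum() >= 3:
        fit = stats.linregress(laps[sel], mean_change[sel])
        slope, p = float(fit.slope), float(fit.pvalue)
    else:
        slope, p = float("nan"), float("nan")
    return ComShiftResult(laps, mean_change, len(usable), slope, p, fit_laps)
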