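"""End-to-end orchestration: behavior -> metrics -> fields -> pairs.

``run_pipeline`` executes every stage in dependency order on one
session, deterministically for a given (session, master_seed), and
returns a bundle of tidy tables plus grouped summaries (by region,
cortical layer, and recording-day group T1 = days 1-2, T2 = days 3-5,
T3 = days 6+).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior, cofluct, fields as fieldmod, ratemaps, shuffle, spikexcorr
from .config import RunConfig
from .geometry import TrackGeometry
from .session import Session

__all__ = ["PipelineResult", "ValidationError", "run_pipeline", "day_group"]

log = logging.getLogger("trackcell")


class ValidationError(ValueError):
    """Raised when a session fails schema validation; carries the item list."""

    def __init__(self, problems: list[str]):
        super().__init__("; ".join(problems))
        self.problems = problems


def day_group(day: int) -> str:
    """Recording-day group: T1 = days 1-2, T2 = days 3-5, T3 = days 6+."""
    if day <= 2:
        return "T1"
    if day <= 5:
        return "T2"
    return "T3"


@dataclass
class PipelineResult:
    laps: pd.DataFrame
    linearized: pd.DataFrame
    behavior_metrics: pd.DataFrame
    metrics: pd.DataFrame
    fields: pd.DataFrame
    bidir: pd.DataFrame
    xcorr_pairs: pd.DataFrame
    pairs: pd.DataFrame
    comshift: pd.DataFrame
    summary: dict
    rate_curves: dict = field(default_factory=dict)      # (cell_id, traj) -> RateCurve
    field_objects: dict = field(default_factory=dict)    # (cell_id, traj) -> [FiringField]


def _pair_rng(master_seed: int, cell_a: str, cell_b: str, trajectory: int):
    key = zlib.crc32(f"{cell_a}|{cell_b}".encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), key, int(trajectory), 7])
    )


def run_pipeline(
    session: Session,
    config: RunConfig | None = None,
    geometry: TrackGeometry | None = None,
) -> PipelineResult:
    """Run the full analysis on one session.

    ``geometry`` defaults to a straight track of the session's length;
    pass the real path for projected 2-D data.
    """
    config = config or RunConfig()
    problems = session.validate()
    clip_only = all("outside position time range" in p for p in problems)
    if problems and not clip_only:
        raise ValidationError(problems)
    if problems:
        session = session.clipped()
    geometry = geometry or TrackGeometry.straight(session.track_length_cm)

    # ---- behavior -----------------------------------------------------
    linearized, laps = behavior.linearize_and_segment(
        session.positions, geometry, config.well_margin_cm
    )
    linearized = behavior.compute_speed_and_mask(
        linearized,
        session.track_length_cm,
        config.well_margin_cm,
        config.speed_floor_cms,
        config.stop_min_s,
    )
    behavior_tbl = behavior.behavior_metrics(laps, linearized)
    trajectories = sorted(laps["trajectory"].unique())
    log.info("laps: %s", {t: int((laps["trajectory"] == t).sum()) for t in trajectories})

    builders = {
        traj: ratemaps.RateCurveBuilder(
            laps, linearized, traj, session.track_length_cm,
            config.bin_cm, config.smooth_sigma_bins,
        )
        for traj in trajectories
    }

    # ---- per-cell metrics ---------------------------------------------
    metric_rows = []
    curves: dict = {}
    eligible: dict = {}      # (cell, traj) -> True for active non-interneuron
    responsive: dict = {}
    for st in session.spikes:
        for traj, builder in builders.items():
            rate = builder.overall_rate_hz(st.times)
            active, interneuron = ratemaps.classify_active(
                rate, st.region, config.active_hz, config.interneuron_hz
            )
            row = {
                "cell_id": st.cell_id,
                "region": st.region,
                "layer": st.layer,
                "day": st.day,
                "day_group": day_group(st.day),
                "trajectory": traj,
                "overall_rate_hz": rate,
                "active": active,
                "putative_interneuron": interneuron,
                "sic_bits_per_spike": np.nan,
                "sir_bits_per_s": np.nan,
                "stability": np.nan,
                "smi": np.nan,
                "location_responsive": False,
            }
            ok = active and not interneuron
            eligible[(st.cell_id, traj)] = ok
            if ok:
                curve = builder.build(st.times)
                curves[(st.cell_id, traj)] = curve
                sic, sir = ratemaps.spatial_information(curve, config.sic_use_smoothed)
                row["sic_bits_per_spike"] = sic
                row["sir_bits_per_s"] = sir
                row["stability"] = ratemaps.spatial_stability(curve).stability
                res = shuffle.compute_smi(
                    st.times,
                    builder,
                    config.n_shuffles,
                    shuffle.cell_rng(config.master_seed, st.cell_id, traj),
                    config.smi_threshold,
                    st.cell_id,
                )
                row["smi"] = res.smi
                row["location_responsive"] = res.location_responsive
            responsive[(st.cell_id, traj)] = row["location_responsive"]
            metric_rows.append(row)
    metrics = pd.DataFrame(metric_rows)
    log.info(
        "cells: %d total, %d active cell x trajectories, %d responsive",
        len(session.spikes), int(metrics["active"].sum()),
        int(metrics["location_responsive"].sum()),
    )

    # ---- firing fields -------------------------------------------------
    # detection runs on trajectory-active CA1 cells and on
    # location-responsive trajectory-active V1 cells
    field_rows = []
    field_objects: dict = {}
    for st in session.spikes:
        for traj in trajectories:
            key = (st.cell_id, traj)
            if not eligible.get(key):
                continue
            if st.region == "V1" and not responsive[key]:
                continue
            flist = fieldmod.detect_fields(
                curves[key],
                st.cell_id,
                config.baseline_pct,
                config.field_peak_min_hz,
                config.field_peak_baseline_frac,
                config.field_boundary_frac,
                config.field_merge_gap_cm,
            )
            field_objects[key] = flist
            for f in flist:
                field_rows.append(
                    {
                        "cell_id": f.cell_id,
                        "region": st.region,
                        "trajectory": traj,
                        "start_cm": f.start_cm,
                        "end_cm": f.end_cm,
                        "peak_pos_cm": f.peak_pos_cm,
                        "peak_rate_hz": f.peak_rate_hz,
                        "length_cm": f.length_cm,
                        "dominant": f.dominant,
                    }
                )
    fields_tbl = pd.DataFrame(
        field_rows,
        columns=[
            "cell_id", "region", "trajectory", "start_cm", "end_cm",
            "peak_pos_cm", "peak_rate_hz", "length_cm", "dominant",
        ],
    )

    # field distributions and their V1-CA1 spatial cross-correlogram
    dist_xcorr = {}
    for traj in trajectories:
        per_region = {}
        for region in ("V1", "CA1"):
            sub = fields_tbl[
                (fields_tbl["trajectory"] == traj) & (fields_tbl["region"] == region)
            ]
            flist = [
                fieldmod.FiringField(r.cell_id, traj, r.start_cm, r.end_cm,
                                     r.peak_pos_cm, r.peak_rate_hz)
                for r in sub.itertuples()
            ]
            per_region[region] = fieldmod.field_distribution(
                flist, traj, region, session.track_length_cm,
                config.bin_cm, config.smooth_sigma_bins,
            )
        try:
            res = fieldmod.field_distribution_xcorr(
                per_region["V1"], per_region["CA1"], config.bidir_window_cm
            )
            dist_xcorr[traj] = {
                "peak_lag_cm": res.peak_lag_cm,
                "peak_corr": res.peak_corr,
                "peak_p": res.peak_p,
            }
        except ValueError:
            dist_xcorr[traj] = None

    # ---- bidirectional calls -------------------------------------------
    bidir_rows = []
    if set(trajectories) >= {1, 2}:
        for st in session.spikes:
            k1, k2 = (st.cell_id, 1), (st.cell_id, 2)
            if not (responsive.get(k1) and responsive.get(k2)):
                continue
            call = fieldmod.classify_bidirectional(
                curves[k1], curves[k2], st.cell_id, True, True,
                config.bidir_window_cm, config.bidir_alpha,
            )
            bidir_rows.append(
                {
                    "cell_id": st.cell_id,
                    "region": st.region,
                    "peak_lag_cm": call.peak_lag_cm,
                    "p": call.peak_p,
                    "class": call.call,
                }
            )
    bidir = pd.DataFrame(
        bidir_rows, columns=["cell_id", "region", "peak_lag_cm", "p", "class"]
    )

    # ---- temporal cross-correlograms (V1-CA1, running epochs) ----------
    run_mask = linearized["running"].to_numpy(dtype=bool)
    t_all = linearized["t_s"].to_numpy()
    dt = np.empty_like(t_all)
    dt[:-1] = np.diff(t_all)
    dt[-1] = dt[-2] if len(dt) > 1 else 0.0
    total_run_time = float(dt[run_mask].sum())

    def running_spikes(times):
        idx = np.searchsorted(t_all, times, side="right") - 1
        ok = (idx >= 0) & (idx < len(t_all) - 1)
        ok &= run_mask[np.clip(idx, 0, len(t_all) - 1)]
        return np.asarray(times)[ok]

    v1_cells = [s for s in session.spikes if s.region == "V1"]
    ca1_cells = [s for s in session.spikes if s.region == "CA1"]
    xcorr_rows = []
    xcorrs: dict = {}
    for va in v1_cells:
        for cb in ca1_cells:
            if not any(
                eligible.get((va.cell_id, t)) and eligible.get((cb.cell_id, t))
                for t in trajectories
            ):
                continue
            pa, qb = running_spikes(va.times), running_spikes(cb.times)
            if len(pa) == 0 or len(qb) == 0 or total_run_time <= 0:
                continue
            xc = spikexcorr.normalized_xcorr(
                pa, qb, total_run_time,
                config.xcorr_bin_ms, config.xcorr_max_lag_ms,
                config.xcorr_peak_window_ms, config.xcorr_sig_threshold,
                va.cell_id, cb.cell_id,
            )
            xcorrs[(va.cell_id, cb.cell_id)] = xc
            xcorr_rows.append(
                {
                    "cell_a": va.cell_id,
                    "cell_b": cb.cell_id,
                    "peak_value": xc.peak_value,
                    "peak_time_s": xc.peak_time_s,
                    "highly_significant": xc.highly_significant,
                }
            )
    xcorr_tbl = pd.DataFrame(
        xcorr_rows,
        columns=["cell_a", "cell_b", "peak_value", "peak_time_s", "highly_significant"],
    )
    if len(v1_cells) == 0 or len(ca1_cells) == 0:
        log.warning("no V1-CA1 pairs exist in this session")

    bias = None
    sig = xcorr_tbl[xcorr_tbl["highly_significant"]]
    if len(sig) and (sig["peak_time_s"] != 0).any():
        frac_pos, p = spikexcorr.peak_time_bias(sig["peak_time_s"].to_numpy())
        bias = {"n_pairs": int(len(sig)), "fraction_positive": frac_pos, "binomial_p": p}

    # ---- pair co-fluctuation -------------------------------------------
    pair_rows = []
    for va in v1_cells:
        for cb in ca1_cells:
            for traj in trajectories:
                ka, kb = (va.cell_id, traj), (cb.cell_id, traj)
                if not (eligible.get(ka) and eligible.get(kb)):
                    continue
                rec = cofluct.classify_pair(
                    field_objects.get(ka, []),
                    field_objects.get(kb, []),
                    responsive[ka],
                    responsive[kb],
                    xcorrs.get((va.cell_id, cb.cell_id)),
                    _pair_rng(config.master_seed, va.cell_id, cb.cell_id, traj),
                    config.overlap_min_frac,
                    config.xcorr_sig_threshold,
                    config.xcorr_peak_window_ms / 1000.0,
                )
                if rec is None:
                    continue
                rec.cell_a, rec.cell_b = va.cell_id, cb.cell_id
                rec.trajectory = traj
                cofluct.lap_fluctuations(
                    rec, va.times, cb.times, laps, linearized, config.min_laps
                )
                pair_rows.append(
                    {
                        "cell_a": rec.cell_a,
                        "cell_b": rec.cell_b,
                        "trajectory": traj,
                        "class": rec.pair_class,
                        "overlap_frac": rec.overlap_frac,
                        "n_laps": rec.n_laps,
                        "r_drate": rec.r_drate,
                        "p_drate": rec.p_drate,
                        "r_dcom": rec.r_dcom,
                        "p_dcom": rec.p_dcom,
                        "r_drate_mod": rec.r_drate_mod,
                        "r_dcom_mod": rec.r_dcom_mod,
                    }
                )
    pairs_tbl = pd.DataFrame(
        pair_rows,
        columns=[
            "cell_a", "cell_b", "trajectory", "class", "overlap_frac", "n_laps",
            "r_drate", "p_drate", "r_dcom", "p_dcom", "r_drate_mod", "r_dcom_mod",
        ],
    )

    # ---- COM backward-shift curve --------------------------------------
    com_series = []
    for (cell_id, traj), flist in field_objects.items():
        if not responsive.get((cell_id, traj)) or not flist:
            continue
        dom = max(flist, key=lambda f: f.peak_rate_hz)
        rec = cofluct.PairRecord(
            cell_id, cell_id, traj, "non_overlapping",
            (dom.start_cm, dom.end_cm), (dom.start_cm, dom.end_cm), 1.0,
        )
        st = session.get_cell(cell_id)
        cofluct.lap_fluctuations(rec, st.times, st.times, laps, linearized, config.min_laps)
        com_series.append(rec.lap_table["com_a"].to_numpy())
    shift = cofluct.com_shift_curve(com_series) if com_series else None
    if shift is not None:
        comshift = pd.DataFrame(
            {"lap": shift.lap_numbers, "mean_com_change_cm": shift.mean_change_cm}
        )
    else:
        comshift = pd.DataFrame(columns=["lap", "mean_com_change_cm"])

    # ---- summaries ------------------------------------------------------
    act = metrics[metrics["active"] & ~metrics["putative_interneuron"]]
    summary = {
        "config_hash": config.hash(),
        "master_seed": config.master_seed,
        "n_cells": len(session.spikes),
        "n_laps": {str(t): int((laps["trajectory"] == t).sum()) for t in trajectories},
        "field_distribution_xcorr": {str(k): v for k, v in dist_xcorr.items()},
        "peak_time_bias": bias,
        "com_shift": None
        if shift is None
        else {
            "n_cells": shift.n_cells,
            "slope_cm_per_lap": shift.slope_cm_per_lap,
            "slope_p": shift.slope_p,
        },
        "by_region": _grouped(act, "region"),
        "by_layer": _grouped(act[act["region"] == "V1"], "layer"),
        "by_day_group": _grouped(act, "day_group"),
        "pair_class_means": {
            cls: {
                "n": int((pairs_tbl["class"] == cls).sum()),
                "mean_r_drate": _nanmean(pairs_tbl.loc[pairs_tbl["class"] == cls, "r_drate"]),
                "mean_r_dcom": _nanmean(pairs_tbl.loc[pairs_tbl["class"] == cls, "r_dcom"]),
                "mean_r_drate_mod": _nanmean(
                    pairs_tbl.loc[pairs_tbl["class"] == cls, "r_drate_mod"]
                ),
            }
            for cls in cofluct.PAIR_CLASSES
        },
    }

    return PipelineResult(
        laps=laps,
        linearized=linearized,
        behavior_metrics=behavior_tbl,
        metrics=metrics,
        fields=fields_tbl,
        bidir=bidir,
        xcorr_pairs=xcorr_tbl,
        pairs=pairs_tbl,
        comshift=comshift,
        summary=summary,
        rate_curves=curves,
        field_objects=field_objects,
    )


def _nanmean(series) -> float | None:
    arr = np.asarray(series, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.mean()) if arr.size else None


def _grouped(metrics: pd.DataFrame, key: str) -> dict:
    out = {}
    for val, grp in metrics.groupby(key):
        out[str(val)] = {
            "n_cell_trajectories": int(len(grp)),
            "median_rate_hz": float(grp["overall_rate_hz"].median()),
            "median_sic": _nanmean_median(grp["sic_bits_per_spike"]),
            "median_smi": _nanmean_median(grp["smi"]),
            "pct_location_responsive": float(100.0 * grp["location_responsive"].mean()),
        }
    return out


def _nanmean_median(series) -> float | None:
    arr = np.asarray(series, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(np.median(arr)) if arr.size else None
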