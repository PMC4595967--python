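"""Reading and writing sessions and result bundles.

Sessions live either in three CSV files (positions.csv, spikes.csv,
cells.csv — coordinates cm, times seconds) or in a single HDF5
container with groups /positions, /spikes/<cell_id> and /cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .session import Session, SpikeTrain

__all__ = [
    "read_session_csv",
    "write_session_csv",
    "read_session_hdf5",
    "write_session_hdf5",
    "write_results",
]


def read_session_csv(
    positions_path, spikes_path, cells_path, track_length_cm: float = 300.0
) -> Session:
    positions = pd.read_csv(positions_path)
    spikes = pd.read_csv(spikes_path)
    cells = pd.read_csv(cells_path)
    trains = []
    by_cell = spikes.groupby("cell_id")["t_s"]
    for row in cells.itertuples():
        times = (
            by_cell.get_group(row.cell_id).to_numpy(dtype=float)
            if row.cell_id in by_cell.groups
            else np.empty(0)
        )
        trains.append(
            SpikeTrain(
                str(row.cell_id),
                row.region,
                np.sort(times),
                getattr(row, "layer", "unassigned"),
                int(getattr(row, "day", 1)),
            )
        )
    return Session(positions, trains, track_length_cm)


def write_session_csv(session: Session, outdir, truth=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    session.positions.to_csv(outdir / "positions.csv", index=False)
    spike_frames = [
        pd.DataFrame({"cell_id": st.cell_id, "t_s": st.times}) for st in session.spikes
    ]
    pd.concat(spike_frames, ignore_index=True).to_csv(outdir / "spikes.csv", index=False)
    pd.DataFrame(
        [
            {"cell_id": st.cell_id, "region": st.region, "layer": st.layer, "day": st.day}
            for st in session.spikes
        ]
    ).to_csv(outdir / "cells.csv", index=False)
    if truth is not None:
        payload = {
            "seed": truth.seed,
            "laps": truth.laps.to_dict(orient="records"),
            "fields": {
                cid: [vars(f) for f in fl] for cid, fl in truth.fields.items()
            },
            "gains": {cid: g.tolist() for cid, g in truth.gains.items()},
            "com_offsets": {cid: o.tolist() for cid, o in truth.com_offsets.items()},
            "speed_coefs": truth.speed_coefs,
            "hdir_coefs": truth.hdir_coefs,
        }
        (outdir / "truth.json").write_text(json.dumps(payload))


def read_session_hdf5(path, track_length_cm: float = 300.0) -> Session:
    with h5py.File(path, "r") as fh:
        pos = pd.DataFrame(
            {k: fh["positions"][k][:] for k in ("t_s", "x_cm", "y_cm", "hd_deg")}
        )
        cells = fh["cells"]
        trains = []
        for cid in cells["cell_id"].asstr()[:]:
            i = list(cells["cell_id"].asstr()[:]).index(cid)
            trains.append(
                SpikeTrain(
                    cid,
                    cells["region"].asstr()[i],
                    fh[f"spikes/{cid}"][:],
                    cells["layer"].asstr()[i],
                    int(cells["day"][i]),
                )
            )
    return Session(pos, trains, track_length_cm)


def write_session_hdf5(session: Session, path) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("positions")
        for k in ("t_s", "x_cm", "y_cm", "hd_deg"):
            g.create_dataset(k, data=session.positions[k].to_numpy())
        sg = fh.create_group("spikes")
        for st in session.spikes:
            sg.create_dataset(st.cell_id, data=st.times)
        cg = fh.create_group("cells")
        str_dt = h5py.string_dtype()
        cg.create_dataset(
            "cell_id", data=[st.cell_id for st in session.spikes], dtype=str_dt
        )
        cg.create_dataset(
            "region", data=[st.region for st in session.spikes], dtype=str_dt
        )
        cg.create_dataset(
            "layer", data=[st.layer for st in session.spikes], dtype=str_dt
        )
        cg.create_dataset("day", data=[st.day for st in session.spikes])


def write_results(result, config, outdir) -> None:
    """Write the pipeline result bundle as CSVs plus summary.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.laps.to_csv(outdir / "laps.csv", index=False)
    result.linearized.to_csv(outdir / "linearized.csv", index=False)
    result.metrics.to_csv(outdir / "metrics.csv", index=False)
    result.fields.to_csv(outdir / "fields.csv", index=False)
    result.bidir.to_csv(outdir / "bidir.csv", index=False)
    result.xcorr_pairs.to_csv(outdir / "xcorr_pairs.csv", index=False)
    result.pairs.to_csv(outdir / "pairs.csv", index=False)
    result.comshift.to_csv(outdir / "comshift.csv", index=False)
    summary = dict(result.summary)
    summary["config_hash"] = config.hash()
    summary["master_seed"] = config.master_seed
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=_json_safe))
    config.to_yaml(outdir / "config_used.yaml")


def _json_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
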