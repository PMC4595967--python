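"""Core containers: spike trains, recording sessions, and validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SpikeTrain", "Session", "REGIONS", "LAYERS"]

REGIONS = ("V1", "CA1")
LAYERS = ("L2/3", "L4", "L5/6", "unassigned")


@dataclass
class SpikeTrain:
    """Spike timestamps of one sorted unit with its metadata.

    times are seconds in the session clock, sorted ascending.
    """

    cell_id: str
    region: str
    times: np.ndarray
    layer: str = "unassigned"
    day: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.times.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if np.any(np.diff(self.times) < 0):
            self.times = np.sort(self.times)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class Session:
    """One recording session: position tracking plus a set of spike trains.

    positions: DataFrame with columns t_s, x_cm, y_cm, hd_deg, sampled at
    ~33 Hz with strictly increasing timestamps.
    """

    positions: pd.DataFrame
    spikes: Sequence[SpikeTrain]
    track_length_cm: float = 300.0
    metadata: dict = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Schema validation; returns an itemized list of problems (empty if OK)."""
        problems: list[str] = []
        required = {"t_s", "x_cm", "y_cm", "hd_deg"}
        missing = required - set(self.positions.columns)
        if missing:
            problems.append(f"positions missing columns: {sorted(missing)}")
            return problems
        t = self.positions["t_s"].to_numpy()
        if t.size < 2:
            problems.append("positions must contain at least 2 samples")
        elif np.any(np.diff(t) <= 0):
            problems.append("position timestamps must be strictly increasing")
        hd = self.positions["hd_deg"].to_numpy()
        if t.size and (np.nanmin(hd) < 0 or np.nanmax(hd) >= 360):
            problems.append("head direction must lie in [0, 360)")
        if self.track_length_cm <= 0:
            problems.append("track_length_cm must be positive")
        ids = [st.cell_id for st in self.spikes]
        if len(ids) != len(set(ids)):
            problems.append("duplicate cell_id in spike trains")
        if t.size:
            t0, t1 = t[0], t[-1]
            for st in self.spikes:
                if st.n_spikes and (st.times[0] < t0 or st.times[-1] > t1):
                    problems.append(
                        f"cell {st.cell_id}: spikes outside position time range "
                        "(clip before analysis)"
                    )
        return problems

    def clipped(self) -> "Session":
        """Copy with spike times clipped to the position time range."""
        t = self.positions["t_s"].to_numpy()
        t0, t1 = float(t[0]), float(t[-1])
        trains = [
            SpikeTrain(
                st.cell_id,
                st.region,
                st.times[(st.times >= t0) & (st.times <= t1)],
                st.layer,
                st.day,
            )
            for st in self.spikes
        ]
        return Session(self.positions, trains, self.track_length_cm, dict(self.metadata))

    def get_cell(self, cell_id: str) -> SpikeTrain:
        for st in self.spikes:
            if st.cell_id == cell_id:
                return st
        raise KeyError(cell_id)
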