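"""Occupancy-normalized firing rate curves and per-cell spatial metrics.

The rate curve of a cell on a trajectory is its firing rate in uniform
2-cm spatial bins, pooled over all laps and restricted to active-running
samples.  From the smoothed curve we compute the Skaggs spatial
information content (bits/spike)

    SIc = sum_i p_i (x_i / r) log2(x_i / r)

with occupancy probability ``p_i`` and mean rate ``r = sum_i p_i x_i``,
the spatial information rate ``SIr = SIc * r`` (bits/s), and the lap-pair
spatial stability (mean Pearson correlation between per-lap curves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RateCurve",
    "RateCurveBuilder",
    "StabilityResult",
    "gaussian_smooth",
    "compute_rate_curve",
    "spatial_information",
    "spatial_stability",
    "classify_active",
]


def gaussian_smooth(x: np.ndarray, sigma_bins: float, truncate: float = 4.0) -> np.ndarray:
    """Smooth with a Gaussian kernel truncated at ``±truncate*sigma``.

    The kernel is renormalized where it overhangs the array ends (no
    reflection or wrap-around: track ends are physical boundaries), so a
    constant input is returned unchanged.
    """
    if sigma_bins <= 0:
        return np.asarray(x, dtype=float).copy()
    radius = int(math.ceil(truncate * sigma_bins))
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma_bins) ** 2)
    x = np.asarray(x, dtype=float)
    # centred slice of the full convolution (mode="same" misbehaves when
    # the kernel outgrows the array)
    num = np.convolve(x, k, mode="full")[radius : radius + len(x)]
    den = np.convolve(np.ones_like(x), k, mode="full")[radius : radius + len(x)]
    return num / den


@dataclass
class RateCurve:
    """Binned firing rate along one trajectory, raw and smoothed."""

    trajectory: int
    bin_edges: np.ndarray          # (N+1,) cm in running coordinate
    occupancy_s: np.ndarray        # (N,) seconds per bin, all laps pooled
    rate_hz: np.ndarray            # (N,) raw rate, 0 where unoccupied
    smoothed_hz: np.ndarray        # (N,)
    per_lap_smoothed: np.ndarray   # (n_laps, N)
    per_lap_occupancy: np.ndarray  # (n_laps, N) seconds
    lap_indices: np.ndarray        # (n_laps,) lap_index of each row
    n_spikes: int                  # spikes contributing (running, in-lap)

    @property
    def n_bins(self) -> int:
        return len(self.occupancy_s)

    @property
    def occupancy_prob(self) -> np.ndarray:
        """p_i over occupied bins (0 where unoccupied); sums to 1."""
        p = np.where(self.occupancy_s > 0, self.occupancy_s, 0.0)
        tot = p.sum()
        return p / tot if tot > 0 else p

    @property
    def mean_rate_hz(self) -> float:
        """Occupancy-weighted mean of the smoothed curve, r = sum p_i x_i."""
        return float(np.sum(self.occupancy_prob * self.smoothed_hz))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


class RateCurveBuilder:
    """Precomputed occupancy and spike-assignment machinery for one
    (session, trajectory), reusable across spike trains and shuffles.

    Spikes are assigned to the tracking sample they fall on (the sample
    whose period contains the spike time); a spike contributes only if
    that sample is flagged running on this trajectory.  The spike's
    position is linearly interpolated between tracking samples, then
    binned into half-open bins ``[k*w, (k+1)*w)`` with the final bin
    closed.
    """

    def __init__(
        self,
        laps: pd.DataFrame,
        linearized: pd.DataFrame,
        trajectory: int,
        track_length_cm: float,
        bin_cm: float = 2.0,
        smooth_sigma_bins: float = 2.0,
    ) -> None:
        self.trajectory = int(trajectory)
        self.bin_cm = float(bin_cm)
        self.smooth_sigma_bins = float(smooth_sigma_bins)
        self.n_bins = int(math.ceil(track_length_cm / bin_cm))
        self.bin_edges = np.arange(self.n_bins + 1) * bin_cm

        t = linearized["t_s"].to_numpy(dtype=float)
        pos = linearized["pos_cm"].to_numpy(dtype=float)
        running = linearized["running"].to_numpy(dtype=bool)
        traj = linearized["trajectory"].to_numpy()
        lap = linearized["lap"].to_numpy()

        dt = np.empty_like(t)
        dt[:-1] = np.diff(t)
        dt[-1] = dt[-2] if len(t) > 1 else 0.0

        self._t_all = t
        self._pos_all = pos
        self._use = running & (traj == self.trajectory)

        sel = laps[laps["trajectory"] == self.trajectory]
        self.lap_indices = sel["lap_index"].to_numpy(dtype=int)
        self._lap_row = {int(li): r for r, li in enumerate(self.lap_indices)}
        self.lap_windows = sel[["t_start", "t_end"]].to_numpy(dtype=float)
        n_laps = len(self.lap_indices)
        if n_laps == 0:
            raise ValueError(f"no laps on trajectory {trajectory}")

        use_idx = np.flatnonzero(self._use)
        bins = np.minimum(
            (pos[use_idx] / bin_cm).astype(int), self.n_bins - 1
        )
        lap_rows = np.array([self._lap_row[int(l)] for l in lap[use_idx]], dtype=int)
        self.per_lap_occupancy = np.zeros((n_laps, self.n_bins))
        np.add.at(self.per_lap_occupancy, (lap_rows, bins), dt[use_idx])
        self.occupancy_s = self.per_lap_occupancy.sum(axis=0)
        if self.occupancy_s.sum() <= 0:
            raise ValueError("zero total occupancy on trajectory")
        self.total_running_time_s = float(self.occupancy_s.sum())
        self._lap_of_sample = lap

    # -- spike handling -------------------------------------------------
    def assign_spikes(self, spike_times: np.ndarray):
        """Return (bin index, lap row) of each included spike."""
        st = np.asarray(spike_times, dtype=float)
        idx = np.searchsorted(self._t_all, st, side="right") - 1
        ok = (idx >= 0) & (idx < len(self._t_all) - 1)
        ok &= self._use[np.clip(idx, 0, len(self._t_all) - 1)]
        st, idx = st[ok], idx[ok]
        pos = np.interp(st, self._t_all, self._pos_all)
        bins = np.minimum((pos / self.bin_cm).astype(int), self.n_bins - 1)
        lap_rows = np.array(
            [self._lap_row[int(l)] for l in self._lap_of_sample[idx]], dtype=int
        )
        return bins, lap_rows, pos

    def build(self, spike_times: np.ndarray) -> RateCurve:
        """Full rate curve (pooled + per-lap) for one spike train."""
        bins, lap_rows, _ = self.assign_spikes(spike_times)
        n_laps = len(self.lap_indices)
        counts = np.zeros((n_laps, self.n_bins))
        np.add.at(counts, (lap_rows, bins), 1.0)
        total_counts = counts.sum(axis=0)
        occ = self.occupancy_s
        rate = np.divide(total_counts, occ, out=np.zeros_like(occ), where=occ > 0)
        per_lap_rate = np.divide(
            counts,
            self.per_lap_occupancy,
            out=np.zeros_like(counts),
            where=self.per_lap_occupancy > 0,
        )
        smoothed = gaussian_smooth(rate, self.smooth_sigma_bins)
        per_lap_smoothed = np.apply_along_axis(
            gaussian_smooth, 1, per_lap_rate, self.smooth_sigma_bins
        ) if n_laps else per_lap_rate
        return RateCurve(
            trajectory=self.trajectory,
            bin_edges=self.bin_edges,
            occupancy_s=occ,
            rate_hz=rate,
            smoothed_hz=smoothed,
            per_lap_smoothed=per_lap_smoothed,
            per_lap_occupancy=self.per_lap_occupancy,
            lap_indices=self.lap_indices,
            n_spikes=int(len(bins)),
        )

    def smoothed_curve(self, spike_times: np.ndarray) -> np.ndarray:
        """Pooled smoothed curve only — the fast path for shuffles."""
        bins, _, _ = self.assign_spikes(spike_times)
        total_counts = np.bincount(bins, minlength=self.n_bins).astype(float)
        occ = self.occupancy_s
        rate = np.divide(total_counts, occ, out=np.zeros_like(occ), where=occ > 0)
        return gaussian_smooth(rate, self.smooth_sigma_bins)

    def information(self, spike_times: np.ndarray) -> tuple[float, float]:
        """(SIc, SIr) of one spike train on this trajectory.

        The SIr multiplier is the raw mean rate (included spikes over
        occupied time), invariant under circular shuffling.
        """
        bins, _, _ = self.assign_spikes(spike_times)
        total_counts = np.bincount(bins, minlength=self.n_bins).astype(float)
        occ = self.occupancy_s
        rate = np.divide(total_counts, occ, out=np.zeros_like(occ), where=occ > 0)
        x = gaussian_smooth(rate, self.smooth_sigma_bins)
        sic = _sic_from_curve(x, occ)
        r = float(total_counts.sum() / self.total_running_time_s)
        return sic, sic * r

    def sic(self, spike_times: np.ndarray) -> float:
        """Spatial information content of one spike train (bits/spike)."""
        return self.information(spike_times)[0]

    def overall_rate_hz(self, spike_times: np.ndarray) -> float:
        """Mean rate over running epochs of this trajectory."""
        bins, _, _ = self.assign_spikes(spike_times)
        return len(bins) / self.total_running_time_s


def compute_rate_curve(
    spike_times: np.ndarray,
    laps: pd.DataFrame,
    linearized: pd.DataFrame,
    trajectory: int,
    track_length_cm: float,
    bin_cm: float = 2.0,
    smooth_sigma_bins: float = 2.0,
) -> RateCurve:
    """One-shot convenience wrapper around :class:`RateCurveBuilder`."""
    builder = RateCurveBuilder(
        laps, linearized, trajectory, track_length_cm, bin_cm, smooth_sigma_bins
    )
    return builder.build(spike_times)


def _sic_from_curve(
    x: np.ndarray, occupancy: np.ndarray, r: float | None = None
) -> float:
    occ = np.where(occupancy > 0, occupancy, 0.0)
    tot = occ.sum()
    if tot <= 0:
        return float("nan")
    p = occ / tot
    if r is None:
        r = float(np.sum(p * x))
    if r <= 0:
        return float("nan")
    mask = (p > 0) & (x > 0)
    ratio = x[mask] / r
    return float(np.sum(p[mask] * ratio * np.log2(ratio)))


def spatial_information(curve: RateCurve, use_smoothed: bool = True) -> tuple[float, float]:
    """(SIc bits/spike, SIr bits/s) of a rate curve.

    Inside the sum, r is the occupancy-weighted mean of the curve the
    x_i come from (keeping SIc >= 0 by Jensen's inequality); the rate
    multiplier in SIr = SIc * r is the cell's true mean firing rate
    (spike count over occupied time, i.e. the raw-curve mean), which
    smoothing does not perturb.  Bins with zero rate contribute zero
    (the x log x -> 0 limit); bins with zero occupancy are excluded
    from the occupancy probability.  Returns (nan, nan) for a silent
    cell (r = 0).
    """
    x = curve.smoothed_hz if use_smoothed else curve.rate_hz
    sic = _sic_from_curve(x, curve.occupancy_s)
    if math.isnan(sic):
        return float("nan"), float("nan")
    r = float(np.sum(curve.occupancy_prob * curve.rate_hz))
    return sic, sic * r


@dataclass
class StabilityResult:
    stability: float          # mean lap-pair Pearson correlation
    n_pairs_used: int
    n_pairs_skipped: int      # zero-variance or <2 shared occupied bins


def spatial_stability(curve: RateCurve) -> StabilityResult:
    """Mean Pearson correlation between all unordered pairs of per-lap
    smoothed curves, over bins occupied in both laps of a pair.

    Pairs where either lap has zero rate variance (or fewer than two
    shared occupied bins) are skipped and counted.
    """
    n_laps = curve.per_lap_smoothed.shape[0]
    if n_laps < 2:
        return StabilityResult(float("nan"), 0, 0)
    used = skipped = 0
    acc = 0.0
    occ = curve.per_lap_occupancy > 0
    for i in range(n_laps):
        xi = curve.per_lap_smoothed[i]
        for j in range(i + 1, n_laps):
            m = occ[i] & occ[j]
            if m.sum() < 2:
                skipped += 1
                continue
            a, b = xi[m], curve.per_lap_smoothed[j][m]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                skipped += 1
                continue
            acc += float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
            used += 1
    if used == 0:
        return StabilityResult(float("nan"), 0, skipped)
    return StabilityResult(acc / used, used, skipped)


def classify_active(
    overall_rate_hz: float,
    region: str,
    active_hz: float = 0.5,
    interneuron_hz: float = 5.0,
) -> tuple[bool, bool]:
    """(active, putative_interneuron) flags for a cell on a trajectory.

    A cell is trajectory-active above ``active_hz``.  CA1 cells above
    ``interneuron_hz`` are flagged putative interneurons and excluded
    downstream; high-rate V1 cells are retained.
    """
    active = overall_rate_hz > active_hz
    interneuron = region == "CA1" and overall_rate_hz > interneuron_hz
    return active, interneuron
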