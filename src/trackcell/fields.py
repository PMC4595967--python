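"""Firing-field detection, field distributions, and spatial cross-correlograms.

A firing field generalizes the hippocampal place field to V1 cells: a
contiguous stretch of track where the baseline-subtracted smoothed rate
curve stays above 10% of a qualifying peak.  Field peaks accumulated
over a population give a field-distribution curve per region; the
sliding Pearson correlation between the V1 and CA1 curves measures
whether one population's fields lead the other's along the track.  The
same sliding correlation applied to one cell's rate curves on the two
opposite running directions classifies the cell as prospective or
retrospective relative to shared landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .ratemaps import RateCurve, gaussian_smooth

__all__ = [
    "FiringField",
    "FieldDistribution",
    "XcorrResult",
    "BidirectionalCall",
    "detect_fields",
    "field_distribution",
    "sliding_pearson",
    "field_distribution_xcorr",
    "classify_bidirectional",
]


@dataclass
class FiringField:
    """A detected field on one trajectory, in running-direction cm."""

    cell_id: str
    trajectory: int
    start_cm: float     # half-open interval [start, end)
    end_cm: float
    peak_pos_cm: float
    peak_rate_hz: float  # baseline-subtracted peak height
    dominant: bool = False

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    def overlap_cm(self, other: "FiringField") -> float:
        return max(0.0, min(self.end_cm, other.end_cm) - max(self.start_cm, other.start_cm))


def detect_fields(
    curve: RateCurve,
    cell_id: str = "",
    baseline_pct: float = 30.0,
    peak_min_hz: float = 1.0,
    peak_baseline_frac: float = 0.2,
    boundary_frac: float = 0.1,
    merge_gap_cm: float = 4.0,
) -> list[FiringField]:
    """Detect firing fields on a smoothed rate curve.

    The baseline is the ``baseline_pct``-th percentile of the smoothed
    curve; it is subtracted (negatives clipped to 0).  Local maxima of
    the remainder taller than both ``peak_min_hz`` and
    ``peak_baseline_frac`` x baseline become fields; boundaries extend
    outward to the first bin at or below ``boundary_frac`` of the
    subtracted peak.  Fields separated by less than ``merge_gap_cm`` are
    merged (interval union, keeping the larger peak), repeated to a
    fixpoint.
    """
    x = curve.smoothed_hz
    baseline = float(np.percentile(x, baseline_pct))
    sub = np.clip(x - baseline, 0.0, None)
    if not np.any(sub > 0):
        return []
    n = len(sub)
    peaks = list(signal.find_peaks(sub)[0])
    # track ends can host genuine peaks (or edge plateaus) that
    # find_peaks excludes; sub-threshold ones are filtered below
    if n >= 2 and sub[0] >= sub[1]:
        peaks.insert(0, 0)
    if n >= 2 and sub[-1] >= sub[-2]:
        peaks.append(n - 1)
    min_height = max(peak_min_hz, peak_baseline_frac * baseline)
    edges = curve.bin_edges
    centers = curve.bin_centers

    raw_fields: list[FiringField] = []
    for p in peaks:
        h = sub[p]
        if h <= min_height:
            continue
        thr = boundary_frac * h
        i0 = p
        while i0 > 0 and sub[i0 - 1] > thr:
            i0 -= 1
        i1 = p
        while i1 < n - 1 and sub[i1 + 1] > thr:
            i1 += 1
        raw_fields.append(
            FiringField(
                cell_id=cell_id,
                trajectory=curve.trajectory,
                start_cm=float(edges[i0]),
                end_cm=float(edges[i1 + 1]),
                peak_pos_cm=float(centers[p]),
                peak_rate_hz=float(h),
            )
        )
    merged = _merge_fields(raw_fields, merge_gap_cm)
    if merged:
        best = max(range(len(merged)), key=lambda i: merged[i].peak_rate_hz)
        merged[best].dominant = True
    return merged


def _merge_fields(fields: list[FiringField], merge_gap_cm: float) -> list[FiringField]:
    """Left-to-right interval union of fields closer than the gap."""
    if not fields:
        return []
    fields = sorted(fields, key=lambda f: f.start_cm)
    out = [fields[0]]
    for f in fields[1:]:
        cur = out[-1]
        if f.start_cm - cur.end_cm < merge_gap_cm:
            keep, other = (cur, f) if cur.peak_rate_hz >= f.peak_rate_hz else (f, cur)
            out[-1] = FiringField(
                cell_id=keep.cell_id,
                trajectory=keep.trajectory,
                start_cm=min(cur.start_cm, f.start_cm),
                end_cm=max(cur.end_cm, f.end_cm),
                peak_pos_cm=keep.peak_pos_cm,
                peak_rate_hz=keep.peak_rate_hz,
            )
        else:
            out.append(f)
    return out


@dataclass
class FieldDistribution:
    """Histogram of field-peak positions per 2-cm bin for one region."""

    trajectory: int
    region: str
    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        tot = self.counts.sum()
        self.normalized = self.smoothed / tot if tot > 0 else self.smoothed.copy()


def field_distribution(
    fields: list[FiringField],
    trajectory: int,
    region: str,
    track_length_cm: float,
    bin_cm: float = 2.0,
    smooth_sigma_bins: float = 2.0,
) -> FieldDistribution:
    """Count field peaks per spatial bin and smooth the histogram."""
    n_bins = int(np.ceil(track_length_cm / bin_cm))
    edges = np.arange(n_bins + 1) * bin_cm
    peaks = [f.peak_pos_cm for f in fields if f.trajectory == trajectory]
    counts, _ = np.histogram(peaks, bins=edges)
    counts = counts.astype(float)
    return FieldDistribution(
        trajectory=trajectory,
        region=region,
        bin_edges=edges,
        counts=counts,
        smoothed=gaussian_smooth(counts, smooth_sigma_bins),
    )


@dataclass
class XcorrResult:
    lags_cm: np.ndarray
    corr: np.ndarray         # Pearson r at each lag (NaN where undefined)
    peak_lag_cm: float
    peak_corr: float
    peak_p: float


def sliding_pearson(
    a: np.ndarray, b: np.ndarray, max_lag_bins: int, min_overlap: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of ``a[i]`` with ``b[i + lag]`` for integer
    lags in ``[-max_lag_bins, max_lag_bins]``, over the overlapping
    support only.  Lags with fewer than ``min_overlap`` points or zero
    variance yield NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b):
        raise ValueError("curves must share binning")
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    out = np.full(len(lags), np.nan)
    n = len(a)
    for i, k in enumerate(lags):
        if k >= 0:
            sa, sb = a[: n - k], b[k:]
        else:
            sa, sb = a[-k:], b[: n + k]
        if len(sa) < min_overlap or sa.std() == 0 or sb.std() == 0:
            continue
        out[i] = float(np.corrcoef(sa, sb)[0, 1])
    return lags, out


def _xcorr_with_peak(
    a: np.ndarray, b: np.ndarray, max_lag_bins: int, bin_cm: float
) -> XcorrResult:
    lags, corr = sliding_pearson(a, b, max_lag_bins)
    if np.all(np.isnan(corr)):
        raise ValueError("cross-correlogram undefined (zero-variance curve)")
    best = int(np.nanargmax(corr))
    k = int(lags[best])
    n = len(a)
    if k >= 0:
        sa, sb = a[: n - k], b[k:]
    else:
        sa, sb = a[-k:], b[: n + k]
    p = float(stats.pearsonr(sa, sb).pvalue)
    return XcorrResult(
        lags_cm=lags * bin_cm,
        corr=corr,
        peak_lag_cm=float(k * bin_cm),
        peak_corr=float(corr[best]),
        peak_p=p,
    )


def field_distribution_xcorr(
    dist_a: FieldDistribution,
    dist_b: FieldDistribution,
    max_lag_cm: float = 50.0,
) -> XcorrResult:
    """Spatial cross-correlogram between two smoothed field-distribution
    curves.  A positive peak lag means curve ``b``'s features sit at
    larger positions than curve ``a``'s, i.e. ``a`` leads along the
    running direction.
    """
    if not np.array_equal(dist_a.bin_edges, dist_b.bin_edges):
        raise ValueError("distributions must share binning")
    bin_cm = float(dist_a.bin_edges[1] - dist_a.bin_edges[0])
    max_lag_bins = int(round(max_lag_cm / bin_cm))
    return _xcorr_with_peak(dist_a.smoothed, dist_b.smoothed, max_lag_bins, bin_cm)


@dataclass
class BidirectionalCall:
    cell_id: str
    peak_lag_cm: float
    peak_p: float
    call: str   # prospective | retrospective | none
    reason: str = ""


def classify_bidirectional(
    curve_traj1: RateCurve,
    curve_traj2: RateCurve,
    cell_id: str = "",
    responsive_traj1: bool = True,
    responsive_traj2: bool = True,
    window_cm: float = 50.0,
    alpha: float = 0.00098,
) -> BidirectionalCall:
    """Prospective/retrospective call for a cell responsive on both
    running directions.

    The trajectory-2 curve is flipped into trajectory-1's physical
    coordinate and cross-correlated over lags within ``±window_cm``
    (2-cm steps, 51 lags at the default).  After flipping, a cell that
    fires a distance d before a shared landmark on both directions
    produces a peak at +2d, so a significant positive peak lag means
    prospective firing and a negative one retrospective; ``alpha`` is
    the per-lag Bonferroni level.
    """
    if not (responsive_traj1 and responsive_traj2):
        return BidirectionalCall(cell_id, float("nan"), float("nan"), "none",
                                 "not location-responsive on both trajectories")
    bin_cm = float(curve_traj1.bin_edges[1] - curve_traj1.bin_edges[0])
    flipped = curve_traj2.smoothed_hz[::-1]
    res = _xcorr_with_peak(
        curve_traj1.smoothed_hz, flipped, int(round(window_cm / bin_cm)), bin_cm
    )
    if res.peak_p >= alpha:
        return BidirectionalCall(cell_id, res.peak_lag_cm, res.peak_p, "none",
                                 "no significant peak within window")
    if res.peak_lag_cm > 0:
        call = "prospective"
    elif res.peak_lag_cm < 0:
        call = "retrospective"
    else:
        call = "none"
    return BidirectionalCall(cell_id, res.peak_lag_cm, res.peak_p, call)
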