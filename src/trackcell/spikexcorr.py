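"""Poisson-normalized spike-count cross-correlograms between cell pairs.

For spike trains P (M spikes) and Q (N spikes) observed over a total
time T, the raw cross-correlation at lag dT counts, over all spikes of
P, the Q spikes falling within a window of width B centred at P_i + dT.
Under independent homogeneous Poisson firing the expected count is
m = M * N * B / T, and the normalized correlogram

    C~(dT) = (C(dT) - m) / sqrt(m)

is approximately a z-score, insensitive to the cells' firing rates.  A
pair is called highly significantly correlated when the peak of C~
within the search window exceeds a threshold (default 8, roughly
p < 1e-4 by z-test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SpikeXcorr", "normalized_xcorr", "peak_time_bias"]


@dataclass
class SpikeXcorr:
    cell_a: str
    cell_b: str
    lags_s: np.ndarray        # symmetric about 0, step = bin width
    values: np.ndarray        # normalized correlation at each lag
    peak_value: float         # max within the peak search window
    peak_time_s: float        # lag of that max
    highly_significant: bool  # peak_value > threshold and |peak| <= window


def normalized_xcorr(
    train_p: np.ndarray,
    train_q: np.ndarray,
    total_time_s: float,
    bin_ms: float = 10.0,
    max_lag_ms: float = 500.0,
    peak_window_ms: float = 200.0,
    sig_threshold: float = 8.0,
    cell_a: str = "",
    cell_b: str = "",
) -> SpikeXcorr:
    """Normalized spike-count cross-correlogram of two spike trains.

    ``total_time_s`` is the total included observation time (running
    epochs) from which both trains were taken.  Positive peak time means
    spikes of ``train_q`` tend to follow spikes of ``train_p``.
    Antisymmetric under exchanging the trains: C~_PQ(dT) = C~_QP(-dT).
    """
    p = np.sort(np.asarray(train_p, dtype=float))
    q = np.sort(np.asarray(train_q, dtype=float))
    if total_time_s <= 0:
        raise ValueError("total_time_s must be positive")
    if len(p) == 0 or len(q) == 0:
        raise ValueError("both trains must contain at least one spike")
    b = bin_ms / 1000.0
    lags = np.arange(-max_lag_ms, max_lag_ms + bin_ms / 2, bin_ms) / 1000.0
    m = len(p) * len(q) * b / total_time_s
    counts = np.empty(len(lags))
    for i, lag in enumerate(lags):
        lo = np.searchsorted(q, p + lag - b / 2, side="left")
        hi = np.searchsorted(q, p + lag + b / 2, side="right")
        counts[i] = (hi - lo).sum()
    values = (counts - m) / np.sqrt(m)
    window = np.abs(lags) <= peak_window_ms / 1000.0 + 1e-12
    widx = np.flatnonzero(window)
    best = widx[np.argmax(values[widx])]
    peak_value = float(values[best])
    peak_time = float(lags[best])
    return SpikeXcorr(
        cell_a=cell_a,
        cell_b=cell_b,
        lags_s=lags,
        values=values,
        peak_value=peak_value,
        peak_time_s=peak_time,
        highly_significant=bool(peak_value > sig_threshold),
    )


def peak_time_bias(peak_times_s) -> tuple[float, float]:
    """Sign bias of a set of signed peak times.

    Returns the fraction of positive peak times among nonzero ones and
    the exact two-sided binomial p-value against equal probability.
    Zero peak times are excluded.
    """
    pt = np.asarray(peak_times_s, dtype=float)
    pt = pt[pt != 0]
    if pt.size == 0:
        raise ValueError("no nonzero peak times")
    n_pos = int((pt > 0).sum())
    res = stats.binomtest(n_pos, pt.size, 0.5, alternative="two-sided")
    return n_pos / pt.size, float(res.pvalue)
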