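"""Run configuration: every numeric constant of the analysis in one place."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Analysis constants with their standard defaults.

    Spatial binning is 2 cm with 2-bin Gaussian smoothing; activity
    thresholds are 0.5 Hz (trajectory-active) and 5 Hz (putative CA1
    interneuron); the running mask excludes the final ~10 cm at each
    track end and stops slower than 6 cm/s lasting at least 0.5 s; the
    shuffle null uses 100 shuffles with a location-responsiveness cutoff
    of SMI > 2.325; field detection uses a 30th-percentile baseline,
    1-Hz / 20%-of-baseline peak criteria, 10% boundaries and a 4-cm
    merge gap; spike correlograms use 10-ms bins with a significance
    threshold of 8 and a ±200-ms peak window; bidirectional calls use a
    ±50-cm window at the per-lag Bonferroni level 0.00098; pair
    analyses require ≥50% field overlap and ≥10 usable laps.
    """

    bin_cm: float = 2.0
    smooth_sigma_bins: float = 2.0
    n_shuffles: int = 100
    smi_threshold: float = 2.325
    active_hz: float = 0.5
    interneuron_hz: float = 5.0
    speed_floor_cms: float = 6.0
    stop_min_s: float = 0.5
    well_margin_cm: float = 10.0
    baseline_pct: float = 30.0
    field_peak_min_hz: float = 1.0
    field_peak_baseline_frac: float = 0.2
    field_boundary_frac: float = 0.1
    field_merge_gap_cm: float = 4.0
    xcorr_bin_ms: float = 10.0
    xcorr_max_lag_ms: float = 500.0
    xcorr_peak_window_ms: float = 200.0
    xcorr_sig_threshold: float = 8.0
    bidir_window_cm: float = 50.0
    bidir_alpha: float = 0.00098
    overlap_min_frac: float = 0.5
    min_laps: int = 10
    sic_use_smoothed: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("master_seed", "sic_use_smoothed"):
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
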