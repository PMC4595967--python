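# Methods

This note documents the models and procedures implemented in
`trackcell`, the defaults and why they were chosen, what the synthetic
sessions do and do not emulate, and the numerical decisions that were
genuinely open.

## Behavior: linearization, laps, running mask

Tracked positions (t, x, y, head direction at ~33 Hz) are projected
onto a piecewise-linear track path and expressed as arclength `s` from
one food well.  The two **trajectories** are the two running
directions; within a lap, position is re-expressed in the direction of
running (`pos = s` on trajectory 1, `pos = L − s` on trajectory 2,
track length L = 300 cm by default).

A **lap** runs from the last sample inside the departure well zone
(within 10 cm of a track end) to the first sample inside the opposite
zone.  Excursions that leave a well zone and return to it without
reaching the far well are discarded; this is a stated convention — on a
rewarded back-and-forth task the behavioral unit is the completed
traversal, and partial runs are rare and ambiguous.

Speed is the forward difference of linearized distance,
`|s[i+1] − s[i]| / (t[i+1] − t[i])`, with the last sample copying its
predecessor.  A sample is **running** iff it is inside a lap, outside
both 10-cm well zones, and not inside a stopping interval — a maximal
stretch of samples with speed < 6 cm/s spanning ≥ 0.5 s.  Because
speed is forward-looking, the time span of a slow stretch includes the
period after its last slow sample; stop boundaries are therefore
accurate to one sample period.  All downstream stages consume only
running samples and the spikes that fall on them.

## Rate curves and spatial metrics

Rate curves use uniform 2-cm bins (150 on a 300-cm track), half-open
`[2k, 2k+2)` with the last bin closed.  Occupancy is the summed sample
period per bin over running samples; the raw rate is pooled spike
count over occupancy.  Spikes are assigned to the tracking sample
whose period contains them (so the running mask applies at spike
resolution) and positioned by linear interpolation between samples,
since spike timing is much finer than 33-Hz tracking.

Smoothing uses a Gaussian kernel, sigma = 2 bins, truncated at ±4σ and
renormalized where it overhangs the array — no reflection or
wrap-around, because the track ends are physical boundaries.  A
constant curve is exactly invariant under this smoothing.

Spatial information content (bits/spike) over occupied bins:

    SIc = Σ_i p_i (x_i / r) log2(x_i / r),   p_i = t_i / Σ t_i

with the `x log x → 0` convention for silent bins.  Inside the sum, r
is the occupancy-weighted mean of the curve supplying the `x_i`, which
keeps SIc ≥ 0 (Jensen).  The rate multiplier in `SIr = SIc × r` is the
cell's raw mean rate (included spikes over occupied time): it is
unaffected by smoothing and invariant under the circular shuffle,
which makes the SIc- and SIr-based modulation indices (below) agree
closely.  Whether the x_i come from the smoothed or raw curve is a
config switch (`sic_use_smoothed`, default smoothed — the curves are
defined as smoothed throughout the pipeline).

Spatial stability is the mean Pearson correlation between the smoothed
per-lap curves of every unordered lap pair, computed over bins occupied
in both laps; pairs where either lap has zero rate variance (or fewer
than two shared occupied bins) are skipped and counted.

Activity classes: a cell is trajectory-active above 0.5 Hz over the
trajectory's running epochs; CA1 cells above 5 Hz are flagged putative
interneurons and excluded downstream, while high-rate V1 cells are
retained (V1 rate distributions do not separate into clusters the way
CA1 pyramidal/interneuron rates do).

## Shuffle null and the spatial modulation index

The null hypothesis is that spike timing is unrelated to position.
Within each lap `[T1, T2]`, all spikes are shifted by a single offset R
drawn uniformly from `[0, T2 − T1)` and wrapped circularly,

    P → T1 + ((P + R − T1) mod (T2 − T1)),

independently per lap.  This preserves per-lap spike counts and, up to
one wrap point per lap, the inter-spike-interval structure, while
destroying spatial correlates.  The full shuffled train is re-binned
and its SIc recomputed; with m, s the mean and SD of 100 shuffle
values and a the actual SIc,

    SMI = (a − m) / s,

and a cell is **location-responsive** when SMI > 2.325.  The threshold
is stored as the constant 2.325 (the conventionally printed normal
99th percentile, which `scipy.stats.norm.ppf(0.99) = 2.3263` matches to
0.06%) rather than recomputed, so classifications are bit-reproducible.
Each (cell, trajectory) gets its own RNG stream derived from
`(master_seed, crc32(cell_id), trajectory)`, making results independent
of iteration order.

A calibration caveat documented by `calibration.smi_null_calibration`
and exercised in the test suite: for location-independent Poisson
cells the mean SMI is ~0 as expected, but the fraction exceeding 2.325
is ~2–3%, not 1%.  Smoothing leaves the SIc null with few effective
degrees of freedom, so it is right-skewed and a Gaussian quantile
under-covers its upper tail; the unsmoothed variant sits nearer the
nominal rate.  Users who need a calibrated false-positive rate should
use the empirical shuffle percentile rather than the z-cutoff.

## Firing fields

On the smoothed curve, the baseline is its 30th percentile (robust to
a field occupying up to ~half the track; detection results are stable
for percentiles between roughly the 15th and 50th, which is exposed by
the `baseline_pct` parameter).  After subtracting the baseline and
clipping at zero, local maxima taller than both 1 Hz and 20% of the
baseline become fields; track-end bins count as peak candidates.
Boundaries extend outward to the first bin at or below 10% of the
*subtracted* peak — interpreting the 10% criterion on the subtracted
scale keeps boundaries defined even when the baseline exceeds 10% of
the raw peak.  Fields closer than 4 cm merge by interval union,
keeping the larger peak, iterated left-to-right (a fixpoint for
interval unions, so ordering does not matter); post-merge gaps are
always ≥ 4 cm.  Detection runs on trajectory-active CA1 cells and on
location-responsive trajectory-active V1 cells.

Field-peak positions per 2-cm bin, smoothed with the same 2-bin
Gaussian, give a per-region field-distribution curve; the V1 and CA1
curves are compared by a sliding Pearson correlation over integer-bin
lags (overlapping support only).  The lag convention throughout:
correlating `a[i]` with `b[i + lag]`, a positive peak lag means curve
b's features sit at larger positions, i.e. curve a leads along the
running direction.

**Bidirectional cells** (location-responsive on both directions): the
trajectory-2 curve is flipped into physical coordinates and
cross-correlated with the trajectory-1 curve over lags −50…+50 cm in
2-cm steps (51 lags).  A peak significant at the per-lag Bonferroni
level 0.05/51 ≈ 0.00098 classifies the cell as prospective (positive
lag: firing precedes the shared landmark on both directions — a cell
firing d cm before a landmark peaks at +2d) or retrospective (negative
lag).

## Temporal cross-correlograms

For trains P (M spikes) and Q (N spikes) restricted to running epochs
of total duration T, the raw correlation at lag dT counts Q spikes in
`[P_i + dT − B/2, P_i + dT + B/2]` over all i, with B = 10 ms.  The
Poisson expectation is `m = M·N·B/T`, and

    C~(dT) = (C(dT) − m) / √m

is displayed over ±500 ms; the peak is searched within ±200 ms and a
pair is highly significantly correlated when the peak exceeds 8
(~z-test p < 1e-4; the significant set is insensitive to thresholds
between 3 and 10 for strongly coupled pairs).  The construction is
exactly antisymmetric under exchanging the trains.  Only P spikes are
required to lie in running epochs; Q spikes are counted wherever they
fall, an edge effect that is second-order for 10-ms windows.  The
population sign bias of significant peak times is tested with an exact
two-sided binomial test against 0.5, excluding exactly-zero peaks.

## Lap-by-lap pair co-fluctuation

Pairs of cells active on the same trajectory are classified:

* **overlapping** — some field pair overlaps by ≥ 50% of the *shorter*
  field (the strictest symmetric denominator; configurable) and the
  pair's spike correlogram has a peak ≥ 8 within ±200 ms (screening
  out pairs that rarely fire together in time).  The probed fields are
  the overlapped pair with the largest summed peak rates.
* **non-overlapping** — both cells have fields, none overlapping
  enough; each cell is probed in its dominant field.
* **non-responsive** — one cell responsive with fields, the other not;
  the responsive cell's dominant field is probed and the other cell
  receives a copy of that interval shifted by a seeded random distance
  giving an overlap uniform in [50%, 100%].

Pairs with enough field overlap but a sub-threshold correlogram fit no
class and are excluded.

Per lap and per cell, the within-interval firing rate (spikes over
in-interval running time) and spike COM are computed; Δrate and ΔCOM
are deviations from their across-lap means, so each Δ series sums to
zero.  Zero-spike laps contribute rate 0 (a real observation) but have
undefined COM and are dropped pairwise for COM correlations.  Pearson
correlations require ≥ 10 paired laps (below that, p-values are too
unstable to report; flagged missing instead).

Behavioral covariates per lap: mean running speed through the probed
interval and Δhdir — the circular-mean head direction through the
interval minus the circular mean over laps, wrapped to (−180°, 180°]
and treated linearly thereafter (lap-to-lap head-direction spread on a
track is a few tens of degrees, well inside the linear regime).  The
modified Δ series are residuals of an ordinary least-squares fit
`Δ = αV + βD + intercept + x′` (intercept included as standard OLS
practice; collinear covariates fall back to the pseudo-inverse with a
warning).  Residuals are exactly uncorrelated with V and D, so any
remaining pair correlation cannot be carried by those covariates.

**COM drift**: for cells with ≥ 25 laps, per-lap COM change is
measured relative to the mean over laps 21–25 (the stabilized value);
the population mean per lap and the least-squares slope over laps 1–10
quantify early backward shift.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes:

* **Behavior** — back-and-forth runs on a 300-cm track at 33 Hz; speed
  follows an Ornstein–Uhlenbeck process (sd 5 cm/s, mean-reversion
  1/s) around a per-lap mean drawn N(35, 3²) cm/s, floored at 2 cm/s
  so arclength is strictly monotone within a run; 2-s well pauses and
  optional scripted mid-track stops; head direction is the running
  heading plus a per-lap offset (sd 8°) and per-sample noise (sd 3°).
  The 35 cm/s mean matches typical rat running on such tracks.
  Tracking is modelled as quantization of the true position to the
  0.2-cm tracker resolution (with optional additive jitter, default
  off): a stationary animal then reads a constant position, as real
  trackers do after their sub-resolution jitter is absorbed by
  quantization.  Per-frame jitter that straddles a quantization
  boundary — which can make stationary "speed" flicker above a 6-cm/s
  threshold in real data — is deliberately not emulated.
* **Spiking** — inhomogeneous Poisson via Bernoulli thinning.  Cell
  rate at sample k:

      λ = clip0( [baseline + Σ_f g_{c,l} · peak_f ·
                  exp(−(s_k − (center_f + j_{c,l}))² / 2σ_f²)]
                 · (1 + c_v (v_k − μ)/μ + c_d Δhdir_k / 30°) )

  with per-(cell, lap) multiplicative gain `g = max(0, 1 + 0.35 z)`
  and field-center jitter `j = 3 cm · z′`, where the latent standard
  Gaussians z, z′ are correlated within designated pairs (ρ_gain,
  ρ_com) and independent otherwise.  The Δhdir modulation is scaled by
  30° so coefficients are order-1 over the realistic head-direction
  range.  Thinning probability λ·Δt is capped at 0.95 with a warning
  (error if >10% of samples hit the cap); a finer thinning grid
  (`time_resolution_s`, e.g. 1 ms) is available where sub-frame spike
  timing matters — the 10-ms cross-correlograms — or where λ·Δt would
  saturate.
* **Not emulated** — theta rhythmicity and phase precession, bursting,
  refractoriness, 2-D fields, slow electrode drift, sleep/rest states.
  Passing tests therefore demonstrate estimator correctness and
  parameter recovery under the assumed model, not robustness to every
  property of real recordings.

Sessions are byte-reproducible from (config, master_seed); all latent
truth (lap windows, fields, gains, jitters, coefficients) is returned.

## Calibration experiments and problem sizes

`trackcell.calibration` packages the recovery studies used by the test
suite and `scripts/acceptance.py`; sizes were chosen to give 3-SE
discrimination in seconds to minutes on one core:

* SMI null: 200 Poisson cells at 3 Hz, 25 laps, 100 shuffles, both
  trajectories (400 indices).
* Gain-correlation recovery: ρ ∈ {0, 0.2, 0.4, 0.6, 0.8}, 50 pairs per
  ρ, 50 laps, 20-Hz fields; measured Δrate correlation is attenuated
  below ρ by Poisson noise but strictly increasing in ρ.
* Pair-class contrast: 20 pairs per class, 40 laps; only overlapping
  pairs carry shared gain (ρ = 0.6).
* Confound removal: 40 pairs, 40 laps; scenario A couples both cells to
  running speed only (speed coefficient 2, no latent coupling),
  scenario B uses latent coupling only.
* Field detector: 200 single-Gaussian-field cells (peak 8 Hz, σ = 8 cm,
  baseline 0.05 Hz), 25 laps.
* Bidirectional recovery: one cell firing 18 cm before a landmark on
  both directions (expected lag +36 cm).

## Known limitations

* The SMI z-cutoff over-rejects under the smoothed-SIc null (see
  above); the empirical shuffle percentile is the calibrated
  alternative.
* Lap segmentation assumes the animal eventually completes traversals;
  pathological dithering exactly at a well-zone edge can split laps.
* The default track geometry for analysis is a straight path; for
  projected 2-D data with a genuinely curved track, pass the real
  `TrackGeometry` to `run_pipeline`.
* Δhdir is treated linearly; sessions with multimodal or large
  head-direction spread violate this.
* The spike-correlogram edge convention (Q counted outside running
  epochs) slightly inflates counts at epoch boundaries; negligible at
  B = 10 ms but visible for very long lags.
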