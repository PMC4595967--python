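# trackcell

Spatial-coding analysis for paired extracellular recordings on a
linearized running track — built for datasets where a visual-cortex
(V1) population is recorded simultaneously with hippocampal CA1 place
cells while a rodent runs back and forth between two reward wells.

The package answers three kinds of questions:

1. **Is a cell's firing location-specific?**  Occupancy-normalized
   firing-rate curves in 2-cm bins, Skaggs spatial information
   (SIc, bits/spike; SIr, bits/s), lap-pair spatial stability, and a
   rate-insensitive **spatial modulation index (SMI)** — the z-score of
   the cell's SIc against a null built by circularly shifting its
   spikes within each lap (100 shuffles; location-responsive when
   SMI > 2.325, the normal 99th percentile).
2. **Where and when do two populations interact?**  Firing-field
   detection (30th-percentile baseline, 1-Hz peak floor, 10%
   boundaries, 4-cm merge gap), field-distribution cross-correlograms,
   prospective/retrospective classification of bidirectional cells,
   and Poisson-normalized spike-count cross-correlograms
   `C~(dT) = (C(dT) − MNB/T) / sqrt(MNB/T)` with an exact binomial
   sign-bias test on the population of peak times.
3. **Do cell pairs co-fluctuate lap by lap?**  For pairs with
   overlapping firing fields, within-field firing rate and spike
   center-of-mass (COM) per lap, their deviations from the across-lap
   mean (Δrate, ΔCOM), Pearson correlations between the two cells'
   deviations, and the same after regressing out running speed and
   head direction (`Δ = αV + βD + x′`) — the "noise-correlation"
   analysis that separates genuine coupling from shared behavioral
   modulation.

A first-class synthetic-session simulator generates tracking and spike
trains with known ground truth (fields, per-lap gains, injected pair
correlations, speed/head-direction modulation), so every stage of the
pipeline is testable by parameter recovery without any recorded data.

## Worked example

```python
import trackcell as tc

cfg = tc.demo_config(master_seed=1)          # 10 cells, 4 coupled V1–CA1 pairs
session, truth = tc.generate_session(cfg)
result = tc.run_pipeline(session, tc.RunConfig(master_seed=1))

m = result.metrics
act = m[m["active"]]
print("active cell x trajectories:", len(act))
print("location-responsive:", int(act["location_responsive"].sum()))
print(act[["cell_id", "trajectory", "overall_rate_hz", "sic_bits_per_spike", "smi"]]
      .head(6).round(2).to_string(index=False))
ov = result.pairs[result.pairs["class"] == "overlapping"]
print("overlapping pairs:", len(ov),
      " mean r_drate = %.2f" % ov["r_drate"].mean(),
      " mean r_dcom = %.2f" % ov["r_dcom"].mean())
```

prints

```
active cell x trajectories: 18
location-responsive: 16
cell_id  trajectory  overall_rate_hz  sic_bits_per_spike   smi
   v1_0           1             2.29                0.71 19.67
   v1_0           2             2.10                0.81 27.55
  ca1_0           1             1.73                1.54 22.99
  ca1_0           2             1.42                1.51 19.36
   v1_1           1             2.34                0.78 25.03
   v1_1           2             2.26                0.79 24.74
overlapping pairs: 8  mean r_drate = 0.23  mean r_dcom = 0.16
```

Each simulated cell carries one Gaussian firing field, so every active
cell scores far above the SMI cutoff; the four designated V1–CA1 pairs
were generated with a latent gain correlation of 0.6, and the measured
lap-by-lap Δrate correlation of ~0.23 reflects that coupling attenuated
by Poisson spiking noise.

## Command line

```bash
trackcell simulate --out demo --seed 1            # positions/spikes/cells CSV + truth.json
trackcell analyze --positions demo/positions.csv --spikes demo/spikes.csv \
                  --cells demo/cells.csv --out results --seed 1
```

`analyze` writes `metrics.csv`, `fields.csv`, `bidir.csv`,
`xcorr_pairs.csv`, `pairs.csv`, `comshift.csv`, `laps.csv`,
`linearized.csv` and `summary.json` (grouped by region, cortical layer,
and day group T1/T2/T3); it exits with code 2 on schema-validation
failure.  Sessions can also be supplied as a single HDF5 container
(see `trackcell.io`).

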