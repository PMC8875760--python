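# chronofish

Circadian rhythm, sleep, and bioluminescence-reporter analysis for zebrafish
larval recordings.

Chronobiology labs routinely ask three questions of a larval zebrafish
experiment: *does each animal have a circadian rhythm, and with what period,
phase, and amplitude?* (from locomotor tracking, distance moved per 10-min
bin); *how much does each larva sleep, and when?* (from ~1-s velocity
traces); and *what is the molecular clock doing?* (from per-well luciferase
bioluminescence under light/dark and constant-dark conditions).  chronofish
implements one coherent, tested pipeline for all three, plus a synthetic-data
generator with known ground truth so that every stage can be validated by
parameter recovery — useful because raw recordings in this field are rarely
shared.

## Methods at a glance

**Locomotor rhythms.** Each trace is normalized by its mean and smoothed by a
LOESS-smoothed running 75th-percentile curve (half-windows 3.33 h and 8.33 h;
20 and 50 sliding points each side at 10-min bins).  From the peaks (local
maxima) and troughs of the smoothed curve:

- period: P̂ = weighted mean of consecutive peak gaps, each peak weighted in
  proportion to its amplitude (peak height − preceding trough height);
- phase: φ̂ = weighted circular mean direction of peak times on the P̂-circle,
  θᵢ = 2π(tᵢ mod P̂)/P̂, reported both on the P̂-circle and rescaled to the
  24-h circadian (CT) clock;
- amplitude: Â = ½·(height of the 2nd-day peak − preceding trough height);
- rhythmicity: the **G-factor**, the DFT periodogram power at the frequency
  bin nearest 1/24 h⁻¹ divided by the summed power of all positive
  frequencies (DC excluded) — 1 for a clean 24-h rhythm, ≈0 for noise.

**Sleep.** A velocity hysteresis (stop threshold 0.59 cm/s, start threshold
0.60 cm/s) classifies each sample as moving or still; a still bout lasting
*more than* one minute is sleep.  Sleep minutes are apportioned to clock
hours and to day/night totals by exact overlap with the lighting schedule.

**Bioluminescence.** Each well is standardized (z-scored), detrended and
smoothed by moving averages (29 h / 9 h full windows) or LOESS (44 h / 22 h),
and peak-split at the 108-h last-light mark into LD and DD segments, with
period/phase/amplitude estimated per segment.

**Group statistics.** Circular mean phases with resultant lengths,
Watson–Williams F tests for phase, exact/asymptotic Wilcoxon rank-sum tests
for period, amplitude and G-factor, Benjamini–Hochberg FDR adjustment, a
permutation-tested two-cluster heat-map analysis, and dark-flash
(before/during/after) response extraction.

## Worked example

Simulate two 12-larva groups with an imposed 7.2-h phase delay under three
days of constant dim light, then analyze and compare:

```sh
chronofish simulate --kind activity --groups wt,mut --phase-offset-h 7.2 \
    --n-subjects 12 --n-days 3 --seed 7 --out-dir demo
chronofish analyze-activity --input demo/tracking.csv --out-dir demo
chronofish compare-groups --input demo/rhythm_results.tsv --out-dir demo
```

`demo/rhythm_results.tsv` holds one row per larva:

```
subject_id  group  period_h  phase_ct_h  amplitude  g_factor  n_peaks
wt_000      wt     24.167    5.793       0.413      0.328     2
wt_001      wt     24.333    4.438       0.550      0.301     2
...
```

and `demo/group_comparison.json` reports the group-level comparison; with the
data above it contains

```
wt:  phase_mean_ct_h = 5.83,  R̄ = 0.97, period_median_h = 24.17
mut: phase_mean_ct_h = 13.31, R̄ = 0.99, period_median_h = 23.84
phase_difference_h = 7.49   (imposed: 7.2)
Watson–Williams F = 478.6, p = 2.0e-16
```

i.e. the pipeline recovers the imposed 7.2-h delay to within ~0.3 h at
realistic noise and flags it as highly significant, while the unshifted
periods do not differ (Wilcoxon p = 0.22).

The same CLI provides `simulate --kind velocity|lum`, `analyze-sleep`, and
`analyze-lum`; every run writes a `resolved_config.yaml` next to its outputs
for provenance.  All stages are also available as a library —
`RhythmEstimator`, `SleepScorer`, `MeanNormalizer`/`ActogramSmoother` follow
scikit-learn's fit/transform conventions and compose with sklearn pipelines.

## Layout

| module | contents |
| --- | --- |
| `chronofish.schedule` | lighting protocols (LD, LDim, DimDim, DD, LD→DD, entrainment→DimDim) |
| `chronofish.simulate` | synthetic locomotor / velocity / bioluminescence generators with ground truth |
| `chronofish.preprocess` | mean-normalization, z-scoring, moving average/percentile, LOESS, actogram smoothing |
| `chronofish.rhythm` | extrema, period/phase/amplitude, G-factor, LD/DD split, `RhythmEstimator` |
| `chronofish.sleep` | velocity hysteresis, sleep bouts, hourly/day/night summaries, `SleepScorer` |
| `chronofish.stats` | circular statistics, Watson–Williams, Wilcoxon, BH, clustering, dark-flash responses |
| `chronofish.io` / `chronofish.cli` | CSV/TSV/JSON readers and writers, YAML config, `chronofish` command |

See `docs/methods.md` for the full statistical methodology, parameter
defaults, and known limitations.
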