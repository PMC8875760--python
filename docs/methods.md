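# Methods

This note documents the models, estimators, defaults, and numerical
conventions implemented in chronofish, and what the synthetic-data
validation does and does not demonstrate.

## Time and lighting conventions

Time is decimal hours from the recording start; hour 0 is lights-on (ZT0
under an entraining cycle, projected CT0 under constant conditions).  Bins
are half-open `[start, start + bin)` and stored times are bin left edges.
Lighting schedules are contiguous epochs of LIGHT (770 lux), DARK (0 lux),
or DIM (7.5 lux).  Composite protocols are pinned as: `LD_THEN_DD` =
`n_days` 12:12 LD cycles followed by `n_days` of constant dark;
`ENTRAIN_THEN_DIMDIM` = 3 LD + 2 LDim cycles followed by `n_days` of
constant dim.  A schedule's free-run onset is the start of its terminal
constant epoch (the first moment the lights stop cycling).

## Locomotor rhythm estimation

1. **Normalization** — each trace is divided by its mean (all-zero traces
   are an error, not a silent NaN).
2. **Smoothing** — a centered running 75th percentile (half-window 3.33 h)
   followed by a LOESS smooth (half-window 8.33 h); at 10-min bins these are
   exactly 20 and 50 sliding points on each side.  The 75th percentile
   tracks the upper envelope of bursty larval activity, which is where the
   circadian signal lives.
3. **Extrema** — strict interior local maxima/minima; plateaus contribute a
   single extremum at their midpoint; endpoints are never extrema;
   alternation is enforced by discarding the lower of two consecutive peaks
   (and symmetrically for troughs).  Two practical guards are applied by the
   estimator:
   * *prominence pruning*: adjacent peak/trough pairs closer in height than
     10⁻⁶ of the curve range are removed — they are floating-point ripple in
     near-flat regions, and under amplitude weighting their gaps would
     otherwise receive half the weight of a real peak's gap;
   * *edge exclusion*: extrema within one LOESS half-window (8.33 h) of
     either end come from truncated, extrapolative windows and sit up to
     ~1 h off; they are excluded whenever at least two interior peaks
     remain (otherwise all extrema are kept and a note is logged).
4. **Period** — the weighted mean of consecutive peak gaps.  Weights attach
   to peaks in proportion to their amplitude (peak height − preceding trough
   height; the first peak, lacking a preceding trough, uses the following
   trough); a gap's weight is the mean of its two flanking peak weights
   (alternatives `left`/`right` are config-exposed).
5. **Phase** — the weighted circular mean direction of peak times on the
   estimated period circle: θᵢ = 2π(tᵢ mod P̂)/P̂ and
   φ̂ = (P̂/2π)·atan2(Σwᵢ sin θᵢ, Σwᵢ cos θᵢ) mod P̂, reported both on the
   P̂-circle and rescaled to 24 circadian hours (φ̂·24/P̂) for cross-subject
   comparison.  A zero resultant (perfectly antipodal peaks) is an error.
6. **Amplitude** — half the height difference between the 2nd-day peak
   (the highest peak with time in [24 h, 48 h)) and its preceding trough.
7. **G-factor** — the series is mean-subtracted and a plain DFT periodogram
   computed (the recordings are uniformly sampled; a Lomb–Scargle variant
   is available behind the same interface).  G = power at the positive
   frequency bin nearest 1/24 h⁻¹, divided by the summed power of all
   positive frequencies up to Nyquist, DC excluded.  For a 72-h recording
   the 24-h period is an exact bin (k = 3).  G is invariant to adding a
   constant and to rescaling; it requires a span of at least two target
   periods.

### Precision of the phase estimate

Because peak times enter the phase as absolute times mod P̂, an error δP in
the period propagates into the phase multiplied by roughly the mean number
of elapsed cycles.  The estimate is unbiased, but its standard error is a
multiple of the period's.  Consequences measured on synthetic cohorts
(6-day recordings): at bin-level noise CV ≈ 0.22 the per-subject ±0.5 h
precision for both period and phase is met for ≥ 90 % of subjects across
periods 22–30 h; at CV ≈ 0.55 (the generator's realistic default)
per-subject phase precision degrades to ~1 h, while group-level phase
contrasts (circular means over n = 24) remain accurate to well under
±0.5 h.  Recovery experiments therefore run at dispersion 0.05 (CV ≈ 0.22,
"moderate"), and group-comparison conclusions are robust at realistic noise.

## Bioluminescence analysis

Each well is standardized (subtract mean, divide by sample SD, ddof = 1 —
a constant well is an error), long-term detrended and smoothed either by
centered moving averages (29 h and 9 h full windows) or by LOESS (44 h and
22 h full windows), chosen per experiment.  Peaks are split into LD and DD
sets at the 108-h mark (end of the last light period): the last peak counted
as LD is the first one strictly after 108 h.  Period (unweighted mean gap by
default for bioluminescence), phase (rescaled to the 24-h clock), and
successive peak amplitudes are estimated per segment.  Peaks within one
smoothing half-window of the recording end are excluded from segment
estimates — local regression is extrapolative there and the final peak's
apparent amplitude is unreliable.

## Sleep scoring

A hysteresis state machine with stop threshold 0.59 cm/s and start threshold
0.60 cm/s: a moving larva becomes still when velocity drops below the stop
threshold, a still larva starts moving when velocity exceeds the start
threshold, and velocities inside the band preserve the current state; the
initial state is MOVING iff the first sample exceeds the start threshold.
A still run spanning samples i…j (inclusive) lasts (j−i+1)·Δt and becomes a
sleep bout iff strictly longer than 60 s (a 60-s run is not sleep; a 61-s
run is).  Bout minutes are apportioned to clock hours — and to day (LIGHT
epochs) and night (DARK epochs) totals — by exact interval overlap; a bout
crossing a boundary is split, never rounded to one side.  DIM epochs count
toward hourly values but toward neither day nor night total.  Negative
velocities are an input error.

## Group statistics

* **Circular mean** — atan2 of weighted sine/cosine sums, with the mean
  resultant length R̄; R̄ = 0 leaves the mean undefined (error).
* **Watson–Williams** — the classical F test for homogeneity of mean
  directions with concentration correction K = 1 + 3/(8κ̂), κ̂ estimated
  from the pooled within-group resultant length by Fisher's approximation;
  a warning is attached when pooled R̄ < 0.7.  Peak weights are ignored:
  the test is defined for unweighted samples.  Monte-Carlo calibration
  (von Mises κ = 5, n = 20+20) puts the empirical type-I error at ≈ 0.05.
* **Wilcoxon rank-sum** — exact two-sided p (full U distribution) when the
  combined sample has ≤ 20 observations without ties; otherwise mid-ranks
  with the tie-corrected normal approximation (no continuity correction, so
  identical samples give p = 1).  The method used is recorded in the result.
* **BH adjustment** — standard step-up, monotone and capped at 1.  (Note
  that BH is *not* idempotent: re-adjusting adjusted p-values changes them.)
* **Clustering** — hierarchical clustering of per-subject smoothed profiles
  (correlation distance, average linkage — the field reports no standard
  here, so both are config-exposed), cut at k = 2, with leaf order exported
  for heat-map display.  Genotype–cluster association is assessed by
  permuting group labels (default 10,000 permutations; p has resolution
  1/(n_perm+1)) with the best-matching agreement fraction as statistic.
* **Dark-flash responses** — mean activity before/during/after each flash
  window, with bin values averaged by exact overlap weighting (flashes are
  shorter than one bin); group comparison is delegated to the rank-sum test.

## Synthetic data

The generators are pure functions of (config, schedule); subjects and wells
draw from counter-derived substreams `(seed, index)` so cohorts can grow
without reshuffling. Ground truth is stored on every trace.

* **Locomotor** — activity(t) = baseline·(1 + A·max(0, cos(2π(t−φ)/P)))
  with multiplicative gamma noise of unit mean (shape = 1/dispersion), a
  nonnegative, daytime-peaked waveform.  Defaults: P = 24 h, φ = 6 h,
  A = 2, baseline 20 cm/bin, 10-min bins, dispersion 0.3 (CV ≈ 0.55 —
  real larval bins are noisier still), between-subject period SD 0.25 h and
  wrapped-normal phase SD 0.5 h (emulating mutant-like variability when
  raised), and an additive masking burst of 1.5×baseline in the first two
  bins after every light→dark transition (the acute startle response; no
  dark→light burst by default).
* **Velocity** — a two-state (moving/still) Markov chain per 1-s sample
  with day/night transition probabilities (defaults 0.005/0.2 by day,
  0.05/0.02 by night: larvae nap briefly by day and consolidate sleep at
  night); moving speed is Gaussian (1.2 ± 0.3 cm/s) floored just above the
  start threshold, still speed is 0.  DIM epochs use the night
  probabilities (dim is the rest phase of an LDim cycle).  The 1-s sampling
  is a stand-in: tracker frame rates vary and are rarely reported.
* **Bioluminescence** — cosine with phase-continuous period switch from
  24 h (LD) to 26 h (DD) at the schedule's free-run onset, exponential
  amplitude damping after DD onset (0.01 /h), a linear baseline trend
  (100 − 0.05·t counts), and additive Gaussian well noise (SD 2 counts on a
  20-count amplitude), 10-min sampling, 8 wells; 5 LD cycles + 5 DD days by
  default.

What the generators deliberately do **not** model: biomechanics of larval
swimming, development across 4–8 dpf, melatonin kinetics, light-history
(aftereffect) dependence of period, well-position plate effects, and
photobleaching nonlinearity.  Passing recovery tests therefore shows the
*estimators* are correct and calibrated under the stated noise model — not
that real recordings meet that model.

## Numerical conventions

* Sample SD (ddof = 1) everywhere.
* Percentiles use linear interpolation between closest ranks.
* Smoothing windows truncate at series boundaries; no padding, reflection,
  or gap imputation (readers reject gaps outright).
* LOESS is degree-1, tricube, no robustness iterations; distances are
  scaled by (half-window + one sample spacing) so the outermost sliding
  point retains positive weight — scaling by the half-window itself would
  zero it and make the minimal window degenerate.  Interior points reduce
  exactly to a tricube-weighted moving average (symmetry cancels the slope
  term), which is used as a fast path; boundary points get explicit
  weighted fits.
* The half-window/full-window distinction follows the sources of the
  defaults: actogram windows (3.33/8.33 h) are half-windows; moving-average
  (29/9 h) and LOESS (44/22 h) bioluminescence windows are full widths.
  Both interpretations are exposed in the API.
* Phase differences are signed minimal circular differences in
  (−circle/2, +circle/2], with the antipodal tie reported as +circle/2.
* G-factor target bin: nearest frequency bin to 1/24 h⁻¹, logged at DEBUG
  level.

## Experiment sizing in the validation suite

Recovery experiments use 6-day constant-dim recordings so the slowest
cohort (P = 30 h) shows at least four usable cycles after edge exclusion;
a 3-day recording cannot constrain a 30-h period to ±0.5 h by peak gaps.
Group-comparison and clustering demonstrations use the 3-day design at the
realistic noise default.  The statistical calibrations use 2000 null
replicates (Watson–Williams), full enumeration over all two-group splits of
8 distinct values (exact Wilcoxon), and 999–10,000 permutations
(clustering).

## Known limitations

* Peak-gap period estimation is less efficient than spectral or cosinor
  fits at high noise; it is used because it is the pipeline's defining
  procedure.  No cosinor regression or wavelet ridge tracking is provided.
* The phase estimator's error grows with recording length × period error
  (see above); phases of weakly rhythmic subjects (low G-factor) should be
  interpreted at the group level.
* Missing bins are rejected, not imputed; irregular sampling is supported
  only by the Lomb–Scargle G-factor variant.
* The linear mixed model and repeated-measures ANOVA used for some
  experiment-level comparisons in this literature are out of scope; the
  package exports tidy tables for fitting those in any standard package.
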