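# Methods

This note documents the models, conventions, and numerical choices behind
`circalab`, and what the simulator-based validation does and does not show.

## Time frames and containers

All absolute times are minutes from recording start; day 0 begins at ZT0
(lights-on) of the first protocol segment.  Bins are half-open `[t, t+bin)`
with timestamps at bin starts.  Zeitgeber Time (ZT0 = lights-on, ZT12 =
lights-off) is defined per schedule segment; in constant darkness it is
undefined and conversions raise.  Circadian Time anchors CT12 at the
regression-predicted activity onset, and one circadian hour is τ/24 clock
hours, so a time *d* minutes after predicted onset is CT `12 + (d/60)·(24/τ)`.

Activity traces store counts (float, NaN = missing) with a light-schedule
reference; immobility traces are 1-Hz binary flags.  The CSV dialect uses
`# key: value` comment headers (kind, start_min, bin_min, units) followed by
`timestamp,value` rows; missing values are empty fields, excluded from means
and warned about above 10% in a window.  Round trips are bit-exact.

## The virtual mouse

The simulator is a behavioral reduction, not a biophysical oscillator model
(explicitly out of scope, as are two-process sleep homeostasis and EEG).

**Phase dynamics.**  A daily onset anchor follows the protocol: under LD (or
a skeleton photoperiod the animal can lock to) it sits at lights-off; in DD it
drifts by (τ − 24) h per cycle; after an LD shift it moves toward the new
lights-off at most `reentrain_rate_h_per_day` per day (first-order
re-entrainment — reproduces the days-to-re-entrain readout without an
oscillator model); a CT16 light pulse in DD delays the anchor by
`phase_shift_delay_min`, accrued at the re-entrainment rate over at most two
transient cycles.  The realized onset each day adds Gaussian jitter
(`onset_jitter_min`), applied to the onset only — the offset is anchored —
mirroring the field's focus on onset precision.

**Activity.**  Counts are Poisson per bin.  The per-minute rate is
`active_rate` for half a cycle from the onset (12 h entrained, τ/2 in DD) and
a rest rate otherwise.  The nominal parameter is `activity_frac_night`, the
fraction of counts emitted in the active phase; the rest rate is derived as
`active_rate·(1−f)/f` (equal-length phases).  A duty-cycle reading of this
parameter was rejected: a mouse emitting 98% of counts at night would then be
"active" 23.5 h/day, contradicting nocturnality.  Light that falls inside the
active window multiplies the rate by (1 − m), the negative-masking
coefficient; under a skeleton photoperiod a mouse entrains iff m ≥ 0.5 (an
admitted invention — no quantitative masking/PRC model exists to copy — used
only for scenario tests).  Feeding windows (e.g. TRF ZT15–21) are carried in
the protocol and recorded in outputs but have no behavioral effect by
default.

**Immobility.**  Alternating mobile/immobile bouts with exponential
durations; the means switch between rest-phase ("day") and active-phase
("night") values at bout start.  Records begin mobile.

**Presets.**  `wt_like` and `ko_like` encode the direction of a wild-type vs
circadian-impaired contrast: τ 23.6 vs 23.4 h, onset jitter 8 vs 30 min,
night-activity fraction 0.98 vs 0.92, masking 0.78 vs 0.33, phase delay 136
vs 64 min, re-entrainment 1.0 vs 0.53 h/day, day sleep bouts 22 vs 15 min.
They are qualitative, not fitted; the day-time bout means were chosen so the
scored bout-count separation exceeds 2 SD at n = 8/group (a renewal-process
variance calculation), which the end-to-end direction test requires.

What passing recovery tests shows: the analysis chain is unbiased and
appropriately calibrated for data of this structure.  What it does not show:
robustness to ultradian activity structure, within-night pauses, missing-data
patterns, or sensor artifacts of real recordings.  In particular the
homogeneous active window yields far fewer activity bouts per day than real
mice (~1–6 vs ~20); the bout segmenter itself is validated by exact oracle
equivalence, not by the simulator.

## Sleep scoring

A second is scored asleep iff it lies in a run of ≥ 40 s whose immobile
fraction is ≥ 95% and that begins and ends on an immobile second (without the
endpoint rule, mobile padding would stretch a 39-s immobile stretch into a
qualifying 41-s run, defeating the length threshold).  The 95% criterion is
temporal — only the temporal trace survives export from the tracker.  The
scorer computes the union of all qualifying runs in O(n log n) using prefix
sums on an integer lattice and binary search over a prefix-minimum sequence;
it is exact (verified against an O(n²) enumerator on thousands of random
traces).  Sleep counts are `floor(scored seconds / 10)` per minute (0–6); the
10-s unit is a declared convention, recorded in the series metadata, chosen
so the bout criterion "count > 3/min" means > 30 s/min asleep.  Sleep bouts
are maximal runs of minutes with count > 3 (strict), minimum one minute.
Note that the 95% rule merges sleep separated by wake interruptions shorter
than ~2 min; scored bout lengths therefore sit above the generator's bout
means under realistic interruption rates (≈ +35% with 12-min mean wake
bouts).  Metrics assign a bout to day or night by its start minute; bouts
spanning ZT12 are not split, so per-phase bout counts sum to the 24-h count
only approximately.

## χ² periodogram

For each trial period of P bins (every integer bin count inside 20–28 h;
0.1-h steps at the default 6-min analysis bin) the series is folded into P
columns and

    Qp = N · Σ_h n_h (M_h − M)² / Σ_i (x_i − M)²

is compared against χ² quantiles with P − 1 degrees of freedom (the classic
Sokolove–Bushell statistic; the incomplete final fold row is included, with
column means over actual counts).  τ is the argmax of Qp among periods above
the α = 0.001 line; rhythmic power is %V(τ) = 100·Qp/N minus the p = 0.05
line in the same units — "variance explained, corrected for activity amount
and normalized to peak significance".  The exact normalization used by
commercial packages is proprietary; this definition is a declared
reconstruction.  Zero-variance or sub-threshold records return a flagged
arrhythmic result (τ = NaN, power 0) so batch runs never crash.  Measured
under white noise, the per-period test size is 0.5–0.8 × 10⁻³ at nominal
10⁻³ (slightly conservative because the denominator uses total rather than
within-column variance); across the 81-period grid roughly 3% of null records
show some supra-threshold period, which is the expected multiplicity of
per-period testing — peak significance across a grid is not family-wise
controlled, and the calibration test asserts the test-wise rate.

## Onsets, bouts, windows

The onset detector (the upstream tools never published theirs) correlates the
per-minute profile with a 6 h low / 6 h high step template within ±6 h of the
previous onset plus the expected period, then snaps to the first minute ≥ 3
counts/min that starts three consecutive supra-threshold minutes, is
sustained over the next 10 (≥ 6 above threshold, mean above threshold), and
follows ≥ 4 h averaging < 3 counts/min.  The quiescence test uses the mean
rather than every bin — with any realistic Poisson rest rate a literal
240-min spur-free run almost never exists.  Days without a candidate yield a
missing onset.  Onset variability is the SD of residuals about the
least-squares line through ≥ 5 onsets (denominator n − 2; the
mean-|residual| alternative is not implemented).  Activity bouts: minutes ≥ 3
counts/min, merged across sub-threshold gaps < 21 min, with sub-threshold
minutes inside a bout contributing their counts.  Windowed activity sums
counts in a ZT window per day and averages across days.

## Photic assays

Masking is `100·(baseline − light)/baseline` with the baseline taken at the
same ZT hour on the preceding day — sign-flipped from the raw percent-change
formula so suppression reads positive; a zero baseline is flagged undefined.
Re-entrainment requires the onset within 30 min (configurable; generous
relative to ~8-min wild-type onset variability) of the new lights-off for 5
consecutive days, returning the 1-based first day of the run or a sentinel.
Phase shift fits separate lines to 10 pre- and 10 post-pulse onsets and
evaluates both on the day after the pulse (pre − post; delays negative); an
option to exclude two post-pulse transient days exists but is off by default.
Skeleton-photoperiod metrics delegate to the periodogram and onset machinery
with ZT0–12 spanned by the two pulses as the subjective day.

## Densitometry

Integrated density is mean gray × ROI area, averaged left/right per section
and then across sections per animal.  Profile alignment fits a degree-5
polynomial per section (x normalized to [−1, 1] for conditioning), locates
its peak on a 10× oversampled grid, shifts the *original* y values by whole
bins to the median peak position (no interpolation), and averages over the
common support, dropping non-overlapping edges.  Left and right sides are
processed separately and orientation is normalized lateral→medial before
averaging.  No baseline subtraction is applied (none is documented upstream).
A global quintic carries a small position-dependent bias on narrow off-center
bumps (~2 bins on a Gaussian at 1/10 domain offset); differential bias
between similarly placed sections — what alignment depends on — is well
under a bin, and alignment is exact on polynomial bumps.  Degenerate
(constant) profiles fall back to a flagged unaligned average.

## Statistics

Two-group comparisons gate on Shapiro–Wilk per group and Brown–Forsythe
(median-centered Levene) across groups, both at α = 0.05: pass → Student t;
fail → Mann–Whitney (two-sided throughout).  Welch's t is available behind a
flag for the variance-only failure, off by default.  Factorial ANOVAs are OLS
fits with type-II sums of squares; repeated-measures waveform designs are
approximated as between/within with the animal as a blocking factor (exact
error terms for the original mixed design are not reconstructable).
Holm–Šidák step-down: for raw p sorted ascending,
`p̃_(k) = max_{j≤k} [1 − (1 − p_(j))^(m−j+1)]`, clipped to 1; the default
contrast family for 3-way designs is pairwise contrasts of the first factor
within each level of the slicing factor (e.g. genotype within time bins),
adjusted as one family.  Pearson correlations are pairwise-complete with
cells under 4 pairs or zero variance flagged as NaN.  Measured null
calibration with n = 8/group: gated-test and ANOVA main-effect type-I rates
are 5% within Monte-Carlo error.

## Problem sizes and determinism

All generators and the pipeline are pure functions of (params, protocol,
seed); per-animal seeds are derived deterministically from the run seed, and
every output file records the seed and a config hash.  The validation suite
uses the study's own scales: 10-day analysis windows at 1-min simulation
bins, 2-day sleep records at 1 Hz, 8 animals per group, 100 pipeline
replicates for the direction test, 500 white-noise records for periodogram
calibration, 2000 null tables for test calibration, 100–200 replicates per
recovery target, and 5-section × 100-replicate densitometry runs.  The full
suite completes in well under two minutes on one CPU.
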