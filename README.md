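# circalab

Behavioral chronobiology analysis for rodent sleep/circadian studies, with a
virtual-mouse simulator for ground-truth validation.

Mouse models of neurodevelopmental disorders are routinely phenotyped through
their sleep/wake behavior: immobility-defined sleep under a 12:12 light-dark
(LD) cycle, wheel-running or infrared activity rhythms in LD and constant
darkness (DD), and a battery of light-response assays (negative masking,
re-entrainment to a shifted LD cycle, entrainment to a skeleton photoperiod,
light-evoked phase shifts).  `circalab` implements that entire analysis chain
as a tested Python library:

* **Sleep scoring** — a second counts as sleep iff it lies in a run of ≥ 40 s
  that is ≥ 95% immobile (a criterion validated against EEG); per-minute sleep
  counts (1 count / 10 s); sleep bouts as maximal runs of minutes with count
  > 3; duration / bout number / bout length / max bout per light phase.
* **χ² periodogram** (Sokolove–Bushell) — for each trial period of *P* bins,

  Q<sub>P</sub> = N · Σ<sub>h</sub> n<sub>h</sub> (M̄<sub>h</sub> − M̄)² / Σ<sub>i</sub> (x<sub>i</sub> − M̄)² ,

  compared against χ²<sub>1−α, P−1</sub>; the free-running period τ is the
  supra-threshold peak (α = 0.001), and rhythmic power is reported as
  %V = 100·Q<sub>P</sub>/N at the peak minus the p = 0.05 significance level.
* **Activity onsets** — template-correlation detection per cycle, best-fit
  regression through 10 days, onset variability (SD of residuals, n − 2),
  activity-bout fragmentation (threshold 3 counts/min, maximum gap 21 min),
  ZT-windowed activity.
* **Photic assays** — masking (% suppression vs the same hour on the
  preceding day), days to re-entrain after a 6-h advance (onset within 30 min
  of the new lights-off for 5 consecutive days), phase shift from pre/post
  onset regressions evaluated the day after a CT16 pulse (delays negative),
  and skeleton-photoperiod rhythm metrics.
* **Densitometry** — relative integrated density (mean gray × ROI area) and
  averaging of 1-D intensity profiles after aligning each section's
  fifth-order-polynomial peak estimate by whole bins.
* **Group statistics** — Shapiro–Wilk/Brown–Forsythe-gated t vs Mann–Whitney
  tests, 2-/3-way ANOVA with Holm–Šidák step-down follow-ups, Pearson
  correlation tables.
* **Simulator** — virtual mice with known τ, onset jitter, masking
  coefficient, re-entrainment rate, phase-response delay, and day/night
  immobility-bout structure, under any protocol (LD, DD, SPP, phase shifts,
  ZT- or CT-timed light pulses, feeding windows), plus synthetic profiles and
  group tables.  Every analysis above is validated by recovering the
  parameters that generated the data.

## Worked example

```python
import circalab as cl

# a wild-type-like virtual mouse: tau 23.6 h, 8-min onset jitter
params = cl.make_params("wt_like", seed=1)
protocol = cl.Protocol([cl.LD(14), cl.DD(14)])
trace = cl.simulate_activity(params, protocol, bin_min=1)

pg = cl.chi2_periodogram(trace, n_days=10, start_day=15)   # free-running days
print(f"tau = {pg.tau_h:.1f} h, rhythmic power = {pg.rhythmic_power:.1f} %V")

onsets = cl.detect_onsets(trace, expected_period_h=23.6)
sub = cl.OnsetSeries(onsets.days[16:26], onsets.onset_min[16:26])
print(f"onset variability = {cl.onset_variability(sub):.1f} min")

immob = cl.simulate_immobility(params, cl.Protocol([cl.LD(2)]))
day = cl.sleep_metrics(cl.score_sleep(immob), window="day")
print(f"day sleep: {day.duration_min:.0f} min in {day.n_bouts:.1f} bouts "
      f"of {day.mean_bout_min:.1f} min")
```

prints

```
tau = 23.6 h, rhythmic power = 85.2 %V
onset variability = 9.6 min
day sleep: 466 min in 14.5 bouts of 31.5 min
```

— the injected period is recovered exactly on the 0.1-h grid, the onset
variability estimate sits near the injected 8-min jitter, and the day-time
sleep of a wild-type-like mouse comes out around 470 of 720 light-phase
minutes in ~15 consolidated bouts.

A whole simulated study (two groups, per-animal metric table, gated group
contrasts) runs from one config:

```bash
circalab run --config study.yaml     # seed, n_per_group, groups, out_dir
```

Subcommands `simulate / sleep / rhythm / photic / densito / stats` expose the
individual stages on CSV files; see `circalab --help`.

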