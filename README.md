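# gpsgait

Outdoor walking-capacity analysis from 1-Hz GPS Doppler speed traces.

People with conditions that limit ambulation — multiple sclerosis,
intermittent claudication — often walk outdoors in an intermittent pattern:
a walking bout, a symptom-forced stop, another bout. Corridor tests such as
the 6-min walking test compress this behaviour into a single number; a
consumer GPS logger worn during a free outdoor session captures the whole
pattern instead. `gpsgait` turns such a session — a GPX 1.1 track with a
per-point Doppler speed channel, sampled at 1 Hz — into validated walking
and stopping bouts and clinically meaningful outcomes: maximal walking
distance (MWD, the greatest single-bout distance before a stop), usual
walking speed, number and duration of stops.

## Method

For a session with raw Doppler speeds ν_i (km/h), the pipeline is:

1. **Calibration** — on a representative window of steady walking (≤ 120 s),
   compute the mean v̄, sample SD σ_v and CV(ν) = 100·σ_v/v̄ of speed.
2. **Spike filter** — every ν_i > 2·v̄ is replaced by the mean of the five
   following epochs.
3. **Zero-threshold filter** — every ν_i < v̄ − K·σ_v is set to 0, with
   K = 2 when CV(ν) ≥ 15 % and K = 5 otherwise: an adaptive separation of
   genuine walking from the low-amplitude jitter a GPS receiver reports at
   rest.
4. **Smoothing actions 1–5** — sequential local passes that re-anchor the
   first epoch of each walking bout and erase one-or-two-epoch spurious
   bouts (isolated zeros inside walking, isolated positive epochs at rest).
5. **Bout detection** — maximal runs of walking (ν > 0) and stopping
   (ν = 0) become bouts; a state shift is validated only by a run lasting at
   least 15 s, shorter runs being absorbed into the open bout
   (`min_bout_s=0` disables the rule for sensitivity analyses).
6. **Outcomes** — per session: duration (first to last walking bout), total
   walking time and distance (distance integrates the Doppler speed, not the
   coordinates), time-weighted mean speed, interior stop count, MWD and the
   bout achieving it, per-bout distance/speed means and CVs, stop-duration
   statistics. A final bout ended by the clock rather than by symptoms can
   be excluded from the capacity outcomes via a per-session flag.
7. **Group statistics** — median [IQR] with 90 % BCa bootstrap CIs
   (999 replicates), exact Clopper–Pearson CIs for proportions, and
   Pearson (Fisher z) / Spearman (BCa bootstrap) correlations against a
   comparator such as the 6-min walking distance.

A synthetic-session generator produces 1-Hz traces with a known bout
schedule, Gaussian walking-speed noise, rest jitter, spikes and dropouts,
plus coordinates advanced along a course polyline — so every stage is
testable end-to-end against ground truth without any field data.

## Worked example

`python examples/simulate_and_detect.py` simulates a noisy session and runs
the full pipeline:

```
simulated 1392 1-Hz epochs, 11 scheduled bouts
calibration: v_bar=2.95 km/h, CV=16.2% -> K=2, zero threshold 1.99 km/h
  stopping     30 s      0.0 m  0.00 km/h  (absorbed runs: 0)
  walking     218 s    180.2 m  2.98 km/h  (absorbed runs: 0)
  stopping     46 s      0.0 m  0.00 km/h  (absorbed runs: 1)
  ...
session: 22.2 min, total walking 722 m at 2.89 km/h, 4 stops, MWD 180 m on bout 1
truth:   total 723 m, MWD 182 m
evaluation: 11/11 bouts detected (100%), distance-error CV 0.62%
```

The calibration line shows the adaptive filter setup (CV ≥ 15 % selects
K = 2, putting the walk/rest threshold at 1.99 km/h); each detected bout
reports its duration, integrated distance and mean speed; the evaluation
line scores detection against the generator's schedule (a true bout counts
as detected when exactly one same-state detected bout overlaps more than
half of it). Other examples: `gpx_roundtrip.py` (GPX I/O and derived speed),
`group_summary.py` (cohort medians, CIs and correlations),
`sensitivity_min_bout.py` (effect of the 15-s rule on mean speed).

## Command line

```
gpsgait analyze  --config run.yaml        # GPX -> processed CSV, bouts, outcomes, logs
gpsgait summarize --outcomes out/outcomes.csv --covariates walk6.csv
gpsgait simulate --spec spec.yaml --out-gpx s.gpx --out-truth s.json
gpsgait evaluate --spec spec.yaml --bouts out/sim_bouts.csv
```

The run configuration lists, per session, the GPX path, the analysis and
calibration windows (seconds from trace start or ISO timestamps), an
optional corrected-altitude CSV and the last-bout-exclusion flag; defaults
are 1-s epochs, 15-s minimum bout, 90 % CIs with 999 replicates.

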