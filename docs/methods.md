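# Methods

## Signal model and processing cascade

A session is a 1-Hz series of Doppler speeds ν_i (km/h) with coordinates.
The Doppler channel is treated as the primary measurement: walking distance
is the time integral of processed speed, never the sum of coordinate
displacements, because positional fixes carry correlated multipath error
while Doppler speed is comparatively well behaved at walking pace.

Calibration computes v̄, σ_v (sample SD, divisor n−1, the default of
mainstream statistical environments) and CV(ν) = 100·σ_v/v̄ over a
user-chosen representative window of steady walking. The window is capped
at 120 s and must contain movement; choosing it is deliberately a manual
input — it encodes a judgement about what "representative" means for a
session — though `suggest_calibration_window` offers a CV-minimising
candidate. That helper is labelled a heuristic: minimising the *sample* CV
over thousands of overlapping windows biases the selected CV low and can
flip K from 2 to 5, so its output should be inspected, not trusted blindly.

The cascade applies seven passes, each a full left-to-right sweep over the
output of the previous pass; within a pass, updates are in place, so later
epochs see already-updated earlier ones. The passes:

1. **Spike filter.** ν_i > 2·v̄ is replaced by the mean of the five
   following epochs' raw values. In a left-to-right sweep the following
   epochs are necessarily unvisited, so "raw" and "current" following
   values coincide; there is one implementation, not a switch. Edge rules:
   fewer than five followers → use all available; a spike at the final
   epoch → last preceding non-spike value (mean v̄ if the entire vector is
   spikes).
2. **Zero-threshold filter.** Values strictly below T = v̄ − K·σ_v become
   0; a value exactly at T survives. K = 2 when CV(ν) ≥ 15 % (boundary
   included), else K = 5. If T ≤ 0 the filter is disabled with a logged
   warning — the calibration window was too noisy to separate walking from
   rest, and silently zeroing nothing is the only honest behaviour.
3–7. **Smoothing actions 1–5.** Action 1 re-anchors the first positive
   epoch after a zero to the mean of its five followers; actions 2–3 fill a
   zero at i when epochs i−2, i−1, i+2, i+3 are all positive (mean of those
   four); actions 4–5 zero a positive epoch whose same four neighbours are
   all zero. Epochs whose neighbour indices fall outside the vector are
   left unchanged — no boundary extrapolation. Action 1 at the final epoch
   is also left unchanged: its trigger guarantees the preceding value is 0,
   so substituting it would fabricate a stop.

One consequence worth stating: under the literal Action-1 rule, an isolated
positive epoch whose five followers are all zero is zeroed by Action 1
itself (its "local mean" is 0). The same epoch would fall to actions 4–5
anyway, so the cascade's outcome is unaffected, but "actions 1–3 only ever
raise values" is not a universal invariant and the tests do not claim it.

## Bout detection

Maximal runs of walking (ν > 0) and stopping (ν = 0) are scanned left to
right. The first run opens a bout regardless of duration (a short leading
rest is expected, since the analysis window starts a few seconds before the
first walking bout). Each subsequent run is absorbed into the open bout if
it is shorter than the minimum bout duration (default 15 s) or has the
bout's own state; otherwise it validates a state shift. A sub-threshold
run at the very end is absorbed symmetrically — no special end rule.
`min_bout_s = 0` reproduces the no-minimum sensitivity analysis exactly
(bouts ≡ runs). Absorbed zero epochs contribute duration but no distance,
so a walking bout's mean speed is diluted by the pauses it absorbed.

Leading and trailing stopping bouts are retained by the detector and
trimmed at the outcome stage, where the session is defined from the first
walking bout's start to the last walking bout's end. Interior stops only
are counted as "stops".

## Outcomes and the last-bout exclusion

The session mean speed is the time-weighted value (total distance over
total walking time); the unweighted mean of per-bout mean speeds is
reported separately, so both readings of "mean speed over the walking
bouts" are available. When a session ends because time ran out rather than
because of symptoms, the final walking bout does not measure capacity: a
per-session boolean excludes it (and the stop immediately before it) from
the capacity outcomes — MWD, per-bout distance/speed statistics,
stop-duration statistics — while session duration, totals and mean speed
keep every bout. The flag is manual by design: whether a bout was
symptom-limited is a human judgement, not something inferable from speed.
CV outcomes are reported only when at least two qualifying bouts (or
stops) exist; they are otherwise absent rather than zero.

## Group statistics

Medians with type-7 quantile IQRs (the R/numpy default, so printed values
match the usual environments); 90 % BCa bootstrap CIs for medians
(999 replicates, jackknife acceleration, seeded generator — bit
reproducible); exact Clopper–Pearson intervals for proportions; Pearson
correlation CIs via Fisher z; Spearman CIs via a seeded BCa bootstrap of
the rank correlation with average ranks (Fisher z on ranks available as an
alternative, since no standard method is canonical for Spearman at n ≈ 10).
Bootstrap resampling is i.i.d. with replacement at the participant level.
A perfectly monotone sample (|ρ| = 1) short-circuits to a degenerate
interval, as every resample reproduces ±1.

## Synthetic sessions

The generator emulates what the cascade exists to remove. Walking epochs
take target × (1 + N(0, cv/100)) floored at 0 (white noise — the real
receiver's error autocorrelation is not modelled, a stated
simplification); rest epochs are U(0, 0.5) km/h, below any plausible
zero-filter threshold for walking at 2–4 km/h, which is precisely why the
threshold filter works; spikes multiply the current value by 3 with
per-epoch probability; dropouts zero a walking epoch. Coordinates advance
along a course polyline at the *clean* speed (equirectangular local frame
re-expressed as WGS84 lat/lon), cycling the course when exhausted; the
default course is a 200 × 100 m loop with four 90° corners and a ≈170°
hairpin, the turn geometry known to depress real walking speeds. The
generator does not model satellite geometry, multipath, altitude effects
or gradual speed ramps at bout transitions — so passing tests demonstrate
the pipeline's logic under the stated noise model, not its behaviour on
every real-world trace.

Evaluation matches each true bout (duration ≥ min_bout_s; shorter true
bouts are unmatchable by construction and leave the denominator) to
detected bouts of the same state; a true bout counts as detected when
exactly one such bout overlaps more than 50 % of its duration. The
detection rate pools matches over sessions; the distance-error CV is the
sample SD of per-matched-walking-bout relative distance errors in percent.

## Benchmark conditions

The validation benchmark simulates 200 sessions with 5–10 walking bouts of
30–300 s alternating with 30–180 s stops, framed by 30-s rests. Each
session draws a base speed U(2, 4) km/h; per-bout targets vary around it
with a 6 % CV, matching the within-session bout-speed stability observed
in ambulatory patient cohorts (median per-bout speed CV ≈ 6 %) — sessions
whose bouts jump independently across the full 2–4 km/h range would
contradict the single-calibration-window design the filters assume.
Walking noise CV is 15 %, spikes ×3 at p = 0.01, dropouts at p = 0.005.
The calibration window is the first 120 s of the first walking bout
lasting ≥ 120 s (from the generator schedule), standing in for the manual
representative-window choice. Session i uses seed base·100000 + i, so one
base seed reproduces the whole benchmark. At these sizes the benchmark
runs in a few seconds on one CPU.

## Numerical notes

- Haversine distances use a 6 371 000 m spherical Earth; derived speed at
  the first fix is 0 by convention.
- Gap filling in `canonicalize` is linear and capped at 2 s by default
  (>99 % of real epochs are 1 s, so longer holes are declared, logged
  gaps, never fabricated data). The operation is idempotent.
- GPX output writes coordinates to 6 decimal places and speed (m/s) to 6,
  making read→write→read a fixed point to the documented precision.
- The extension speed unit defaults to m/s (the common GPX dialect) with
  km/h and a magnitude-heuristic auto mode available.
- Degenerate inputs fail loudly: empty window selections, calibration
  windows without movement or longer than 120 s, sessions with no walking,
  zero-variance correlation inputs all raise with specific messages;
  all-stop sessions become error rows in batch output rather than
  vanishing.
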