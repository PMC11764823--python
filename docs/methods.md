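# Methods

## Pipeline model and assumptions

The pipeline assumes a wrist-worn triaxial accelerometer reporting in
milli-G at a nominal 5 Hz, with gravity dominating the static signal
(rest pose reads a vector of magnitude 1000 milli-G). Tilt is recovered
from the gravity projection as `pitch = atan2(y, sqrt(x² + z²))` and
`roll = atan2(−x, z)`; with the second pitch argument nonnegative,
pitch lies in [−π/2, π/2] and roll in (−π, π]. `G` is fixed at exactly
1000 milli-G — no site-specific gravity correction. The total-energy
channel keeps the absolute value inside the square root,
`sqrt(|power² − G²|)`, so sub-1G magnitudes (transient free-fall phases
of a gesture) yield a positive energy rather than an error. Per-axis
gravity removal by high-pass filtering is deliberately out of scope;
the derived channels are used instead.

An all-zero sample (physically impossible for a gravity-loaded sensor)
maps to pitch = roll = 0 by convention and is counted in a warning
rather than failing the stream: one corrupt sample should not poison a
whole recording.

## Clock synchronization

The watches and the camera cannot synchronize electronically, so each
food-item segment opens with a single hand clap. Detection runs on the
power channel (orientation-invariant): the clap is the global maximum
within a search window, required to exceed the window median by a
prominence (default 1000 milli-G on the watch side; 0.5 on the
unit-normalized audio envelope), ties breaking to the earliest index
(the leading edge). Offsets are estimated *per segment* — one clap per
food item — rather than per meal; per-meal pooling can be layered on
top by averaging the exported offsets table. The audio search window
spans ±5.5 s around the segment start, which resolves offsets up to
about 5 s unambiguously provided segments last at least ~11 s; clock
drift within a meal is not modeled.

## Labels and Information Units

Evaluator intervals are half-open `[start, stop)` on the accelerometer
clock after subtracting the segment's offset; a sample is eating iff
its timestamp falls inside an interval, which avoids double-counting
shared boundaries. United = OR of the two evaluators, intersected =
AND; intersected therefore implies united at every sample, and the same
inclusion is inherited by IU labels at every window width.

Windows step by 1 s (5 samples) and never cross a food-item segment,
so each IU has a single food label. The only per-window summary is the
closed-form OLS slope of each kinetic variable against time (units per
second). Full-source IUs concatenate the dominant wrist's 7 slopes with
the non-dominant wrist's 7 (dominant first, fixed variable order), one
IU per time window; a window with any missing or corrupt sample would
be dropped and logged. The eating rule is a strict majority: exactly
50% does not label an IU eating.

## Classification

Only eating IUs (under the active criterion) are classified, with the
segment's food item as a 13-class target; non-eating IUs take no part.
Forests grow 500 trees (tests and the acceptance script use 40–200 to
keep desk-scale runtimes short) to purity with minimum leaf size 1 and
no class weighting. `mtry` is searched over the full range 1..p by
stratified k-fold CV (default 5 folds, reduced with a warning when the
rarest class has fewer members); global validation accuracy is pooled
over folds and ties break toward the smallest candidate. The final
forest is refit on all eating IUs with the chosen `mtry` — the
alternative of assembling the CV-fold forests is not used.

OOB evaluation reconstructs each tree's bootstrap draw and takes the
majority vote among trees for which the IU was out-of-bag; argmax ties
break toward the lowest food id. A unit test cross-checks the vote
tallies against scikit-learn's independently computed
`oob_decision_function_`. Raw variable importance is the mean over
trees of the un-normalized Gini impurity decrease per feature; min-max
scaling maps it to 0–100, with the degenerate all-equal case reported
as all-100 plus a warning, and a single feature assigned 100 by
convention.

## Synthetic data generator

The generator reproduces the *shape* of the study — 20 subjects evenly
randomized to menus A/B, four meals and 7 food segments per subject,
13 foods with yogurt in both menus, two wrists at 5 Hz, a clap spike
(3000 milli-G, decaying over 2 samples) at each segment start mirrored
as a unit peak in a 25 FPS audio envelope, and two evaluators whose
interval endpoints carry zero-mean Gaussian jitter (default SD 0.3 s).
Default segment length is 60 s per food item, a desk-scale stand-in
for the original recordings.

Gesture dynamics are free parameters organized around one
`effect_size` dial. Every food deviates from a common baseline by
`spread × effect_size × coefficient`, where the coefficients come from
balanced modular rankings (one coprime multiplier per parameter over
the 13 ids), so any two foods differ along several parameters at once
and at effect 0 all foods are kinetically identical. Baselines
(spreads): bite period 11 s (0.75), bite duration 7 s (0.5), pitch
amplitude 0.45 rad (0.20), roll amplitude 0.35 rad (0.15), burst 200
milli-G (80), noise SD 30 milli-G (10), apex fraction 0.5 (0.15),
burst azimuth 0 rad (0.45). A complete eating movement is deliberately
longer than the widest (5 s) window so that windows inside one
movement see a monotone limb of the triangular orientation waveform —
slope features then carry nearly deterministic food-specific rise/fall
rates, which is what makes the default study separable. The waveform's
apex fraction and the burst's azimuth in the device frame give foods
signatures in the *pattern* of the seven slopes, not only their scale.

The accelerometer model is the gravity vector rotated by the
instantaneous (pitch, roll) — axis convention chosen so the kinetics
formulas invert it exactly — plus a nonnegative half-sine
linear-acceleration burst during each bite and i.i.d. Gaussian noise.
The non-dominant wrist scales the gesture by 1 for two-handed foods
(taglierini, mozzarella, meatballs, sandwich, stracchino) and by
`max(0, 1 − effect_size)` otherwise, so the two-handed flag cannot
leak class information at effect 0 while one-handed foods' non-dominant
wrists are pure baseline at the default effect size 2.

What the generator does *not* emulate: chewing micro-movements,
utensil physics, posture drift, autocorrelated sensor noise, clock
drift, annotator disagreement beyond boundary jitter, or any
food-specific dynamics measured from real data. Passing tests
therefore demonstrate that the pipeline recovers structure the
simulator encodes — they say nothing quantitative about performance on
real recordings, and per-food headline numbers from real studies are
explicitly not comparison targets.

All randomness descends from one explicit seed through keyed
`numpy.random.SeedSequence` children, making every artifact
bit-reproducible; forest and CV seeds are reduced modulo 2³¹ − 1.

## Numerical choices and degenerate inputs

Window slopes use the centered closed form
`Σ(tᵢ−t̄)(vᵢ−v̄) / Σ(tᵢ−t̄)²` as a dot product with precomputed
weights; constant windows give exactly 0 and sub-2-sample windows are
rejected. Importance scaling computes the ratio before multiplying by
100 so the maximum is exactly 100. Segments shorter than the window
yield zero windows rather than an error; a meal where an evaluator
marked nothing rasterizes to an all-false track. CSV round-trips use
pandas' `round_trip` float parsing so serialized studies reproduce
byte-identical downstream results.

## Problem sizes

Desk-scale defaults keep the full pipeline fast while preserving the
study's structure: the default synthetic study is 20 subjects × 7
segments × 60 s × 2 wrists at 5 Hz (84 000 raw samples, ~7800
five-second IUs); the recovery analyses in the test suite and
acceptance script use 200-tree forests, and the 20-cell grid
determinism check runs 3 subjects at 20 s per item with 40-tree
forests. These sizes are the package's validation conditions, chosen
to keep iteration cheap; all of them are parameters, and full-scale
runs only change `n_subjects`, `duration_per_item_s` and `n_trees`.

## Known limitations

- Slope-only features discard within-window magnitude information by
  design; phase-symmetric gestures would be nearly unclassifiable.
- Per-segment offsets assume one clean clap per segment; a missed clap
  raises rather than falling back to neighboring segments.
- The audio search half-width (5.5 s) bounds recoverable offsets and
  requires segments of at least ~11 s to be unambiguous.
- Class imbalance (yogurt appears in both menus) is left unadjusted,
  exactly as in the modeled design; chance-level accuracy is therefore
  slightly above 1/13 (Σpₖ² ≈ 0.082).
- FIT binary ingestion is not implemented; the pipeline consumes the
  CSV dialect documented in `kineat.pipeline`.
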