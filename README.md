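# shoalkit

Trajectory analytics for collective motion in small fish schools, with the
predator-response, visual-performance and brain-allometry analyses that
typically accompany schooling-selection experiments on guppies — plus a
synthetic-data layer (an agent-based schooling simulator, a virtual
optomotor fish and a brain-volume generator) that makes every stage of the
pipeline testable without video recordings.

It is written for behavioural ecologists working with multi-animal tracker
output (idTracker-style `frame, fish, x, y` tables) from groups of ~8 fish
in a circular arena, scored behavioural event tables, drum-arena optomotor
tracks, and region-level brain volumetry.

## What it computes

**Collective motion.** Per-fish velocities are first differences of the x
and y position series smoothed with a third-order Savitzky–Golay filter
(11 frames at 25 Hz by default). Group polarization in a frame is the
directional order parameter

&nbsp;&nbsp;&nbsp;&nbsp;R = ‖(1/N) Σᵢ uᵢ‖ ∈ [0, 1],

the norm of the mean unit heading vector over the N fish with a defined
heading; it is computed only when at least 6 of the 8 group members
contribute. Per-trial summaries are medians (per fish first, then across
the group) of polarization, speed (mm/frame) and nearest-neighbour
distance, and a trial is retained only when ≥ 70% of its frames pass the
6-of-8 tracking rule.

**Spatial structure.** Polarization heatmaps over 20 × 20 mm grid cells of
the group centroid, restricted to frames where ≥ 6 fish form a connected
group (graph connectivity at a 100 mm link distance) and suppressing cells
supported by fewer than 8 distinct groups; per-trial occupancy density
maps; zone statistics near a centred stimulus (< 200 mm) and on the
head (y > 0) / tail (y < 0) sides of a predator model.

**Predator inspections.** Scored event tables (first 3 min after predator
introduction) become counts, total time and mean duration, and can be
joined back to frame metrics (distance to stimulus, polarization during
the event).

**Optomotor performance.** Single-fish drum-arena tracks are scored
against a 40-segment stimulus program (4 speeds × 2 directions × 5
repetitions × 23 s): relative orientation arcsin(sin(θ − ϑ)) with
clockwise positive, signed angular speed in deg/s, per-segment
direction-following proportions and speed deviations, plus visual-acuity
score aggregation.

**Brain allometry.** Per-region log-log models of region volume against
the rest of the brain (whole brain minus the region), selection regime as
fixed effect and a random intercept per replicate selection line; contrasts
reported as volume ratios / percent differences; region-by-region residual
correlations.

**Line-versus-control inference.** Mixed models with replicate-line random
intercepts (Satterthwaite-style degrees of freedom), Poisson GEE
incidence-rate ratios for counts, a replicate-line permutation test, and
Tukey-adjusted post-hoc contrasts.

## Worked example

```python
import pandas as pd
import shoalkit as sk

# simulate a two-regime cohort: 3 replicate lines x 14 trials per regime,
# polarization-selected lines get higher alignment and speed
cfg = sk.SchoolSimConfig(duration_s=15)
cohort = sk.simulate_line_cohort(cfg, "open_field", trials_per_line=14, seed=0)
df = pd.DataFrame([vars(sk.summarize_trial(t, window_s=15)) for t in cohort])
print(df.groupby("line")[["median_polarization", "median_speed"]].mean().round(3))

mixed = sk.compare_lines(df, "median_polarization")
perm = sk.line_permutation_test(df, "median_polarization", seed=0)
print(f"mixed-model contrast {mixed.estimate:.3f} "
      f"[{mixed.ci_low:.3f}, {mixed.ci_high:.3f}], p={mixed.pvalue:.4f}")
print(f"line-permutation p={perm.pvalue:.3f}")
```

prints

```
              median_polarization  median_speed
line
control                     0.661         2.257
polarization                0.774         2.476
mixed-model contrast 0.113 [0.103, 0.122], p=0.0000
line-permutation p=0.100
```

The polarization-selected regime is ~0.11 more polarized and ~0.22
mm/frame faster, matching the generator's configured line offsets; the
mixed model recovers the contrast with a tight interval, while the exact
3-vs-3 line permutation test bottoms out at its smallest attainable
two-sided p of 2/20 = 0.1 — the honest price of having six replicate
lines.

The same stages are available from a shell:

```bash
shoalkit simulate school -o trials/ --n-trials 4 --duration 60 --seed 1
shoalkit metrics trials/ -o summaries.csv
shoalkit compare summaries.csv --response median_polarization
```

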