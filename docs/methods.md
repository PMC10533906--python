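# Methods

This note records the models, conventions and numerical choices behind
shoalkit, in the order data flows through the pipeline.

## Coordinates, units and missingness

All positions are in millimetres with the origin at the center of the
circular test arena (radius 275 mm for the 55 cm arena; 250 mm for the
50 cm drum arena). When a stimulus is present it sits at the center with
the predator-model head toward positive y and the tail toward negative y;
every zone rule downstream depends on this single convention. Speeds are
mm/frame internally (25 Hz sampling), converted to mm/s only for
reporting.

Missing detections are NaN, never sentinel coordinates. This matters
because the quality-control rules are defined over missingness: a fish is
*tracked* in a frame when its smoothed velocity is defined there, a frame
*passes* when at least 6 of the 8 fish are tracked, and a trial is
*retained* when at least 70% of its frames pass (boundary inclusive).
Whether the published completeness rule counted frames with all 8 or ≥ 6
fish is not stated anywhere we know of; we adopt the ≥ 6 reading so that
the same gate governs completeness and per-frame statistics. Positions
within 2% of the radius beyond the wall are treated as tracking jitter
(warned about and marked missing on ingest); anything farther is a hard
validation error.

## Kinematics

Velocities are the Savitzky–Golay first derivative (order 3) of the x and
y series per fish, applied only to contiguous non-missing runs and only
where the window is fully supported — no interpolation across gaps, so an
11-frame window discards 5 frames at each run edge. The window length is
not fixed by any published protocol we reproduce; 11 frames (0.44 s)
suppresses tracker jitter without flattening the burst-and-glide speed
profile of guppies, and it is configurable.

Headings are directions of smoothed velocities; below 0.1 mm/frame
(2.5 mm/s) the direction of motion is noise-dominated and the fish
contributes no heading. This threshold protects the polarization of
freezing groups from being set by tracker noise.

Group polarization per frame is the standard directional order parameter
R = ‖mean unit heading vector‖. Note the finite-size floor: for 8
independent random headings E[R] = 0.886/√8 ≈ 0.31, so "disordered"
groups score ~0.3, not 0. The per-trial value is the median of per-frame
values; per-trial speed and nearest-neighbour distance are per-fish
medians first, then the median across fish. Open-field trials are
summarised over their first 6 min so they compare evenly with stimulus
assays.

## Spatial maps and zones

Grid cells are 20 × 20 mm, half-open ([x₀, x₀+20)), anchored at the arena
center. Heatmaps of polarization by centroid location use only frames in
which ≥ 6 fish form a connected group (pairwise link distance 100 mm);
connectivity is computed for all frames at once by boolean squaring of
the adjacency matrix (three squarings reach path length 8). Aggregation
averages within each group first and then across groups per cell, so each
group contributes once to the support count, and cells with fewer than 8
supporting groups are suppressed — the group, not the frame, is the unit
of evidence. Density maps are per-trial occupancy distributions over
individual fish positions (nonnegative, sum exactly 1).

Zone statistics evaluate the group centroid: *near stimulus* is a
center distance < 200 mm (the stimulus is centred and its 18 × 3 cm
extent is not modelled as a polygon); *head* is y > 0 and *tail* y ≤ 0,
with the measure-zero y = 0 case assigned to the tail for determinism.

## Predator inspections

The pipeline consumes manually scored event tables (one randomly chosen
focal fish per trial, first 180 s after predator introduction); it does
not attempt to recognise inspection postures from trajectories. Events
are half-open [start, end) so contiguous events never double-count time;
events crossing the 3 min boundary are truncated at the window (with a
warning), which keeps total time ≤ 180 s by construction.

## Optomotor scoring

Angles use a compass convention (measured clockwise from +y), chosen so
that the published sign statement — clockwise circulation positive — holds
literally for both relative orientation arcsin(sin(θ − ϑ)) and angular
speed. The angular-speed magnitude comes from the dot product of
consecutive position vectors, but the sign comes from their cross
product: an unsigned angle cannot distinguish the two stimulus
directions, so the signed version is a deliberate strengthening. Frames
with position radius ≤ 10 mm are excluded (polar angle unstable at the
center).

The standard schedule is 300 s acclimation, then 8 speed × direction
combinations × 5 repetitions × 23 s with 3 s speed ramps between
presentations (920 s scored). Presentation order was randomised once and
held constant for all fish; a fixed-seed shuffle plays that role here.
Transitions are excluded from scoring (stimulus speed is ill-defined
mid-ramp), and a frame is scored only when its *preceding inter-frame
step* lies entirely inside the segment, so boundary steps never leak
transition motion — this is what makes a perfect virtual follower score
exactly 1.0 / 0.0. "Swimming with the stimulus" is sign agreement of
relative orientation with the stimulus direction (no magnitude
threshold by default; one is configurable, and displacement-sign scoring
is available as an option). Acuity scores are time-fraction aggregates
of manually scored following intervals per 60 s presentation, with the
static-control activity proportion carried as a covariate, never
subtracted.

## Brain allometry

Models are linear on the log scale: log region volume against log
rest-of-brain volume (whole brain minus the region of interest), regime
as fixed effect, random intercept per replicate selection line; the whole
brain is modelled against log standard length. The log scale makes the
regime contrast a volume ratio (reported as a percent difference) and
renders everything scale-equivariant. The published per-region contrasts
were reported as "odds ratios" — an unusual scale for volumes — and we
read them as multiplicative volume ratios.

Two estimators are provided: the mixed model (REML) and a fixed-effects
fallback with the within-regime replicate index as crossed dummies.
The fallback codes replicate as crossed rather than nested because
per-line dummies would absorb the regime contrast entirely. Residual
correlations between regions — our frequentist approximation of a fully
multivariate Bayesian model with an LKJ correlation prior, an
approximation and not a reproduction — remove one intercept per replicate
line plus the rest-of-brain slope and correlate what is left. A caveat
discovered while validating: because each region's noise appears inside
every other region's rest-of-brain covariate, truly independent regions
show induced negative correlations up to ≈ −0.3 between the largest
regions whenever the whole brain varies; "independent" test fixtures
therefore hold the whole-brain volume fixed.

## Line-versus-control inference

Replicate selection lines are the units of independent evolution, and
trials within a line are pseudo-replicates, so all inference clusters on
the line. The mixed model refers the regime contrast to a t distribution
on Welch–Satterthwaite effective degrees of freedom combining the
between-line (n_lines − 2) and residual components according to the
estimated variance shares; with 3 lines per regime a plain normal
reference overstates certainty badly, while a fixed between-line df is
far too conservative when line variance is negligible. Count responses
(inspection tallies) use a Poisson GEE with exchangeable within-line
correlation, reported as incidence-rate ratios; a dispersion diagnostic
accompanies the fit in place of a genpois family.

The permutation test reassigns whole replicate-line labels between
regimes and compares differences of line means: exact enumeration up to
1000 assignments, otherwise Monte-Carlo with the add-one rule. With 3
lines per regime the two-sided statistic pairs every assignment with its
mirror image, so the smallest attainable p is 2/20 = 0.1 — a structural
limit of the design, reported as such. Post-hoc contrasts across stimulus
levels use Tukey's studentised-range adjustment on the regime × level
crossing.

## The synthetic-data layer

`simulate_school` is a zonal (repulsion / alignment / attraction)
agent-based model: 8 fish, 25 Hz Euler steps of one frame, heading chosen
by a weighted sum of neighbour repulsion (within 25 mm), alignment to
neighbour headings (within 150 mm), attraction to the neighbour centroid,
heading persistence and wrapped-normal noise; speed relaxes toward a
preferred value. The zonal family was chosen over a plain alignment model
because it lets speed, cohesion and polarization be manipulated
independently — the three response variables of the analyses. Defaults:
preferred speed 3.0 mm/frame (~3 body lengths/s for a 25 mm female),
alignment weight 0.8 with heading noise 0.9 rad — a control-line group
medians ~0.65 polarization — and polarization-line offsets of +0.4
alignment and +0.25 mm/frame speed, giving a ~0.1 polarization contrast
comparable to a few generations of directional selection. Stimulus
treatments add center avoidance, speed slowdown (×0.45 novel object,
×0.3 predator) and exponential freezing bouts (predator: 0.08/s, mean
2.5 s), with extra avoidance on the head (y > 0) side of the predator.
Walls reflect the heading about the tangent with a small inward bias,
which keeps density maps free of boundary pile-up. The whole stepper is
vectorised over a batch of trials, so an 84-trial cohort costs well under
a second.

What the simulator emulates: treatment-graded slowing, freezing and
avoidance; line-structured alignment and speed differences; tracker-style
contiguous track loss (a two-state Markov chain per fish with a target
stationary missing fraction). What it does not: burst-and-glide speed
profiles, body shape and occlusion-driven identity swaps, hydrodynamics,
3-D motion, or any calibration to reproduce published effect magnitudes.
Passing tests therefore demonstrate that the pipeline recovers what a
generator of this structure puts in — not that real guppies behave like
the generator.

`simulate_optomotor_fish` orbits at fixed radius with angular speed
gain × stimulus speed (lagged, noised). `simulate_brain_volumes` builds
region volumes independently (log-normal around species-plausible shares
of an ~8 mm³ brain, allometric slope 2.0 on standard length, per-line
replicate intercepts), with the whole brain as the region sum plus an
unparcellated 8% remainder — so applying a regional effect ratio leaves
that region's rest-of-brain covariate untouched and noiseless recovery is
exact. Summary-level generators (`simulate_trial_summaries`,
`simulate_inspection_counts`) produce cohorts directly at the
trial-summary scale for calibrating the statistics layer, where running
the agent-based model hundreds of times would add cost but no
information about the inferential procedures under test.

## Problem sizes and determinism

Verification uses 15 s trials (375 frames), cohorts of 3 replicate lines
× 14 trials per regime (42 per arm), 100-run sign-recovery and 200-run
type-I calibrations, and n = 200 brain tables; these sizes put
Monte-Carlo error well below the effects being checked while keeping the
full suite fast on a single CPU. Every stochastic component takes an
explicit seed (numpy `default_rng`) and is bit-reproducible given it; the
acceptance script derives all of its seeds from a single `--seed`
argument.

## Known limitations

- The 6-of-8 gate applies to *headings* for polarization, so a tracked
  but fully frozen group contributes no polarization frames.
- GEE robust standard errors with 6 clusters are anti-conservative; the
  t(n_lines − 2) reference softens but does not fix this. The permutation
  path is the design-robust alternative.
- The Tukey post-hoc layer pools variance across the regime × level
  crossing and ignores the replicate-line clustering; it is a screening
  tool, not the primary inference.
- The residual-correlation approximation shares none of the shrinkage of
  the Bayesian multivariate model it stands in for; with 28 fish its
  off-diagonals are noisy (sd ≈ 0.2).
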