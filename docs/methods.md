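# Methods

This note documents the models, formulas, parameter choices and known
limitations behind `larvascreen`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Assay model

The session is 3 h at one frame per 6 s (1800 frames), split into 18
contiguous 10-minute periods: 1–6 no stimulus, 7–14 moving lines
(7–8 red/normal, 9–10 green/normal, 11–12 blue/normal, 13–14 red/fast),
15 no stimulus, 16–18 acoustic. Line motion is horizontal by default
and alternates 0°/180° between consecutive line periods; the absolute
direction is a convention, not a measurement, and is configurable. The
acoustic block defaults to inter-stimulus intervals of (20 s, 1 s,
20 s) so that habituation can be read as the first-versus-last response
to the sparse stimulus; the order is configurable.

All coordinates are mm in a y-up frame ("up" points away from the
bottom of the image); files in the image-native y-down convention
(the DeepLabCut-style wide dialect) are flipped on read. This fixes
"upward orientation" unambiguously. The 96-well plate uses the nominal
9 mm pitch and a 3.2 mm well radius.

## From pose to behavior

Per frame, the larva's position is the midpoint of the two eyes and its
heading the direction from the yolk sac to that midpoint. Frames where
any body point has likelihood < 0.50 are invalid and excluded from
every aggregate; displacements and heading changes are defined only
between adjacent valid frames, so degrading any set of frames never
changes quantities computed from the remaining ones.

Displacement per 6-s transition is classed rest (< 0.15 mm), scoot
(0.15–1 mm) or burst (≥ 1 mm). The cut-offs are design choices scaled
to the well: a typical well crossing is a burst; both are configurable.
Activity is the percentage of transitions classed scoot or burst.

Per period we record: activity%, scoot%, burst%, edge% (fraction of
frames with radial position > 0.67 of the well radius), clockwise%
(sign of cross(center→position, heading) negative in the y-up frame;
frames with zero cross product are excluded from the denominator so
that clockwise% + counterclockwise% = 100 exactly and mirror symmetry
holds exactly), optomotor% (heading within ±45° of the line motion
direction; line periods only), up% (heading within ±45° of 90°), and
the mean signed and mean absolute heading change. A period with fewer
than 50% valid frames is missing. The ±45° cones and the 0.67 edge
fraction are conventions, exposed as parameters.

The 25-behavior vector combines period summaries: activity over periods
1–6 and over period 15; habituation = activity(first 20-s-interval
acoustic period) − activity(last one); startle = activity(first
20-s-interval period) − activity(period 15); excitability =
activity(1-s-interval period) − activity(period 15); optomotor and
upward orientation per line color/speed, with the combined measures
averaging red, green and blue (excluding fast red); scoot/burst/edge/
clockwise over periods 1–6 and over all line periods; signed and
absolute turn angle over periods 1–6. The acoustic contrasts are the
simplest activity differences consistent with the reference compound's
described signature; all three are strategy hooks that can be swapped.
A behavior whose component periods are all missing is missing, never
zero. Larvae moving in fewer than 1% of transitions over the whole
session are excluded.

## Profiles and scaling

Per-compound vectors are unweighted means over non-missing larvae
(48 larvae per compound in the screen design this mirrors). Profiles
subtract the batch-matched DMSO mean (global DMSO mean when no batch
IDs exist); egg-water controls enter QC reporting only. Profiles are
location-invariant by construction.

Because the 25 behaviors mix percentage points and degrees, profiles
are z-scored per behavior (sample SD, n−1) before clustering by
default; a flag disables this, and the option sweep runs both ways
because external profile tables may have been clustered on raw
differences. Zero-variance columns map to 0 with a warning and invert
exactly. Missing cells are mean-imputed (0 after z-scoring) for
distance computations only; statistics always use raw data.

## Clustering

K-means runs on the top-2 PCA embedding (sign fixed so each component's
largest-magnitude loading is positive), Lloyd iterations from
k-means++ starts, best of 50 restarts. k is chosen by an automated
elbow: the k maximizing the second difference of **log** inertia over
k = 1..10. On a log scale the elbow is the last large *relative* drop,
which is what the eye picks out on an inertia plot; the second
difference of raw inertia is dominated by the k = 2 drop for most
multi-cluster geometries and fails to find four well-separated planted
blobs, which the log form recovers. A curve whose maximum curvature
does not clearly exceed the featureless-decay baseline
log(k²/(k²−1)) is flagged as having no pronounced elbow. k can always
be overridden (`--k 4`).

Hierarchical clustering is complete-linkage agglomeration on Euclidean
distances over the full (scaled) matrix; merge heights equal the
maximum pairwise distance between merged groups and are verified in
tests against a naive O(n³) agglomeration. The reference cluster is the
tree cut into the same k as K-means (a height threshold is available),
taking the reference compound's group.

The cluster report gives both member sets, their intersection and
union, and two correlation summaries computed on the raw (unscaled)
profiles: the mean of all pairwise Pearson correlations among members
including the reference (the headline statistic), and the mean
correlation to the reference alone — either reading of "the cluster's
correlation value" is defensible, so both are reported. A harness
(`sweep_cluster_options`) reruns the pipeline over the documented
option grid (scaling on/off × correlation definition) for matching
externally reported cluster numbers when a real profile table is
available.

## Screen statistics

Welch's unequal-variance t-test per (compound, behavior) against DMSO
larvae (batch-matched, pooled as fallback), two-sided p-values from the
t distribution with Welch–Satterthwaite degrees of freedom. The
Bonferroni divisor is the number of compounds m, not compounds ×
behaviors, matching the screen convention; with m = 876 the tiers are
5.7×10⁻⁵, 1.1×10⁻⁵ and 1.1×10⁻⁶ (2 significant figures). Tiers are
monotone in p by construction. Larvae are the replication unit.

## Synthetic screen generator

Trajectories are a stimulus-modulated correlated random walk — the
simplest generative process exposing all 25 measures; it makes no claim
of biological fidelity. Per 6-s transition the larva:

1. re-orients: heading mixes with attractors toward the line-motion
   direction (weight `omr_gain`, line periods) and "up" (`up_gain`),
   with Gaussian angular noise scaled by
   `heading_noise_deg × (1 − heading_persistence)`; attractor weights
   summing to ≥ 1 saturate alignment (noise-free, `omr_gain = 1` gives
   100% optomotor alignment);
2. moves with probability `p_move`, plus `excitability_gain` during
   acoustic periods, plus a startle term
   `startle_gain × (1 − habituation_rate)^(stimuli already delivered)`
   during sparse (20-s interval) acoustic periods;
3. if moving, displaces `scoot_mm` or (with probability
   `p_burst_given_move`) `burst_mm`, jittered ±30%, along its heading,
   with an outward radial bias proportional to `thigmotaxis`; a step
   that would exit the well bounces by reversing its radial component
   (preserving step length), with a fold-back across the rim as a
   safety net — so movement classes, and hence activity = `p_move`,
   are preserved in closed form.

Body points sit 0.15 mm either side of the position (eyes) and 0.5 mm
behind it (yolk); likelihoods are uniform on [0.9, 1] with a 2%
corruption rate pushing points below the QC threshold.

Baseline (DMSO) parameters — `p_move` 0.30, scoot 0.5 mm, burst 2.0 mm,
burst share 0.30, persistence 0.5, `omr_gain` 0.40, `up_gain` 0.25,
thigmotaxis 0.40, startle 0.25, habituation 0.005 per stimulus,
excitability 0.10, heading noise 60° — were chosen so that the
baseline walk expresses every measure away from its floor or ceiling
(in particular, a real upward-orientation signal exists for an
archetype to reduce: a very weak attractor saturates at the 25% uniform
floor and cannot decrease). Drug archetypes are additive offsets,
clipped into range: the reference-like archetype raises activity,
scoot share and excitability and lowers startle, habituation and both
orientation gains (partly via extra heading noise); `sedative` and
`stimulant` complete a 4-archetype palette.

The fast profile-level generator draws compound rows as archetype mean
vectors (in percentage points, matching the reference-like signature's
directions) plus independent Gaussian noise (default SD 3 per
behavior), planting a designated reference row. Minimum inter-archetype
separation is ≈ 13× the within-cluster SD, comfortably above the 4×
regime where both clustering methods recover the planted partition.

What the generator does **not** emulate: inter-larva variability
structure (real larvae are heterogeneous beyond parameter noise),
correlated measurement error, mortality, plate-position effects, and
any correlation between behaviors beyond what the walk induces. Passing
tests therefore demonstrate that the analysis recovers structure the
generator plants, not that it would recover the same numbers from a
real screen.

## Numerical and problem-size choices

- K-means/PCA use scikit-learn, hierarchical linkage scipy; both are
  cross-checked in tests against independent oracles (exhaustive
  2-partitions for K-means at n ≤ 8; a naive O(n³) agglomeration for
  linkage heights at n ≤ 12).
- Pose CSV values are printed at 6 decimals; round-tripping is
  bit-exact after one quantization. Files are UTF-8, comma-separated.
- The isotropic-cloud PCA check uses n = 5000 rows: for p = 25
  dimensions the top sample eigenvalue exceeds its population value by
  a factor ≈ (1 + √(p/n))², so n = 500 would violate a 20% relative
  band for reasons unrelated to the implementation.
- Planted-recovery tests run 100 replicate 876×25 matrices;
  trajectory-level end-to-end checks use 10 replicates of 3
  reference-like compounds × 8 larvae against 24 controls, and the
  null screen uses 25 replicate screens of 200 compounds × 48 larvae —
  sizes chosen to keep Monte-Carlo error well below the asserted
  margins while the whole suite stays fast.
- Degenerate inputs: single-row matrices, rank-deficient PCA input,
  all-missing behaviors, empty member sets and zero-variance columns
  raise typed errors or produce explicit missing values; they are never
  silently coerced.

## Known limitations

- The acoustic contrasts (habituation, startle, excitability) are one
  defensible definition among several; alternative baselines (periods
  1–6 instead of period 15) would change magnitudes, not directions.
- The optomotor measure is orientation-based; a positional-drift
  definition is noted as an alternative but not implemented.
- The hierarchical cluster boundary (cut at the K-means k) is a
  convention; a height threshold is available and both are reported.
- One larva per well is assumed; multi-larva disambiguation and
  sub-6-s events are out of scope.
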