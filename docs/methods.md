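# Methods

## Coordinate normalization and gap repair

Tracking tables arrive as FIMtrack-style CSV (one row per larva and
frame, pixel units, configurable column names). Fragmented tracks of
one larva are stitched by frame index; frames covered by no fragment
are missing. Coordinates are converted to millimetres relative to the
configured arena center (default scale 0.2673 mm/px, 2 frames/s,
arena radius 30 mm) and the radial distance is the Euclidean distance
to that center.

Each maximal run of missing frames receives exactly one repair class,
decided in priority order:

1. **end_hold** — no observation after the gap: the last tracked
   coordinate is repeated. Checked first because a terminal gap has no
   closing flank.
2. **container_contact** — both flanking positions within the
   container-proximity radius (default 8 mm, the center-zone radius)
   while the container is in the arena: the larva is hidden at the
   container, so the entry position is held.
3. **arc** — both flanking radii beyond 21.3 mm: the larva was
   wall-following, and the gap is filled along a circular path.
4. **edge_assigned** — both flanking frames carry the visually
   verified wall flag: the frames contribute dwell time to the edge
   zone at the nominal edge-zone midpoint radius (27 mm) but have no
   x/y position and contribute no path length.
5. **linear** — evenly spaced points on the straight segment.

Arc geometry: the *minor* (shorter) angular path is used — the
minimal-length completion consistent with wall-following — with the
radius blended linearly between the flanking radii (flanks near the
wall have nearly equal radii, so the blend choice is low-impact).
Near-antipodal flanks (within 1e-9 rad of 180°) fall back to a straight
line with a logged warning, avoiding an arbitrary direction choice.
The 21.3 mm wall criterion is applied to *both* flanks; a gap with only
one wall flank is linear.

## Phase segmentation and metrics

The four phases come from the manually recorded event log: baseline
[t₀, container placed), pre-search [placed, first contact),
investigation [contact, removed; 60 s), and the analyzed search window
[removed, removed + 300 s), truncated with a warning if the recording
ends earlier. Control recordings without a container are segmented
with artificial event times through the same code path.

Binning is half-open [lo, hi), so a larva exactly on a category
boundary belongs to the outer category; this guarantees the seven
categories partition the radius axis and that zone dwell equals the sum
of its two constituent categories exactly. Dwell accounting is per
frame (1/frame_rate seconds to the frame's own category, no splitting
of a step across a boundary; at 2 frames/s the error is ≤ 0.5 s per
boundary transition). Path length attributes each
consecutive-coordinate distance to the category of the step's starting
frame; steps touching a position-less (edge-assigned) frame are
dropped. Speed is step length × frame rate; the scalar summary is the
median, the plotted trace a 10-frame moving average. A revisit is a
frame pair crossing the 8 mm center-zone border inward, with a landing
exactly on the border counting as inside (one convention applied
everywhere). The center-zone radius itself is the sum of container
radius (0.35 cm), median larval length (0.35 cm) and a 0.10 cm margin.

Stops: an episode opens at the first step below 0.05 mm, stays open
until every one of the next five steps is at or above the threshold
("moved continuously" read strictly), and episodes separated by five or
fewer moving frames are merged before counting. The merge is applied
before counting because it is a counting rule; the two rules together
are equivalent to clustering sub-threshold steps whose separations are
at most five frames, which is what the independent oracle in the test
suite implements.

The search score is (time in search zone − time in edge zone) divided
by the analyzed window duration, bounded in [−1, 1] and antisymmetric
under exchanging the two zones.

## Statistics

Only rank-based tests, all two-sided: paired Wilcoxon signed-rank for
within-larva baseline-vs-search contrasts, one-sample signed-rank for
scores against zero, Mann–Whitney U for two conditions, Kruskal–Wallis
(tie-corrected) for three or more with post hoc pairwise U tests run
only after a significant global test and corrected family-wise (Holm by
default; the correction method is a switchable argument since no single
convention is canonical). Zero differences are dropped before ranking
(Wilcoxon's original convention) and their count is recorded; an
all-zero sample returns p = 1 with a warning. Exact null distributions
are used for the signed-rank tests up to n = 25 without ties and for
the U test up to group sizes of 8 without ties; otherwise a normal
approximation with tie correction (no continuity correction, so the
approximate p converges to the exact one). Significance stars follow
p ≤ 0.05 / p ≤ 0.01 / p < 0.001. The computational backend is
scipy.stats; the test suite checks every exact branch against full
enumeration oracles (all 2ⁿ sign patterns, all C(n+m, n) group
assignments) written independently of the implementation.

## The synthetic cohort generator

Larval crawling is modelled as a run-and-turn walk: per frame the
heading is pulled with gain *g* toward a preferred radial band and
perturbed by von Mises noise (concentration 8). The preferred band is
just inside the wall (27.5 mm) for the thigmotactic baseline regime and
an inner ring (12 mm, the middle of the search zone) after the
simulated container removal in `local_search` mode. Each larva draws a
per-animal speed (0.7 ± 0.15 mm/s), an orbit chirality, stop episodes
(1.5/min, mean 3 s), and alternates between target-biased crawling and
unbiased exploratory wandering (excursions at 3/min, mean 25 s). The
wall is reflective. Detection dropout deletes frames in geometric runs
(start probability 0.02/frame, mean 10 frames, doubled near the wall
where real trackers lose larvae against the lid), giving a mean missing
fraction around 22–25%, matching the reported detection-failure range.
Event logs are drawn alongside (pre-search waits exponential with a
240 s mean in the standard configuration), so phase segmentation runs
on simulated data unchanged.

The excursion and ring parameters were set so that simulated zone
occupancies land near the cohort-level values reported for the assay
(baseline: ≈60% edge-zone and ≈12% search-zone dwell, score median
≈ −0.5; search phase: ≈33% search-zone, ≈18% edge-zone dwell, score
median ≈ +0.15). What the generator does *not* emulate: burrowing into
the substrate, lid climbing, head casts and posture, odor gradients,
speed changes after stimulation, or any learning dynamics. Passing
tests therefore demonstrate that the pipeline measures what it claims
on data with the assumed statistical structure, not that real larvae
behave like the agent.

Determinism: the master seed expands to per-larva streams via
`SeedSequence(master_seed, spawn_key=(larva_index,))`, so cohorts are
bit-identical across runs and a larva's track does not depend on cohort
size.

### Initial placement and the null construction

By default larvae start at the arena center, emulating placement by
brush; the first minute then shows the characteristic dispersal toward
the wall. This has a statistical consequence: the baseline window
contains a transit through the central zones that no later window
contains, so with behavior held fixed the baseline and search windows
are *not* exchangeable — the measured score difference carries a
placement artifact of about +0.2 regardless of any behavioral change.
A type-I-error calibration needs the null hypothesis to actually hold,
so the generator also offers `initial_placement="stationary"`, which
starts the walk on the current regime's preferred band and discards a
120 s burn-in; the two analysis windows then sample the same stationary
process. The calibration harness uses this construction for null
cohorts, while power estimates keep the paradigm's center placement.

## Monte-Carlo validation sizes

The calibration harness simulates full 5-min baseline and 5-min
analyzed-search windows and draws the pre-search wait with a 60 s mean
— the wait only separates the two analyzed windows, so it is kept
short. Power uses 200 replicate cohorts of 15 larvae; null calibration
400 cohorts (Monte-Carlo sd ≈ 1.1% at a 5% rate); the paired test's
own type-I error uses 10,000 paired normal null datasets of 15 pairs.

## Known limitations

* Dwell and step attribution are per frame; sub-frame boundary
  crossings are not split.
* The speed metric is recomputed from step lengths; trackers that
  smooth internally may report slightly different values.
* Edge-assigned frames assume correct visual verification; their dwell
  goes to the edge zone even if the larva briefly left the wall.
* The lid-climbing episodes of real experiments have no dedicated
  repair class; they surface as ordinary gaps.
* Exact U-test enumeration is limited to group sizes ≤ 8; beyond that
  the tie-corrected normal approximation is used.
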