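# Methods

## Interaction definition

An interaction event is a maximal run of frames in which two flies'
tracked centroids stay within `distance_threshold_bl × body_length_mm`
(default 2 × 2.0 mm = 4 mm) and whose length reaches `min_duration_s`
(default 0.5 s, i.e. 12 frames at 24 fps). Design choices a user should
know about:

- **Inclusive minimum.** An episode of exactly 0.5 s counts. The
  alternative (strictly longer) differs in a single frame; the inclusive
  rule is the one the 12-frame arithmetic makes exact, and it is
  configurable.
- **Per-episode, not cumulative.** The duration criterion is applied to
  each continuous episode; a pair accumulating 0.5 s over several shorter
  brushes has no event.
- **Centroid distance.** Trackers report centroids reproducibly; a
  body-part reference would demand pose data the pipeline does not
  require. When the input carries a per-fly `body_length` column the
  threshold for a pair uses the mean of the two flies' body lengths.
- **Missing detections break runs and are never bridged**, because no
  imputation is performed by default. An optional linear interpolation for
  gaps of ≤ 3 frames exists (`interpolate_gaps`) but is off the default
  path. A separate `gap_tolerance_frames` (default 0) can fuse episodes
  separated by short *above-threshold* excursions, for trackers that
  jitter across the 4 mm boundary; it refuses to bridge missing frames.

## Networks and measures

A group's SIN keeps the full roster as nodes; isolated flies are data, not
noise, since the proportion of non-interacting individuals is itself a
phenotype. Each interacting pair has one edge with integer `w_count` and
`w_duration` in seconds (seconds, not frames, so exported graphs are
frame-rate independent).

Measure conventions, where the mathematics leaves freedom:

- Distance-based and spectral measures (closeness, betweenness,
  eigenvector, information centrality; L, D, E_glob) are computed on the
  **largest connected component**, the standard convention for fragmented
  social networks; nodes outside score 0 so tables stay total over the
  roster. Component size ties are broken toward the component containing
  the smallest node id, making results reproducible.
- Betweenness is normalised by the (N−1)(N−2) ordered pairs of the
  component. Weighted closeness/betweenness convert a weight *w* into a
  length 1/w — a heavier tie is a socially closer one.
- Eigenvector centrality is the non-negative principal adjacency
  eigenvector with unit Euclidean norm over the component (power
  iteration, tolerance 1e−10, max 1000 iterations; non-convergence raises
  rather than returning garbage).
- Information centrality is current-flow closeness: one over the node's
  total effective resistance, from the component Laplacian pseudoinverse.
- Weighted clustering uses the geometric-mean triangle intensity.
- Global measures that are undefined for a graph (diameter of an edgeless
  network, assortativity of a regular one, heterogeneity at mean degree
  zero) return **NaN, never silent zero**, so population aggregation can
  drop them explicitly. Transitivity of a triad-free graph is 0 by
  convention.

## Communities

Louvain (greedy modularity optimisation) with a fixed seed, because the
algorithm is order-dependent; resolution defaults to 1. The
**duration weight is the default** for middle-level analysis: total time
together is the stronger signal of a social tie than the episode count.
(Reference summaries of this analysis describe duration as a node
weight; weights live on edges, so it is applied as the edge attribute.) Modularity is
accumulated edge-by-edge from the chosen weight; isolated flies always end
as singleton communities. `pct_single_element` divides by the number of
communities; the alternative denominator, the number of flies, is a
one-liner on the returned fields, and the choice is presentational.

## Population comparison

Welch-corrected independent-samples t-tests (scipy, Welch–Satterthwaite
df), two-sided, α = 0.05, one test per measure with **no multiple-testing
correction** by default — each measure is reported on its own at
α = 0.05; a Benjamini–Hochberg option exists but is off by default. The unit of analysis for local measures is
the per-network **median**, robust to the skewed, zero-inflated
distributions of per-fly centralities; per-network means are available. Undefined per-network values are dropped
per measure with a count. Measure correlation matrices pool flies across
networks (Pearson). Occupancy heat maps bin positions over the arena's
bounding square; cells entirely outside the disc are NaN-masked and finite
entries conserve total fly-frames.

## The simulator

`synth.simulate_arena` emulates what a tracker exports for ~30 male flies
in a 120 mm arena filmed for 10 min at 24 fps. Its purpose is to give every
pipeline stage a controllable, seedable input whose network-level
statistics move in the directions real manipulations move them — not to be
a biomechanical fly model.

Mechanism (one seeded generator per simulation; a numba-compiled kernel
with a pure-Python fallback of identical semantics):

- **Rest/walk bouts.** Flies are sedentary: away from others they rest in
  geometric bouts of mean `mean_pause_s` (20 s default), with the entry
  rate derived from the stationary fraction `pause_prob` (0.9). Walking
  speed is ~0.8 mm/frame (≈19 mm/s).
- **Thigmotaxis.** An outward heading bias scaled by r/R concentrates
  activity near the wall, reproducing the edge-heavy occupancy maps of
  real arenas.
- **Social spacing.** Walking flies steer away from the nearest perceived
  fly (`avoidance`, default dominating `attraction`), reproducing the
  ~two-body-length spacing walking flies keep. At the default speed a
  straight drive-past stays under the 0.5 s criterion, so passes alone do
  not create events. During development this proved essential: without
  spacing, wall-lane traffic saturates the network (every pair "interacts"
  within minutes), which no observed fly group does.
- **Approach-and-dwell.** With a fly inside the perception radius a walker
  stops with probability `pause_prob_near` per frame, approaches to within
  `contact_distance_mm` (2.5 mm) and sits for a geometric dwell of mean
  `mean_dwell_s`. These dwells are what creates interaction events, so the
  three knobs map almost directly onto network statistics: activity →
  encounters, stop probability → edge count, dwell length → durations.
- **Refractory departure.** After any rest the fly walks ≥ `refractory_s`
  (1.5 s) ignoring other flies, so dwell partners separate; without it,
  mutual attraction locks pairs permanently and inverts the density
  contrast.
- **Immobile flies** (`immobile_fraction`) never move, emulating isolated
  or overdosed individuals; initial placement is uniform in the disc with
  ≥ 5 mm separation. The wall is reflective; every position satisfies
  x² + y² ≤ R².

Presets encode two phenotypes. `ctrl_like`: moderate activity
(pause 0.9), weak attraction (0.2), rare stops (0.005/frame), 2 s dwells,
5% immobile. `coc_like`: **more active** (pause 0.82 — psychostimulants
increase locomotion), stronger attraction (0.6), more frequent stops
(0.018), 5 s dwells, 25% immobile. These magnitudes were calibrated during
design so that the drug-like population shows the qualitative pattern of
the real manipulation — higher density, much higher duration-strength,
shorter average path, lower modularity, and a higher *proportion* of
singleton communities (the proportion, not the absolute count, is the
claimed phenotype, since a population with fewer communities can have
fewer singletons in absolute terms) — and then frozen.

What the simulator does **not** emulate: orientation-dependent interaction
types, courtship/aggression structure, identity swaps and tracking noise,
within-group heterogeneity beyond the immobile class, and arena
inhomogeneities. Passing the recovery tests therefore shows the pipeline
detects such contrasts when present; it does not validate any biological
claim about real flies.

## Problem sizes in the test suite

The direction-of-effect recovery test runs the full recording design
(9 + 11 groups × 30 flies × 600 s) five times. Type-I error calibration of
the Welch comparison uses 200 replicate experiments at a reduced scale
(5 vs 5 groups of 10 flies, 60 s, identical configurations) — the test's
operating characteristics depend on the number of networks per group, not
on arena scale, and this keeps the calibration cheap. Oracle-equivalence
suites compare every measure against brute-force reimplementations
(hand-rolled BFS, exhaustive shortest-path enumeration, Laplacian
pseudoinverse, direct Pearson formulas, frame-scan event detection) on all
fixture graphs, 200 random graphs of ≤ 8 nodes, and 100 random 5-fly
trajectories; Louvain output is checked against exhaustive search over all
partitions of small graphs.

## Known limitations

- Simulated interaction rates are denser than those reported for real
  untreated fly groups (density ~0.24 vs ~0.12) though of the same
  order; contrasts, not absolute rates, are the design target.
- Louvain is a heuristic; different seeds can give different partitions on
  near-degenerate networks. The seed is surfaced everywhere.
- The event detector assumes a common frame clock across flies (tracker
  exports provide this); unsynchronised streams are out of scope.
- Betweenness/closeness weighted variants use the 1/w length convention;
  other conventions (e.g. 1/log w) would need a one-line change but are
  not exposed.
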