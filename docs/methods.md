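# Methods

## Coordinate conventions and input model

All analysis runs in 2-D Cartesian micrometres in the math convention
(y increasing upward).  ImageJ-style exports use the image convention
(y downward); geometry files therefore carry a required `y_axis` field and
track readers accept a `y_axis` argument, and the flip is applied once,
explicitly, on read.  Tracks are single-Z-plane, uniformly sampled
(default 5 s frame interval); a gap in the frame sequence is an error, not
something to interpolate over, because a missed detection breaks the
directional statistics downstream.  Comets already present in a movie's
first frame are excluded from every analysis: they may be pre-existing
microtubules rather than new growth events.

## Initial growth angle

For each comet the initial direction is the first principal axis
(total least squares) of its first `n_direction_points` positions, oriented
by the net displacement.  The default of 3 points (origin plus two frames,
~10 s of growth) is the minimum that smooths single-frame localisation
jitter while still measuring the path "before turning"; it is configurable
because the right value depends on frame rate and noise.  θ is the signed
angle at the comet origin from the ray (origin → axon entry site) to that
direction, positive counterclockwise, in (−180°, 180°].  Folding to |θ|
deliberately discards the left/right distinction.  The sign convention is
observationally irrelevant for every reported quantity (folded angles and
quadrant tests are symmetric); it is fixed purely so tests are
deterministic.

A comet is attributed to a Golgi stack when its origin lies within the
stack's association radius (default 1.0 μm ≈ a Golgi ministack footprint;
nothing in the data formats records the attribution, so it must be spatial).
Ties go to the nearest centre, exact ties to the lexicographically first
stack name (logged).

## Resultant vectors and the uniform null

Comet angles from one stack become unit vectors (sin θ, cos θ) — note the
cosine is the **Y** component, so the +Y axis is "toward the axon" — and
are averaged, giving a resultant of length d ∈ [0, 1]: 1 when all angles
agree, 0 when they cancel.  Only stacks with ≥ 2 comets are informative.
The null model redraws every comet angle from continuous Uniform(−180, 180)
(the measure-theoretically natural reading; integer-degree draws differ
negligibly) while keeping the per-stack comet counts, and recomputes d.
Replicates use substreams spawned from a single seed
(`numpy.random.SeedSequence`), so results are bit-reproducible.  For
display three replicate sets are generated (matching the usual
visual-comparison practice); moment checks in the test suite use 10³–10⁵
replicated stacks, for which analytic anchors exist: E[d] = 2/π for
two-comet stacks and E[d] → 0.886/√n in the Rayleigh limit.

Observed and null d distributions are compared on 10 equal bins over [0, 1]
(the binning is a documented choice; any fixed binning works) with a
one-way chi-squared of observed counts against null-derived proportions;
bins with zero pooled-null mass are merged downward so every expected count
is positive.

## Entry zones, approach and entry

The entrance to each neurite is modelled as a band ~0.5 μm wide
(configurable) across the mouth, bounded by an inner and an outer gate
perpendicular to the local neurite axis.  That axis is estimated as the
outward soma-boundary normal at the entry point.  The gate length
("caliber") spans the mouth; since the geometry format carries no neurite
silhouette, caliber is an explicit parameter, default 2.0 μm, clamped to
[1, 5] μm — wide enough to cover a primary neurite mouth, narrow enough not
to capture soma-interior passes.  A comet whose path touches the band
*approached* that neurite; if it subsequently crosses the outer gate it
*entered*, and classification stops there (beyond the outer gate the comet
is inside the neurite).  A comet may approach more than one neurite
(first-contact order is recorded) but enter at most one; per-neurite
approach counts are the denominators for entry proportions.  Comets whose
origin already lies inside a band are excluded from approach/entry
denominators (logged) — an ambiguity that barely arises in real somas but
must be handled deterministically.

## Turning

Published scorings of "turning behaviour" are by eye; a reproducible
pipeline needs an explicit rule, so every threshold lives in
`TurningParams` and is echoed into run manifests:

- **Qualification**: within-soma path length > 2.0 μm, and not a *cortex
  traveller* (≥ half of within-soma points within 1.0 μm of the soma
  boundary).  Direction changes of cortex-hugging comets are dominated by
  boundary guidance, not by the turning behaviour of interest.
- **Detection**: direction estimates are displacements over windows of
  `smoothing_window` frames (default 3).  Windows truncate at the track
  ends and at locally sharp vertices (per-step direction change above
  `collinearity_tol`, default 5°), so a genuine sharp turn is never
  averaged away; sub-tolerance jitter is still smoothed.  A comet *turned*
  when two window estimates separated along the path differ by at least
  `turn_angle_threshold` (default 45°) **and** the sharpest intervening
  vertex lies farther than `cortex_margin` (default 1.0 μm) from both the
  soma boundary and the nucleus — direction changes at those boundaries are
  collisions, not turns.

The pairwise form makes the rule cumulative: several same-direction bends
that add to ≥ 45° count, which matches the visual impression of a turning
comet better than any single-vertex angle.

## Dendrite polarity

Within a proximal dendrite segment — from the entry zone's outer gate to
the dendrite's branchpoint marker (a geometry-file field, not inferred) — a
comet's net displacement projected on the dendrite axis classifies it as
anterograde (away from the soma; plus-end-out proxy) or retrograde (toward
it).  Displacements below a 0.2 μm noise floor are indeterminate, logged,
and excluded from denominators.  Both comets that originate inside the
segment and comets that grow in from the soma are scored.

## Inference

Proportions carry Wilson-score 95% intervals: the extreme proportions that
arise here (2%, 89%) are exactly where Wald intervals misbehave and Wilson
does not.  Frequency distributions are tested with one-way Pearson
chi-squared goodness-of-fit tests.  Two-condition comparisons use the 2×2
Pearson chi-squared **without** continuity correction; this variant is
pinned by a calibration check in the test suite (114/1058 vs 47/666 must
give p = 0.0098 to two significant figures, which the Yates-corrected
variant fails).  Quadrant skew uses the exact binomial upper tail.  No
multiple-testing correction is applied, matching the source analyses.
P-values are displayed to two significant figures with a "p < 0.001" floor;
stored values keep full precision.

## Synthetic data generator

`simulate_neuron` draws comet trajectories inside a parametric soma (an
ellipse, default 12 × 10 μm, with a concentric nuclear ellipse at 0.55 of
the soma axes, one axon and two dendrite entry points on the boundary, and
8 Golgi stacks placed uniformly in the cytoplasmic annulus — matching the
~8–9 stacks per neuron seen in somata).  Per comet:

- Origin: a Golgi stack with probability `frac_golgi_origin` (0.5), with
  initial angle θ ~ von Mises(0, κ) about the origin→axon direction, else a
  uniform cytoplasmic origin with uniform angle.  Von Mises is the
  canonical circular unimodal family and nests the uniform null at κ = 0;
  the default κ = 3 produces a strong but imperfect axon bias.
- Growth: straight steps of `growth_speed × frame_interval`
  (0.1 μm/s × 5 s) with a per-frame catastrophe probability
  1 − exp(−0.005/s × 5 s), giving tracks of a few μm over tens of frames.
  These kinetics are plausibility stand-ins, not measured values, and are
  never asserted as truth.
- Guided turns: with probability `p_turn_per_frame` (0.05) the direction
  resets toward the current bearing of the axon entry ± von Mises jitter —
  a phenomenological "guidance along a polarised network", not a
  rail-microtubule force model.
- Boundaries: the path reflects off the soma and nuclear ellipses
  (collisions, recorded as such).  Dynamics use the analytic ellipses; the
  emitted polygon is a 256-gon scaled by 1/cos(π/256) so it contains the
  ellipse (max gap ~3×10⁻⁴ μm, negligible against every margin used).
- Gates: on first contact with an entry-zone band a single
  Bernoulli(`p_enter_*`) draw decides entry (continue ≥ 1 μm past the outer
  gate, then terminate) or rejection (terminate inside the band).  Defaults
  0.54 (axon) and 0.28 (dendrite) mirror control-like rates.
- Emission: Gaussian localisation jitter (`position_noise_sd`, default
  0.05 μm ≈ half a pixel of manual clicking error) is added to the true
  path, **conditional on not changing the scored gate events** — noise is
  redrawn (rarely) if the noisy polyline would cross an outer gate it did
  not cross, or touch a band it never contacted.  Without this the emitted
  track could contradict its own ground-truth record.

Each comet carries a `GroundTruth` record: origin stack, injected initial
angle, guided-turn frames, gate contact and Bernoulli outcome, termination
cause, and qualification/turn labels evaluated on the exact polyline with
the same operational turning definition (raw step directions, which on the
exact path are the true segment directions).  At zero noise the sampled
track equals the exact path and classification reproduces these labels
exactly — verified as a test.  What passing such tests does **not** show:
robustness to detection gaps, drift, depth (3-D) effects, curved growth, or
density-dependent tracking errors, none of which the generator emulates.

`fixture_counts` builds fully deterministic piecewise-linear tracks whose
classified counts equal a requested approach/entry table: enterers and
approachers run straight at a zone with sub-caliber lateral offsets and
within-soma paths kept below 2 μm (so they never enter the turning
denominator — mirroring the separate published denominators), turning
fixtures are >2 μm mid-soma chords with or without a 90° vertex, polarity
fixtures live inside the proximal dendrite segment, and filler tracks are
short mid-soma stubs.  Its `seed` argument exists for interface symmetry;
path shapes contain no randomness.

## Problem sizes and numerical choices

Simulation-based checks use 51 comets per neuron (the per-movie average of
the motivating datasets), 10 neurons per replicate, 100 replicates for
CI-coverage checks and 200 for type-I-error checks; Monte-Carlo moment
checks use 10⁴–10⁵ stacks.  Angle arithmetic keeps everything in degrees at
the API surface and converts to radians only inside trigonometric calls;
unit-vector norms hold to 1e-12 and resultant identities are asserted at
that tolerance.  Degenerate inputs fail loudly: zero net displacement has
no direction, empty resultant lists have no quadrant fraction, zero
expected chi-squared counts are an error rather than silently dropped
(except in the documented null-histogram bin merge).

## Known limitations

- The turning rule is one defensible operationalisation of a behaviour that
  was originally scored by eye; its four parameters change absolute turning
  percentages, though relative condition differences are robust in
  simulation.
- The entry-zone caliber is a parameter because the geometry format has no
  neurite silhouette; a grossly wrong caliber misclassifies grazing paths.
- The generator's kinetics and noise are stand-ins; parameter-recovery
  results demonstrate internal consistency of the pipeline, not accuracy on
  any particular microscope's data.
- Single Z-plane only: comets leaving the focal plane are simply truncated
  tracks, and no correction is attempted.
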