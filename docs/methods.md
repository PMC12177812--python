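# Methods

## Stimulus kinematics

A stimulus is a target orbit plus a shared inducer-orbit template
applied at four centres. An orbit is parameterised by centre, radius
`r`, period `T`, direction (CW/CCW as the viewer sees it) and starting
phase `φ₀` measured clockwise from the top of the orbit, so every
object starts from its highest orbital position at `φ₀ = 0`. Positions
are evaluated as

```
p(t) = c + r · (sin α, cos α),   α = φ₀ + s · 360° · t/T,
```

with `s = +1` for clockwise motion in mathematical y-up axes. All
lengths are arbitrary screen units (the display geometry of these
illusions has no canonical absolute scale); the default target orbit
has `r = 1`, `T = 2 s`, and the inducer centres sit at the four
cardinal points of a ring of radius `3r` — the qualitative arrangement
of the demonstrations, chosen here because the model output is
provably independent of the ring radius (see below).

Six presets cover the canonical manipulations: target alone (`movie1`);
counter-rotating inducers at matched speed and phase (`movie2`); the
same with a 180° inducer phase offset (`movie3`); co-rotating inducers
(`movie4`); inducers at 1.5× the target speed (`movie5`); and a target
at half the inducer speed (`movie6`). Two parameters are not pinned
down by the published descriptions and are encoded as the unique values
reproducing the reported percepts, flagged `inferred` in the preset
metadata: `movie4` uses a 180° phase offset (a co-rotating, in-phase
inducer would cancel the relative signal entirely and predict no
illusion, not the reported enlarged circle), and `movie5`/`movie6` keep
the counter-rotating convention of `movie2` (the co-rotating
alternatives do not produce the reported star and triangle).

Sampling is half-open, `t ∈ [0, duration)`, so closed-curve metrics
never see a duplicated endpoint. The duration of a preset is the
common repeat period of target and inducers — `lcm(T_target,
T_inducer)`, which exists because speed ratios are restricted to
reduced fractions `p/q` with `p, q ≤ 64` — and the default grid is 720
samples per common period (enforced minimum: 64 per target period).
720 is enough that every shape metric is unchanged under 4×
oversampling (tested), including resolving the small corner loops of
the inducer-pursuit triangle percept with ≥ 10 segments each.

## Reference frames and eye movements

Viewing conditions are fixation, target pursuit, or pursuit of one
inducer. Pursuit is modelled as sinusoidal tracking with scalar gain
`g ∈ [0, 1]`: the eye orbits the pursued object's centre at `g` times
its orbital displacement, with an optional latency that clamps at
`t = 0`. This is the simplest model consistent with imperfect smooth
pursuit; saccades and head/body motion are out of scope. The efference
copy is `g_e ×` the eye's displacement from its own start, with
`g_e = 1` (a perfect copy) by default: gaze effects on perception are
carried by the cue weight, not by corrupting the frame arithmetic, and
both gains are exposed for users who want to study degraded signals.

The transforms are pointwise: retinal = world − eye; eye-centered =
retinal + efference. The relative path is computed on displacements
(positions minus each object's own orbit centre), not raw positions, so
the undocumented inducer ring geometry cannot leak into the relative
signal; the four inducers are synchronous by construction, and the
pipeline asserts their displacement traces agree (to 1e−9·r) rather
than averaging them, computing the relative path from inducer 0.

## Perceived-path model

The perceived trajectory is the convex combination of displacement
vectors

```
perceived = k · eye_centered + (1 − k) · relative,   k ∈ [0, 1],
```

re-anchored at the target centre. `k` is a time-invariant scalar per
trial; the same weight applies to both spatial dimensions. It can be
supplied directly, derived from cue precisions as
`k = p_ec / (p_ec + p_rel)` (standard reliability weighting), or taken
from condition defaults. The published account gives only open
intervals for the condition dependence — equal weighting under
peripheral fixation, `0.5 < k < 1` under target pursuit, `0 < k < 0.5`
under inducer pursuit — so the defaults are the interval midpoints
(0.5, 0.75, 0.25) and are configurable. Phenomena that *change* the
weighting (stable frames between target and inducers, central fixation,
attentional selection) are representable only as user-supplied `k` or
precision values; modelling their mechanisms is a non-goal.

With a perfect efference copy the model reduces to
`perceived = T − (1 − k)·I` in displacement vectors — a sum of two
circular motions. This identity is the test suite's brute-force oracle,
and gives closed forms for every preset: counter-rotating equal-speed
configurations yield an ellipse with semi-axes `((2 − k)r, kr)` (aspect
ratio `(2 − k)/k`, major axis at minus half the inducer phase offset),
co-rotation yields a circle of radius `(2 − k)r`, and the unequal-speed
presets yield epitrochoid-like curves whose radial profile is
sinusoidal with (speed-sum/common-period) cycles — 5 lobes for the
1.5×-speed preset, 3 for the half-speed target. Corner loops appear
exactly when the relative component's linear speed exceeds the
eye-centered one's, which for the half-speed-target preset happens at
`k < 0.5` (cusps at equality).

## Shape metrics

- **Lobes**: cyclic strict local maxima of distance-to-centroid with
  prominence ≥ 1% of the mean radius (parameter); the threshold
  separates true lobes from floating-point ripple. A circle reports 0.
- **Aspect ratio / orientation**: principal axes of the second central
  moments of the samples. For a uniform-in-time sampled ellipse
  `(A sin ωt, B cos ωt)` this returns exactly `A/B`, which is the
  quantity the inverse estimator needs — a bounding box would not be
  exact off-axis. A circle reports `(1, 0°)` by convention; a collinear
  path (the `k = 0` limit) reports infinity with the line's
  orientation rather than erroring.
- **Self-intersections**: transversal crossings of non-adjacent
  segments of the closed polyline, `O(n²)` pairwise with blocked
  evaluation to bound memory; crossings of distinct segment pairs at
  the same geometric point are deduplicated within 1e−9 of the mean
  radius. Collinear retracing (the segment-shaped relative path) has no
  transversal crossing and counts 0.
- **Side classification**: the path is cut at its lobe maxima (≥ 3
  required); each side's midpoint-vs-chord deviation, signed outward
  from the centroid, classifies it convex / concave / straight
  (|deviation| < 0.5% mean radius), aggregating to `mixed` on
  disagreement. At `k = 0.5` the triangle percept's sides are nearly
  but not exactly straight; the classifier reports what the threshold
  sees and makes no claim of exact straightness.

Closedness is checked by requiring the gap between the last and first
samples to be comparable (≤ 5×) to the median sample spacing.

## Observer fitting

`k_from_aspect_ratio` inverts `ar = (2 − k)/k` for the elliptical
presets. `fit_k` handles arbitrary configurations: it minimises the
mean squared pointwise distance between a centroid-removed observed
trace and the anchor-removed model prediction over `k` — a grid at step
0.001 followed by golden-section refinement to 1e−5. The objective is
an exact quadratic in `k` (the model is linear in `k`), so the grid is
evaluated through its three precomputed coefficients; the grid-then-
refine protocol is kept because it is robust, cheap, and verifiably
unimodal. Alignment removes translation only: traces are assumed
time-locked to the stimulus, as in an adjustment or tracing task, and
no rotation or time-shift is estimated. `bootstrap_ci` resamples time
points of the centred residual pairs with replacement (≥ 100
replicates), refits per replicate, and reports the 2.5–97.5 percentile
interval, deterministic for a fixed seed.

The synthetic observer adds i.i.d. isotropic Gaussian position noise
(sd in screen units) to the model prediction. It emulates a percept
*report*, not a human: no motor dynamics, response lag, temporal
autocorrelation (a hook exists but defaults off), or trial-to-trial
weight variability. Passing parameter-recovery tests therefore shows
the estimator is unbiased and well-conditioned under the stated noise
model (|mean bias| ≤ 0.02 at noise sd 0.05r over 100 replicates, ~95%
bootstrap coverage), not that human data will be as clean. The
co-rotating preset remains identifiable despite its circular percept
because the radius `(2 − k)r` still encodes `k`; the target-only preset
(`movie1`) carries no relative cue and `k` is structurally
unidentifiable there.

## Rendering and I/O

Rendering draws plain grayscale discs (no arbitrary sprites) with
optional veridical/predicted path overlays; world y-up coordinates are
flipped to raster y-down only at pixel-mapping time, and output is PNG
frames or an animated GIF to avoid video-codec dependencies. Configs
are JSON/YAML; trajectories and traces are `t,x,y` CSV with a JSON
sidecar (frame label, anchor, dt, provenance). Each CLI run writes a
manifest sufficient to reproduce its outputs.

## Known limitations

- The model is purely geometric: it predicts trajectory *shape*, not
  perceived speed, disc appearance, or the strength/salience of the
  illusion.
- `k` is constant within a trial and shared across axes; time-varying
  or anisotropic weighting is not modelled.
- Pursuit is idealised sinusoidal tracking; catch-up saccades and gain
  fluctuations are absent.
- Absolute stimulus scale (degrees of visual angle) is undefined; all
  geometry is in arbitrary screen units.
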