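# Methods

This note documents the models implemented in `mitotrack`, the numerical
choices behind them, what the synthetic data generator does and does not
emulate, and the known limitations.  Notation: ψ is the image intensity on
[0, 1]; φ the level-set field (negative inside the contour, a signed
Euclidean distance after reinitialisation); H the sharp Heaviside with
H(φ) = 0 for φ ≤ 0 (inside); δ_ε(φ) = ε/(π(ε² + φ²)) the regularised Dirac
delta.

## Detection: circular Hough transform

Edge pixels (gradient magnitude ≥ `edge_threshold` × frame maximum) vote
into a 3-D accumulator over centre and radius.  Each edge pixel casts one
vote per radius bin at the two points a distance r along ± its gradient
direction (gradient-directed voting; full-circle and phase-coded
accumulators are classical alternatives — phase coding collapses the
radius axis into complex phases but leaves a 2-D accumulator that is
harder to inspect, so it is not used here).  Votes in each radius slice
are divided by 2πr so peak heights are comparable across radii, each
slice is Gaussian-smoothed (σ = 1), and local maxima above
`peak_threshold` × accumulator maximum become candidates.

Two implementation details matter in practice:

* the frame is pre-smoothed (σ = 1.5) before gradients are taken — noisy
  gradient *directions* smear the votes of large circles tangentially in
  proportion to r, which would otherwise bias detection against them;
* an absolute significance floor (`min_significance`, default 0.1 — i.e.
  at least ~10% of a coherent rim's votes) keeps frames with no circular
  object from promoting incoherent noise peaks, since the peak threshold
  alone is relative to each frame's own maximum.

De-duplication is greedy in significance order: a candidate is rejected
within `dedup_spatial` px of an accepted one in the same frame, or within
`dedup_temporal` px in an adjacent frame.  Defaults for both are
`radius_max`.

## Segmentation: the tracking energy

One frame of a tracked cell is segmented by descending

E(φ, c₁, c₂) = λ₁ Σ (|v|−c₁)² (1−H(φ)) + λ₂ Σ (|v|−c₂)² H(φ)
             + μ Σ |∇H(φ)| + ν Σ g(ψ) |∇H(φ)|
             + (ω/2)·max(t_area − A(φ), 0)²,

with A(φ) the enclosed area.  The ingredients:

* **Normal-velocity image** |v| = |ψ_t − ψ_neighbour| / |∇ψ|_ε with
  |∇ψ|_ε = sqrt(ψ_x² + ψ_y² + ε²).  The neighbour is the next frame when
  tracking forwards and the previous frame when tracking backwards; the
  temporal step is one frame.  |v| is large where intensities change in
  time but spatial gradients are weak — exactly the interior of a moving
  phase-contrast cell under shade-off — and small in static background.
  Inside the segmenter |v| is rescaled by its frame maximum so the weights
  are comparable across frames.  Frames are pre-smoothed (σ = 1, a
  tracking parameter) because |v| is a ratio of two noise-limited
  quantities.  ε defaults to 10⁻² as a generic value; the bundled
  synthetic preset raises it to 5·10⁻², which suppresses the noise/noise
  ratios of static background without touching the cell signal.
* **Edge indicator** g: the 3×3 local standard deviation (population
  estimator, reflective padding) of the Gaussian-smoothed frame, rescaled
  to [0, 1], mapped through g = 1/(1 + (s/κ)²) with κ = 0.3.  Cell rims
  (halo) and textured interiors are locally inhomogeneous while background
  is flat, so g ≈ 1 in background and ≈ 0 on rims; plain gradient
  magnitudes are much weaker markers in phase contrast.  The classical
  reciprocal gradient form is available as `edge_mode="gradient"`.
* **Area penalty**: one-sided and quadratic, active only when the area
  falls below `t_area` (default 0.15 × the detection-frame area).  It
  prevents the contour from collapsing on frames where the cell is nearly
  static and the data term momentarily vanishes.  A literal variant that
  instead *subtracts* the penalty above the threshold is provided as
  `area_penalty_sign="as_printed"`; it is not the default because it makes
  the energy unbounded below as the contour grows.

### Numerics

* Gradient descent with the update δ_ε(φ)[λ₁(|v|−c₁)² − λ₂(|v|−c₂)²
  + μ div(∇φ/|∇φ|) + ν div(g∇φ/|∇φ|) − ω max(t_area − A, 0)], the region
  means c₁, c₂ recomputed each iteration.  The length term uses the
  forward/backward/central difference scheme customary for
  piecewise-constant models; the edge term uses central differences
  throughout, which proved the more stable choice.
* **Step control.**  The raw descent direction is rescaled so the front
  advances at most `step_size` (0.5) px per iteration, normalising by the
  90th percentile of |update| near the zero level (the discrete curvature
  of a distance field is spiky right at the contour, and a single noisy
  pixel must not stall the whole front); far-field updates are clipped to
  the same bound.  The normaliser is the running maximum over iterations,
  so dying forces produce dying steps and the front genuinely stops on
  edges instead of being re-amplified.
* **Line search.**  A step is accepted if it does not increase a
  sharp-interface *search energy*: the region terms under the sharp
  Heaviside with optimal means, μ × the boundary-polygon perimeter of the
  zero-level mask, ν × (mean g on the boundary) × perimeter, and the area
  term.  This energy depends on the sign pattern only, so sub-pixel
  motion is free and the δ-quadrature artefact (energy changes from φ
  deforming without the contour moving) cannot block descent.  On
  rejection the scale is halved up to five times; if flips still raise
  the energy they are vetoed while the sub-pixel motion is kept.  The
  energy reported in `energy_log` is therefore non-increasing between
  reinitialisations by construction.
* **Reinitialisation** to a signed Euclidean distance (half-pixel offset:
  a boundary pixel sits at ≈ −0.5) every `reinit_every` = 5 iterations,
  but only if the sign pattern changed since the previous one — rebuilding
  the distance field from an unchanged mask would erase accumulated
  sub-pixel front motion and lock slow fronts into limit cycles.  The
  narrow band (half-width 6 px) is rebuilt after each reinitialisation.
* **Convergence**: a sign pattern static for 30 iterations, or `max_iters`
  (200).  A divergence guard raises an error (carrying the last stable φ)
  after ten consecutive energy increases.
* **Topology.**  Backwards tracking preserves topology: a pixel's sign may
  flip only if it is a *simple point* — flipping changes neither the
  number of 8-connected foreground nor 4-connected background components
  in its 3×3 neighbourhood (checked via a precomputed 512-entry table).
  Forwards tracking leaves topology free so the contour can split at
  division.

The public `tracking_energy` evaluates the energy with the conventional
δ-quadrature for the length terms (Σ δ_ε(φ)|∇φ|), which approximates the
contour length to ~1% on a radius-20 disk at ε = 1.

### Baselines

`chan_vese` is the same machinery on raw intensities with the plain area
term (weight ν); `geodesic_active_contours` integrates
∂φ/∂t = div(g ∇φ/|∇φ|)|∇φ| with the gradient-based g — a pure front
propagation, run without the line search because it is not the gradient
flow of the search energy.  With g ≡ 1 it reduces to mean-curvature
motion, under which a circle shrinks and vanishes.

## The mitosis workflow

1. Detect circles in every frame; keep candidates above
   `peak_threshold` × the best significance *in the whole sequence* (a
   frame-local threshold would promote spurious responses in frames
   containing no mitotic cell); de-duplicate per frame and across
   consecutive frames; cluster detections of the same slowly-drifting cell
   (centres within `dedup_spatial`, frames within 4 — the window is kept
   short so a parent is never absorbed into its own daughters'
   detections); track each cluster representative once, in significance
   order.
2. **Backwards.**  The detection circle initialises φ; each earlier frame
   is initialised by the previous mask dilated by `dilation_radius` (3 px)
   and re-segmented.  Tracking stops when morphology breaks: circularity
   4πA/P² < 0.85 **and** area > 1.3 × the smallest area seen so far on
   this track (the reference is the roundest state, robust to overshoot at
   the detection frame).  The start of mitosis is the frame after the
   break.
3. **Forwards.**  Same propagation.  The *end of the round mitotic phase*
   is dated by the first frame whose mask deforms (circularity < 0.85):
   at division the mask becomes a dumbbell or rosette while the vacated
   space between separating daughters still carries temporal signal, so
   the clean component split settles a few frames later and would date
   the event late.  The *fate* is then decided by the daughter count once
   a split persists for `split_persistence` (2) frames, where the count is
   the maximum of (a) connected components after a radius-2 opening
   (hairline bridges are not connections), (b) well-separated strong peaks
   of the mask's Euclidean distance transform (lobes), and (c)
   daughter-sized circles (0.4–0.9 × the detection radius) found by the
   Hough detector inside the mask — symmetric multipolar daughters can sit
   inside a near-convex mask for several frames, where only (c) counts
   them correctly.  Two daughters ⇒ regular division; one or ≥3 ⇒
   abnormal.  A mask that collapses below `min_component_area` (30 px²)
   while brighter than the frame's 90th intensity percentile — or vanishes
   — is apoptosis; a mask that stays round to the end of the window is no
   division.
4. Events are merged: tracks that cover the same pixels in a shared frame
   (>30% overlap of the smaller mask), or whose detection appears shortly
   after another event's conclusion near its final position, are
   re-detections of the same cell or its daughters; events with a decisive
   fate outrank open-ended `no_division` tracks, then higher detection
   significance wins.
5. Duration = (end − start) × frame interval (minutes); the summary holds
   the event count, the average mitosis duration and the fate counts.

## Fate classification (nine features, 1-NN)

`extract_features` summarises a masked cell by area, boundary-polygon
perimeter, circularity, mean and standard deviation of the masked
intensities, maximum gradient magnitude, mean local standard deviation,
and the total variation of the local-std map and of the grey values — the
two TV features are divided by the area so they compare across cell sizes
(configurable off).  Features are z-scored on the training set before
Euclidean 1-NN (configurable off); without scaling the area feature would
dominate the metric.  Ties break to the lowest exemplar index.
Leave-one-out accuracy refits the standardisation per fold.  The
classifier is a deliberate minimum: with well-chosen features a 1-NN rule
is competitive and fully inspectable.

## Validation metrics

JSC(A, M) = |A∩M| / |A∪M| on pixel sets.  MHD(A, M) =
max(mean_{a∈A} d(a, M), mean_{m∈M} d(m, A)) with Euclidean nearest-point
distances, computed exactly via distance transforms; by default over full
foreground pixel sets (a boundary-only mode exists, as contour practice
often prefers).  Both are checked against brute-force double-loop oracles
in the test suite.

### Circularity

4πA/P² with the perimeter measured on the marching-squares boundary
polygon (level 0.5, zero-padded mask) after a light circular moving
average of its vertices (window 3, two passes).  The raw staircase
polygon overestimates curved perimeters by 5–10%, which would push ideal
disks to ≈ 0.87; the smoothed polygon recovers disks to within ~1% at the
price of slightly rounding sharp corners (a 20 px square reads ≈ 0.85
instead of π/4 ≈ 0.785).  Values are clipped to [0, 1.05].

## The synthetic generator

`mitotrack.synth` renders what the method needs to be tested against, not
microscope physics:

* **Shade-off**: interiors at background ± a small contrast (0.03).
* **Halo**: a Gaussian-profiled rim (width 1.3 px) whose crest runs ~2 px
  *inside* the cell outline, so the visible glow decays outwards across
  the boundary and the cell's apparent extent coincides with its
  ground-truth mask; mitotic rims are 1.6× brighter (rounding cells
  diffract more light).  The rim is an intensity ridge, not a Zernike
  point-spread simulation.
* **Interior texture**: a static smooth random field that translates
  rigidly with each cell (amplitude 0.05–0.06) — phase-contrast cell
  interiors are inhomogeneous, and a rigidly moving texture feeds the
  temporal-derivative signal the tracking model relies on.
* **Events**: scripted rounding (flat ellipse, axis ratio 3, area ≈ 2.2 ×
  the mitotic disk → the morphology break is detectable), division into n
  daughters of radius r/√n whose centres separate for four frames with
  equal inter-daughter gaps, keeping a visible (faded) rim afterwards;
  apoptosis as an abrupt collapse to a small bright fragment (≈ 0.3 r,
  brightness +0.35) that shrinks away.  Trajectories are constant drifts
  (0.6–1.0 px/frame) sampled to stay strictly inside the frame — a cell
  parked against a clipping wall would have no temporal signal, an
  artefact rather than biology.
* Additive Gaussian noise (σ = 0.005) and exact per-frame masks and event
  times.

The battery scenes are 128×128 px, 26 frames at 5 min/frame, one scripted
mitosis (all four fates cycled) plus a flat bystander as a detection
distractor — sizes chosen to exercise every code path while keeping a
20-scene battery in the low minutes on one CPU.  What passing these tests
does **not** show: robustness to crowding and touching neighbours, focus
drift, debris, uneven illumination, or halo morphologies unlike a smooth
ridge; parameters for real data remain per-cell-line choices (the YAML
presets exist precisely because the authors of such pipelines tune per
cell line).

## Known limitations

* The event-dating convention (morphology break) assumes rounding and
  division change shape within about one frame; very slow transitions
  would blur the start/end estimates.
* Division detection needs daughters that stay visible; daughters that
  disperse faster than the contour can follow are scored as apoptosis
  (mask vanishes).
* The normal-velocity model needs motion: a perfectly static cell carries
  no region signal and is held only by the edge term and area floor.
* The 1-NN classifier ships untrained; training data must come from the
  user's annotations (CSV of features + labels) or the synthetic
  generator.
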