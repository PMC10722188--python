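# Methods

`beamgait` analyses the posture of a mouse traversing a balance beam from
markerless 2D tracking of 18 named feature points (3 head, 4 torso, 7
tail, 4 feet).  This note describes the models and algorithms, the
defaults and why they were chosen, and what the bundled simulator does and
does not establish about real data.

## Coordinates and speed

Tracked tables give per-frame pixel coordinates per camera view.  All
analysis operates on the stacked coordinate vector
X(t) = (x1, y1[, z1], x2, ...) and its backward difference

    V(t) = X(t) − X(t − Δt),    Δt = 1/fps (one frame),

evaluated per frame, so V carries coordinate units *per frame* (0.0333 s
per frame at 30 fps).  The cycle-matching and correlation machinery below
is defined on this per-frame displacement; conversion to physical units
per second is an explicit, separate step.  For 18 points the stacked
vector has 36 components in 2D and 54 in 3D.

Gaps from low-confidence tracking (likelihood below 0.9 by default — a
stand-in for the manual curation the original workflow relies on) are
filled by per-coordinate linear interpolation; interior gaps longer than
`max_gap` (default 5 frames) and gaps touching the sequence boundary are
errors rather than silently extrapolated.  Non-walking intervals (stops,
pre-box hesitation) are culled before cycle extraction; culling intervals
are user-supplied, with an optional automatic plan that removes runs of at
least `min_len` frames whose foot-group RMS speed stays below a threshold.

## Geometry

Two camera arrangements are supported.

**Opposed 90° views** are merged in 2D: each view is aligned to beam
coordinates using the traced beam midline (beam → +x, scaled so the traced
beam measures the physical beam length, +y up from the beam midline), the
second view is reflected about the beam axis (opposed cameras see the
scene mirrored; a missing/superfluous reflection is detected as
anti-correlation of the perpendicular coordinate and reported), and
corresponding points are averaged.  Residual perspective error is
first-order cancelled by the averaging; on the simulator it stays below
~0.5 cm over a 60 cm beam.

**45° stereo pairs** are reconstructed in 3D without dedicated
calibration hardware.  The user traces three pairs of parallel scene
lines in both views — the beam edges (x direction), the goal-box outer
edges (y) and the goal-box entrance edges (z).  The pipeline is:

1. *Fundamental matrix* from the 12 corresponding line endpoints by
   least-median-of-squares over 8-point subsamples (all subsamples are
   enumerated when fewer than 500, otherwise seeded random sampling),
   Sampson distance as the residual, normalized coordinates, and an
   inlier refit at the robust scale.  Because 12 points determine F only
   marginally under tracing noise, correspondences can optionally be
   augmented with tracked feature points sampled across frames
   (`augment_correspondences`); this is recommended whenever the traces
   are not pixel-accurate.
2. *Canonical cameras* P_L = [I|0], P_R = [[e']×F | e'].
3. *Metric upgrade.*  A stratified linear solution initialises: each
   parallel pair's triangulated 3D lines meet in a point on the plane at
   infinity (affine upgrade); the three image vanishing points plus
   zero-skew/unit-aspect assumptions determine the image of the absolute
   conic — with the structured 4-parameter form solved exactly, pooling
   both views under a shared-intrinsics assumption (two phones of one
   model) — and a QR orthonormalization aligns the three directions to
   the axes, oriented by the endpoint order of each pair's first segment.
   The returned cameras then come from a constrained reprojection fit
   that adjusts shared intrinsics, both poses, and an axis-aligned line
   model to the traced endpoints (Levenberg–Marquardt on the 12 points;
   focal-sweep and essential-matrix starts when the linear stage is
   infeasible).  A fit that leaves more than 2 px RMS reprojection error
   is rejected as inconsistent/degenerate tracing.  On noiseless
   projections the reconstruction is exact to machine precision.
4. *Physical scaling.*  An in-plane shear parameterized by the measured
   beam inclination maps the entrance direction to the true vertical in
   beam coordinates (identity at zero incline — the approximation is
   documented: forcing an inclined beam orthogonal to vertical entrance
   edges before shearing back is exact only at zero incline), the beam
   start moves to the origin, and a uniform scale makes the reconstructed
   beam the measured length.  Output is in cm with the beam along x.

Opposed 90° cameras share an optical axis: points near the beam centre
are seen along almost the same line from both sides and their depth is
unreliable.  Triangulation therefore measures the angle between metric
viewing rays and warns when the median falls below 40° (the opposed rig
scores ≤ ~30°, the 45° rig ≥ ~55° on beam scenes); such pairs belong in
the 2D merge.

## Standard walk cycle (SWC)

The SWC is a single cycle of V(t) — τ frames × components — representing
the animal's typical gait, plus a cumulative weight.  Extraction:

1. *Template.*  An initial cycle SWC₀ is copied from the culled series,
   either a user-chosen interval or suggested automatically: the dominant
   period is the first autocorrelation peak (height ≥ 0.3) of the summed
   foot-group x-speed energy, and the interval is the highest-energy
   window of that length, shifted to start at its quietest frame so the
   cycle boundary sits in the support phase.
2. *Segmentation.*  The series is decomposed into contiguous cycles
   (t_{i+1} = t_i + τ_i); candidate periods are the integers in
   [⌈τ₀/2⌉, ⌊2τ₀⌋]; for each candidate the template is rescaled by
   linear interpolation and correlated with the data window using the
   non-centred inner product summed over components.  The default mode
   maximises the **total** correlation sum over all contiguous
   segmentations by dynamic programming — the full search over the
   candidate grid.  This objective has two important properties: constant
   components contribute the same total regardless of boundaries (so
   boundaries are located by the informative periodic components), and
   the discarded tail earns nothing (so coverage is preferred).  A greedy
   left-to-right mode (locally best normalised correlation) is provided
   for long series; it is faster but a noisy boundary can ripple into the
   neighbouring period, which is why it is not the default.  Ties go to
   the smaller period.  Length-normalised per-cycle objectives were
   rejected: a length-free score rewards splitting cycles in half, a
   length-weighted one rewards merging them.
3. *Averaging.*  Each cycle is rescaled to the template length and
   averaged with weight Cmax_i — its correlation sum divided by the
   rescaled template's self-inner-product, so a template-like cycle
   weighs ~1, a stationary one 0, and opposite movement negatively.
   Cycles with non-positive weight are excluded (with a warning) from
   both the average and the cumulative weight Σ Cmax.

*Refinement.*  The SWC file stores the values and Σ Cmax, so a new video
folds in as a running weighted mean: the previous SWC serves as the
template, and values/weights combine additively.  Sequential refinement
therefore matches batch extraction over concatenated data up to
segmentation boundary effects (identical to ~1e-16 on the simulator).

Averaging length is the founding template's τ₀ (the alternative — a
weighted-mean period — would make the stored SWC drift in length across
refinements).

## Synthetic walk generation

A raw SWC rarely closes: per-component displacement sums over one period
differ, so naive integration smears the posture.  Normalisation adds a
per-component constant — the smallest change preserving the waveform
shape, in particular zero-speed stance phases (multiplicative scaling
would distort them) — so that every point advances by V_x per period
(V_x = the largest per-point net x-displacement; beam-constrained motion
has zero net y/z).  The animation is the Forward-Euler cumulative sum of
the tiled normalised SWC from a supplied posture X₀; closure (posture
after k periods = X₀ + k·(V_x, 0, 0)) holds to machine precision.  A 2D
SWC can animate a 3D posture: the in-plane axes map to beam (x) and
vertical (z) and the lateral axis simply carries no movement.

## Event abstraction (variance of correlation)

For each segmented cycle and each component, the cycle's speed (rescaled
to the SWC length) is correlated with the SWC and normalised by that
component's self-inner-product.  The normalisation is per component —
not global — because the scale semantics must hold componentwise:
0 = no movement, 1 = match, >1 = same movement faster, negative =
opposite movement.  Components whose SWC norm is zero report 0 and are
flagged.

The VoC is the population variance (second central moment, divisor =
count) of a body-part group's component correlations within each cycle,
expanded to a step function of time over each cycle for plotting.  It is
non-negative, zero when a group moves coherently (whether matching the
SWC or standing still), and rises when components deviate
inconsistently — slips, jumps, head raises.  By default only x/y
components enter the VoC even for 3D data, keeping 2D- and 3D-tracked
animals comparable; a flag enables all axes.  Event flagging (cycles
above a VoC threshold, merged into contiguous runs) is a convenience for
locating peaks; the interpretation of a peak is left to the user.

## The gait simulator

Because no real videos ship with the package, every stage is validated
against a constructed quadruped gait with known ground truth:

- Feet alternate stance (exactly zero velocity, on-beam height) and swing
  (raised-cosine forward speed bump integrating to one stride) following
  a repeating 2-3-3 support pattern: two diagonal feet swing together,
  then each remaining foot in its own sub-phase (lateral mirroring
  reproduces the opposite leg dominance seen between individuals).
  Sub-phase boundaries snap to frame boundaries of the nominal period, so
  an unjittered gait satisfies the support pattern exactly per frame and
  jittered cycles are exact time-warps of the nominal waveform.
- Head, torso and tail points advance at the stride rate with
  period-locked oscillations on all three axes (defaults: head 0.6 cm,
  torso 0.6 cm, tail 1.0 cm; foot lift 1.0 cm, foot sway 0.8 cm;
  stride 5 cm over a 20-frame period at 30 fps on a 60 cm beam).  The
  amplitudes are chosen so that every coordinate carries periodic signal
  well above realistic tracking noise, as curated tracking of a walking
  mouse does; points within a group are phase-staggered.
- Tracking noise is i.i.d. Gaussian on positions; period jitter draws
  each cycle's length uniformly from ±j frames; anomalies are injectable
  per cycle: a stop (inserted zero-speed frames), a jump (both rear feet
  swing together), a slip (the foot's z dips below the beam during stance
  and the recovering swing is compressed into a catch-step — the stance
  dip alone is orthogonal in time to the SWC and invisible to the
  correlation statistic), and a phase shift (one foot's waveform offset
  from a cycle onward).
- A pinhole stereo rig (900 px focal, 1280×720, 80 cm from the beam)
  projects the walk and the three calibration line pairs at 45° or
  opposed 90°, with optional pixel noise.

What the simulator does **not** emulate: soft-tissue and marker-placement
drift, occlusion and mislabeling (left/right switches), motion blur,
lens distortion, out-of-plane body rotation, and biomechanically accurate
limb trajectories.  Passing tests therefore establish the correctness of
the algorithms under the stated geometric and signal assumptions, not the
tracking quality achievable on real video.

## Numerical choices

- Cycle rescaling uses linear interpolation on the frame grid throughout;
  sub-frame cycle alignment is out of scope.
- Robust F: 2.5× the LMedS robust scale for inlier selection; degenerate
  8-point samples (rank-deficient design) are skipped.
- Metric upgrade: LM to 1e-12 tolerances, at most 600 function
  evaluations per start, 2 px reprojection gate, focal accepted within
  (0, 50×image span); a negative-focal solution is mapped through the
  (f, R) → (−f, diag(−1,−1,1)R) gauge symmetry.
- Orthogonality of upgraded directions is reported (max |cos|); noiseless
  scenes reach < 1e-8.
- SWC files encode values and weight as 17-significant-digit decimals,
  which round-trip IEEE doubles bit-exactly.
- Seeded randomness only: the simulator and LMedS take explicit seeds;
  identical seeds give bit-identical outputs.

## Known limitations

- The shear correction for beam inclination is exact only at zero
  incline; at realistic inclinations (~6 cm rise over 60 cm) the residual
  distortion is second-order but not removed.
- With only the 12 traced endpoints and no augmentation, the 45°
  autocalibration tolerates little tracing noise (the vanishing-point
  geometry is intrinsically sensitive); trace long structures carefully
  or enable correspondence augmentation.
- The greedy segmentation mode can ripple a boundary error into the next
  cycle under noise; prefer the default full search except on very long
  recordings.
- VoC localises anomalies to a cycle, not to frames within it, and does
  not classify anomaly types.
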