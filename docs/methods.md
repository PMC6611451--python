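# Methods

## Geometry and coordinate conventions

All public coordinates are continuous millimetres with the origin at the
centre of the top-left pixel, x along the transducer face and y with
depth; pixels are assumed isotropic (`FrameSpec.mm_per_px`).  Fascicles
and aponeuroses are modelled as straight infinite lines.  Fascicle
length is the distance between the fascicle line's intersections with
the two aponeurosis lines; pennation is the acute angle (0°, 90°]
between fascicle and deep aponeurosis, computed from the direction
vectors so it is independent of either line's orientation sign.
Intersections are computed on infinite lines, so attachments outside the
imaged field of view are extrapolated and flagged per frame.

Line fitting defaults to orthogonal (total-least-squares) regression:
anchor at the centroid, direction along the principal axis of the
centred points.  Ordinary y-on-x regression is available
(`fit: ols_yx`) for comparison with slope-based pipelines, but it
biases the slope of steep fascicles, which can exceed 45° of pennation
in contracted muscle.  Lines are treated as parallel when
|sin(inter-line angle)| ≤ 1e-9, far below any physiological
configuration.

## Tracker

The tracker is a classic coarse-to-fine iterative Lucas–Kanade scheme
with per-level Gauss–Newton refinement, template gradients evaluated
once per pyramid level, bilinear sampling with edge clamping, and the
displacement guess doubled when moving to the next finer level.  Two
numerical details matter in practice:

* the base pyramid level is prefiltered (Gaussian, σ = 1 px) before
  differentiation.  Uncorrelated pixel noise otherwise enters the
  spatial gradients and shrinks every flow update (an
  errors-in-variables effect); the shrinkage is individually tiny but
  accumulates over hundreds of frame-to-frame steps into a systematic
  tracking lag.  A symmetric-gradient variant (averaging template and
  target gradients) was evaluated and performed worse, because the
  per-frame noise then correlates the system matrix with the residual;
* a small Tikhonov floor (1e-8 of the structure-tensor trace) keeps
  aperture-limited windows (points on a featureless band) numerically
  stable: their update along the band is ~0 rather than exploding.

Iterations stop when the update falls below 0.03 px or after
`max_iterations` (default 30, matching the validated configuration:
3 mm block, 4 pyramid levels, 2 mm bidirectional error, 100 seed
points, 10% reseed rule, middle-90% fascicle ROI).  Physical-unit
parameters convert to pixels via `mm_per_px`; the block size becomes
the nearest odd pixel count ≥ 3.

Point validity per step: tracker failure (non-finite or off-raster
result), departure from the frame, or a forward–backward re-track
landing more than `fb_error_mm` from the start.  Validity is the only
failure channel; `track_step` is total.

### Seeding

Two readings of "evenly distributed, automatically identified ideal
points" are implemented.  The default seeds an even grid over the ROI's
axis/width coordinates, constructed to be exactly symmetric about the
ROI axis for any point count (full rows plus a remainder placed on the
axis).  Symmetry matters: the line refit of a freshly seeded cloud then
reproduces the drawn annotation line exactly, so a static video yields
measurements constant from frame 0 onward, and the tracker introduces
no systematic line offset at initialisation.  Unreliable grid points
(low texture, off structure) are weeded out by the forward–backward
check as tracking proceeds.  The alternative (`seeding: "corners"`)
takes the strongest Shi–Tomasi minimum-eigenvalue responses first
(integration scale σ = 1.5 px, minimum mutual spacing of a quarter
block) and pads with the grid; corner placement concentrates points on
texture but is asymmetric around the structure, which offsets the
fitted line by a few tenths of a millimetre at initialisation.

### Attrition and reseeding

Invalid points are discarded each frame.  If more than
`reseed_fraction` (10%) of the prior frame's points were lost in one
step, or fewer than `min_points_for_fit` (5) survive, the structure is
reseeded: the ROI is rebuilt around the refitted line with the prior
axial extent and `n_seed_points` fresh points are placed in the current
frame.  Losing every point raises a fatal tracking-lost error naming the
structure and frame.  The 10% rule compares against the prior frame's
surviving count, not the original 100.

### Supervision

There is no interactive GUI.  Supervised re-tracking is performed by
inspecting the exported overlay video and re-invoking `fasctrack track`
with a revised annotation file, which makes examiner-variability
experiments scriptable.

## Reliability statistics

* **ICC(A,1)** — single-measure absolute-agreement intraclass
  correlation from the two-way ANOVA decomposition (targets × raters);
  the result object carries the mean squares it was computed from.  The
  implementation is cross-checked in the tests against both a
  first-principles double-loop oracle and an independent library
  implementation.
* **CMC** — waveform coefficient of multiple correlation: one minus the
  ratio of frame-wise between-waveform variance to total variance, under
  a square root.  A negative radicand (between-waveform differences
  exceeding the waveform's own range, e.g. pure offsets) returns NaN
  rather than being clamped.
* **Bland–Altman** — bias, 1.96·sd limits (sample sd), and a
  within-subject coefficient of variation for paired methods,
  100·(sd(d)/√2)/grand mean, judged against the a-priori 10% threshold.
* **Offset correction** — each series has (its first value − grand mean
  of first values) subtracted, so corrected series share their first
  value while within-series differences are preserved; the operation is
  idempotent.  Aligning to the first series instead is available.
* **Strength classes** — poor/moderate/strong/very strong with
  left-closed boundaries at 0.36, 0.67 and 0.90 (so r = 0.67 is
  "strong" and r = 1.0 "very strong").
* A configurable mistake filter (default 40 mm) masks gross manual
  digitisation errors in paired manual/automatic data.

## Synthetic phantom

The phantom stands in for human imaging data.  It renders a 60 mm ×
60 mm field of view at 512 × 512 px and 60 frames/s: a bright
subcutaneous layer, two bright aponeurosis bands with smooth random
along-band texture, and between them two oblique streak families
anchored at fixed attachment points on the deep aponeurosis — sparse
prominent fascicle streaks (12 mm spacing; the candidate fascicle is
one of these, attached at x = 58 mm) over fine perimysial streaks
(2 mm spacing) — all rotating about their attachments as pennation
changes, so band texture moves with the tissue.  The superficial
aponeurosis depth is derived from the deep depth, L(t) and θ(t) so that
the separation d = L·sin θ holds exactly, making the emitted truth
self-consistent with the measurement geometry to 1e-9.

Rendering applies a Gaussian blur (σ = 1 px), a mean-one multiplicative
lognormal speckle factor per frame (sd 0.15) and additive Gaussian
noise (sd 0.02 on a unit intensity scale), then quantises to 8 bits.
Everything is deterministic given the seed and frame index.  An
optional tissue-attached coherent speckle field advected in material
coordinates can be enabled (`coherent_amplitude`); it is off by default.

Kinematic profiles are linear ramps, ramp-and-hold (isometric-like), or
tabulated per-frame values, with pennation constrained to (5°, 80°).
The default contraction — L 60 → 40 mm with θ 20° → 35° over 120 frames
— gives peak per-frame displacements of roughly half a pixel, matching
the regime in which 60 frames/s imaging keeps point tracking reliable;
halving the frame rate doubles per-frame motion and visibly degrades
tracking, reproducing the known low-frame-rate failure mode.

The first-frame annotation lies exactly on the true structures
("perfect examiner"); optional jitter (translation sd in mm, rotation
sd in degrees about each segment midpoint) emulates different examiners
drawing the same structures.

**What the phantom does not capture:** physical speckle formation
(interference, attenuation, shadowing), out-of-plane fascicle motion,
fascicle curvature, probe motion, and inhomogeneous echogenicity.
Passing the recovery tests therefore demonstrates the pipeline's
correctness and its behaviour under noise and deformation, not clinical
accuracy on human imaging.

## Known limitations

The per-frame line refit of a point cloud spread over the ±2.5 mm ROI
is a biased estimator of structure orientation in deforming tissue:
points with weak local texture hover or follow the flow with
attenuation, so the fitted fascicle angle lags the true rotation by a
few degrees late in a strong contraction, and the length error grows
correspondingly (via dL/dθ = −d·cos θ/sin²θ ≈ −1 mm/deg at 35°).  On
the default contraction phantom this leaves tracked-vs-truth RMSEs of
roughly 1–2.3 mm in length and 0.4–1.3° in pennation depending on the
noise realisation, with waveform CMCs of 0.95–0.99.  The same
mechanism makes late-contraction pennation the least reliable output —
consistent with the general experience that automatic pennation
measurements degrade over a contraction — and is the main reason
supervised re-initialisation exists in the workflow.

## Problem sizes used in tests and the acceptance script

Static invariance uses 50 identical frames; parameter recovery uses the
full 120-frame contraction at 512 × 512; the attrition scenarios use 16
and 12 frames; the examiner-replicate experiment tracks one 30-frame
contraction nine times (3 examiners × 3 days analogue) with jittered
annotations.  Statistics oracles run 200 random ICC matrices and 100
random waveform sets.
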