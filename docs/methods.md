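# Methods note

This note records the model behind `pldstim`, the parameter defaults and
their units, what the synthetic motion generator does and does not emulate,
and the numerical choices made in the implementation. No empirical claim is
made here beyond what the test suite and `scripts/acceptance.py` actually
compute.

## Coordinate and capture conventions

All motion lives in a right-handed, y-up world measured in metres. Yaw 0
faces +z. Capture clips run at 120 Hz; the stimulus unit is a 3-second
window, i.e. 360 frames. Marker data arrive as a 41-marker full-body set
(head band, torso, and limb clusters); the canonical skeleton is the
13-joint set `head, l/r shoulder, l/r elbow, l/r wrist, l/r hip, l/r knee,
l/r ankle`, produced by averaging each joint's marker cluster per frame
(`reduce_to_joints`). The default mapping uses the three head-band markers
for the head, marker pairs for shoulders, wrists, and hips, and single
markers for elbows, knees, and ankles.

## File formats

- **C3D**: a minimal reader/writer for the Intel-float variant (processor
  type 84, negative `POINT:SCALE` = float data). Only the `POINT` group
  parameters needed for marker trajectories are written (`USED`, `FRAMES`,
  `RATE`, `SCALE`, `UNITS`, `DATA_START`, `LABELS`). The reader rejects
  integer-format files and non-Intel processor types rather than guessing.
  Millimetre files are converted to metres on read. Positions are stored as
  float32, so round-trips are exact to ~6e-8 m.
- **TRC**: the 5-line tab-separated header variant, mm → m on read.
- **CSV**: a wide dialect, `frame,time,<label>_x,<label>_y,<label>_z,...`,
  with a uniform-time check.
- **Joint clips**: JSON schema `pldstim.jointclip/1` (rate, joint names,
  positions, optional events/metadata).

## Synthetic motion generator

Real capture data cannot ship with the package, so fixtures are generated:

- `make_walker` builds an in-place gait from sinusoidal oscillators:
  contralateral ankles phase-opposed by half a cycle, arm swing opposed to
  the ipsilateral leg, small vertical bob. Defaults: cycle frequency 1.0 Hz,
  ankle amplitude 0.30 m, wrist amplitude 0.20 m, knee lift 0.06 m, vertical
  bob 0.03 m, hip height 0.95 m. `noise_sd` adds a *constant per-joint*
  offset (a marker-placement-error analogue) rather than per-frame noise, so
  the trajectory stays exactly periodic.
- `make_gesture` interpolates piecewise-linearly between sparse keyframe
  poses (partial joint dictionaries over the neutral standing pose), holding
  the pose before the first and after the last keyframe.
- `make_dyad_fixture` builds an initiator/responder pair: the responder is
  pinned to the neutral pose until its onset (default 1.5 s — half of the
  3-second clip) and then plays its script.
- `expand_to_markers` inverts the joint reduction: each joint is surrounded
  by a zero-mean marker cluster with fixed offsets, and unmapped markers
  ride on interpolated joint pairs. Because clusters are zero-mean,
  `reduce_to_joints(expand_to_markers(clip))` recovers the input to < 1e-9 m.

What the generator emulates: the kinematic *structure* that the pipeline
depends on (13 joints, 120 Hz, 3 s, periodic gait, responder onset, a
catalogue with ≥ 2 actions per category and congruent communicative pairs).
What it does not emulate: biomechanically realistic joint angles, ground
contact, soft-tissue artefacts, inter-actor variability, or any specific
recorded action. None of the package's guarantees depend on realism — only
on the structural invariants above, which the tests check explicitly.

## Scene composition

`place_agents` puts a dyad symmetrically about the midline at
(∓ separation/2, 0) with yaws 90° / −90°, facing each other along x; the
default separation is 3 m. Agents must share frame count and rate. Scenes
are constrained to a 7 × 3.5 m subspace (half-width 3.5 m in x, 3.5 m in z),
with an exemption for contact-flagged actions that must cross the midline.
Congruency of a pairing is "congruent" iff one action lists the other as a
congruent partner, or both are emotional/synchronous actions sharing a
situation tag. `label_scene` maps communicative, happy, angry, and
synchronous categories to "interaction" and object-/non-object-related
actions to "individual".

## Display operations

- **Scrambling** (`scramble`): per marker, draw an axis uniformly from
  {x, y, z} and a sign uniformly from {−, +}; displace the whole trajectory
  by `level/100` metres along that axis. The offset is constant in time, so
  the velocity time series is bit-for-bit unaffected (verified to 1e-12 in
  tests); offsets for the same seed compose additively.
- **Flicker** (`flicker`): per marker, alternate visible/invisible segments
  with durations uniform in `duration_range` (default 0.1–0.5 s), subject to
  a hard cap `max_visible` ∈ [0, 13] on simultaneously visible markers.
  Scheduling is greedy in a seeded random marker order with up to 100
  redraws per marker; if no redraw fits, the marker's visible segments are
  truncated at capacity-full frames. Pure whole-schedule resampling cannot
  satisfy low caps (e.g. 5 of 13 with ~50 % duty cycles), hence the repair
  step; `strict=True` raises `FlickerSchedulingError` instead of repairing.
  Cap 0 blanks the display; cap ≥ 13 makes schedules independent.

## Camera and rendering

Perspective projection is the pinhole model with focal length
`f = (h/2)/tan(fov/2)` pixels (h = image height); a dot of world radius r at
camera depth z has screen radius `f·r/z`. Orthographic projection scales by
`(h/2)/size` and gives every dot the same radius (no depth cue from size).
Dot size is specified as a diameter in centimetres (default 6 cm).
Presets place the camera 15 m from the scene centre at 1 m height:
front (0, 1, −15), right (−15, 1, 0), back (0, 1, 15), left (15, 1, 0), all
looking at (0, 1, 0). Euler rotation is applied as R = Ry·Rx·Rz and the
camera looks along its local +z axis. Occlusion uses the painter's
algorithm (farthest dot first). Frames are rasterised at 4× resolution and
downsampled with a Lanczos filter for anti-aliasing. Video export uses
imageio/FFMPEG when present; otherwise it emits a RuntimeWarning and writes
a lossless PNG sequence (or raises `EncoderUnavailableError` when
`png_fallback=False`).

## Validation harness

- **Pseudorandomisation**: trial orders with no more than `max_run`
  (default 2) same-category trials in a row, built by seeded weighted
  sequential draws with restarts. Feasibility is checked up front with the
  bound `c_max ≤ max_run · (n − c_max + 1)`.
- **Simulated responders**: each stimulus category has a Bernoulli success
  profile. Classification of interactions and dichotomously scored
  identification use 0/2 scoring; per-action identification of individual
  actions is scored 0–2 (binomial over two actions). Two designated
  emotional items are excluded from the classification denominator, mirroring
  a common design choice of dropping ill-fitting items.
- **Statistics**: one-way repeated-measures ANOVA from the explicit
  sums-of-squares partition (F = MS_cond/MS_resid with df (k−1, (n−1)(k−1)),
  partial eta squared = SS_cond/(SS_cond+SS_resid)), and the Friedman test
  with the average-rank tie correction. Both are cross-checked in the test
  suite against `pingouin.rm_anova` and `scipy.stats.friedmanchisquare` on
  fixed tables. Outlier screening removes a participant whose score is more
  than 3 SD from the group mean in at least 2 conditions; the SD includes
  the candidate (the more conservative convention).
- **Studies**: Study 1 presents a 58-item, six-category set (defaults:
  COM 10, ANGRY 10, HAPPY 10, SYNC 8, NORA 11, ORA 9 — all configurable) and
  reports classification and identification tables plus rm-ANOVA/Friedman
  across categories. Study 2 presents single agents at 0/15/30/100 %
  scrambling with a monotone human-resemblance responder profile
  (0.98/0.68/0.20/0.03) and asks whether the pipeline recovers a strictly
  decreasing curve and a significant condition effect. The profile is an
  *input* to the simulation, never asserted as an empirical output.

## Numerical choices

- Trimming uses a half-open window [t0, t1) with `i0 = round(t0·rate)` and
  `n = round((t1−t0)·rate)`, so a 3 s trim at 120 Hz is exactly 360 frames.
- Smoothing is a Savitzky–Golay filter (default window 11, order 3) with
  mirror padding, chosen over zero padding to avoid endpoint transients.
- Resampling is per-coordinate linear interpolation.
- Seeds for sub-tasks are derived via `numpy.random.SeedSequence` from the
  one user seed plus a purpose string, reduced modulo 2³¹−1; all derived
  seeds therefore stay below 2³¹ and distinct purposes decorrelate streams.
- Reported ANOVA degrees of freedom always follow the standard
  (k−1, (n−1)(k−1)) rule for the realised sample size.

## Limitations

- The C3D support covers only Intel-float trajectory data — no analog
  channels, events, or DEC/MIPS variants.
- The synthetic generator is a structural stand-in, not a biomechanical
  model; results about recognition rates are properties of the simulated
  responder profiles, not of human perception.
- Flicker's truncation repair can shorten visible segments below the
  requested minimum duration near capacity; `strict=True` is available when
  exact segment durations matter more than completion.
- The rm-ANOVA is the one-way repeated-measures case without sphericity
  correction; for heavily non-spherical data the Friedman test is reported
  alongside it.
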