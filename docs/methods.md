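# Methods

## The measurement model

A single 9-DoF IMU is worn between the scapulae with the sensor Y axis
along the spine and X across the shoulders. Its orientation at time
*t* is a unit quaternion `q_t` mapping sensor coordinates to a fixed
world frame (X north, Z up). A static accelerometer reads the specific
force `Rᵀ(q)·(0,0,g)` with `g = 9.81 m/s²`; the magnetometer reads a
fixed earth field rotated into the sensor frame; the gyroscope reads
body rates in deg/s.

The quantity that matters for coaching is the **angle of approach**:
the elevation of the spine axis above the player's own reference
horizontal plane. With `q_rel = q_ref⁻¹ ⊗ q_t` the relative orientation
against the calibrated reference pose, the angle is

    α = asin( (R(q_rel) ŷ)_z )   (degrees at the interface)

For a pure rotation about the shoulder axis this equals the relative
pitch; unlike raw Euler pitch it remains meaningful when roll and yaw
mix into the motion, and it is insensitive to spin about the vertical.
A tackle is **SAFE** when `|α| ≤ 10°` (half-width and boundary rule
configurable; the boundary is inclusive by default, a deliberate
convention since "ten degrees above/below" leaves the exact edge
undefined).

## Conventions

- Quaternions are `(w, x, y, z)`, scalar first — forced by logged data,
  where the component labelled 0 sits at 1.00 in a near-identity pose.
  `q` and `−q` are the same rotation; every conversion canonicalises
  the sign first, and passthrough estimation enforces hemisphere
  continuity sample to sample.
- Euler angles use the aerospace ZYX (yaw-pitch-roll) sequence. The
  formulas are the standard ones quoted in the README. Gimbal proximity
  (`|sin pitch| → 1`) is flagged on the result, not raised: the tackle
  regime keeps pitch far from ±90°.
- Axis-angle is canonical with angle in `[0, π]`; the identity rotation
  reports axis `(1, 0, 0)` by convention.
- Radians internally, degrees at every user-facing surface.

## Log format

The 38-field Shimmer-style vocabulary (`Timestamp_RAW/CAL`, raw and
calibrated triplets for both accelerometers, gyroscope, magnetometer,
pressure/temperature pairs, `Axis_Angle_{A,X,Y,Z}_CAL`,
`Quaternion_{0..3}_CAL`) is parsed from tab- or comma-delimited text in
either layout — readings as rows (field devices) or as columns (printed
dumps) — auto-detected from where `Timestamp_RAW` appears. Thousands
separators and the typographic minus are stripped. Values are kept at
full parsed precision; two-decimal rounding in printed dumps is display
only. Unparseable cells and missing fields are hard errors, never
silent nulls; duplicated calibrated timestamps are an ordering error.

The raw timestamp tick rate is **inferred, not specified**: logged data
show 6400 ticks per 195.31 ms, i.e. 32768 ticks/s, which is the
default `ticks_per_second` and remains configurable.

Validation tolerances on logged orientations: onboard quaternion norm
within 0.02 of 1 (absorbs two-decimal component rounding); axis norm
within 0.05 of 1, checked only when the angle exceeds 0.05 rad because
below that the axis direction is numerically meaningless.

## Attitude estimation

`passthrough` (default) trusts the onboard fusion output. The
`complementary` filter re-creates orientation from raw channels: the
gyroscope is integrated exactly via the quaternion exponential, and
each step is slerped a fraction `gain = 0.02` (per sample) toward a
TRIAD-style fix built from the measured gravity direction and the
horizontal magnetic component. The filter initialises from the first
sample's fix, so a static stream is tracked immediately; the gain
trades gyro-drift rejection against accelerometer transients. Whether
the vendor's onboard filter matches this one is unknowable from logs
alone — passthrough mode exists precisely so recorded data never
depend on that question.

## Calibration

The reference pose is the sign-aligned, normalised component mean of
the quaternions inside a user-chosen window (default: the first 1.5 s).
This chordal mean is accurate for tight clusters and is a documented
limitation beyond ~30° dispersion, where an eigen-decomposition mean
would be needed. The stillness gate rejects windows whose maximum
angular deviation from the mean exceeds 3° (default). That gate is a
noise-floor parameter, not a constant of nature: per-sample orientation
noise of σ per axis produces window maxima around 3–4σ, so a sensor
noisier than ~0.75° needs a proportionally wider gate (the test suite
uses 6° for its 1° noise condition). The zero reference is an explicit
input — the toolkit deliberately does not guess whether a team's zero
is the upright stand or the hinged approach pose; whatever posture is
held in the window defines zero.

## Event segmentation and labelling

An event opens when the wide-range acceleration magnitude crosses
25 m/s² (default; comfortably above the 9.81 m/s² gravity baseline and
below the ~80 m/s² contact transients) and closes after 300 ms below
threshold; nearer crossings merge. Both parameters are configurable —
continuous streams need *some* segmentation rule and no canonical one
exists for this task.

The label is computed from the approach angle **at contact, estimated
over a ±100 ms window** centred on the acceleration peak (mean of the
per-sample angles). A single-sample estimate at the peak instant would
carry the full per-sample orientation noise σ, making boundary-adjacent
commands (±12° against a ±10° band) misclassifiable at the percent
level; averaging ~11 samples cuts the error to ≈ σ/√11 while the
commanded angle is held through contact. The single peak-sample value
is retained as `approach_angle_instant_deg` for diagnostics. Shoulder
side is a protocol annotation (scripted per trial), never inferred from
the signals.

## The simulator

`synth` emulates the static tackle drill: calibration stand, then ten
contacts alternating left/right shoulder at commanded angles (0° safe;
±12° unsafe — just outside the band, matching a drill scripted
"roughly ten degrees above and below" the tolerance edge). The torso
rotates about the shoulder axis along a raised-cosine ramp (300 ms),
holds the commanded angle ±100 ms around impact, and returns. Impacts
are half-sine pulses (50 ms, peak 80 m/s²) on the wide-range channel
along the spine axis. The gyroscope channel is the exact finite-
difference derivative of the quaternion trajectory, so integrating it
reproduces the trajectory to numerical precision — a self-consistency
the tests assert. The magnetometer field is 0.5 cgs at 60° inclination,
arbitrary but fixed. Onboard quaternion/axis-angle fields carry the
true orientation perturbed per sample by a random rotation with
per-axis rotation-vector components N(0, σ), σ = 0.5° by default.

Defaults chosen once and held: 51.2 Hz sampling (a typical logging
rate for this sensor class; it also gives an integer 640-tick interval
at 32768 ticks/s), first impact at 2.5 s, 1.5 s spacing. Raw-channel
counts are synthesised with nominal gains for format fidelity only —
analysis reads calibrated channels exclusively.

What the simulator does *not* model: linear (non-gravitational)
acceleration during the approach run, soft-tissue sensor wobble,
magnetic disturbance, temperature drift, or a jointed body — it moves
exactly one sensor frame, which is all the platform measures. Passing
tests therefore demonstrate the correctness of the pipeline's
geometry, segmentation and classification under the drill's stated
noise conditions, not robustness to every artefact of real wearables.

## Problem sizes

The test suite's stochastic checks use 1000 random rotations for the
conversion round-trips, an 801-point angle grid for the classifier
properties, and 100 seeded three-tackle simulations (σ = 0.5°, commands
0°/+15°/−15°) for end-to-end label recovery; the acceptance script runs
both full ten-tackle drills. These sizes resolve the claimed tolerances
comfortably while keeping a full run in well under a minute.

## Known limitations

- No impact-force estimation; the peak acceleration is reported as a
  segmentation feature, not a biomechanical load.
- Static drills only: no dynamic, in-play tackles, and no adjustment of
  the optimal angle per scenario.
- The chordal-mean calibration degrades for dispersions beyond ~30°.
- Shoulder side requires a protocol annotation.
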