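# Methods

This note documents the modelling and numerical choices behind
`motionbids`: what the package assumes, which knobs matter, what the
synthetic data does and does not emulate, and where the design was
genuinely open.

## Data model

A recording is a **tracking system**: channels that synchronously sample
motion data from one or more tracked points, sharing sampling rate and
duration, stored as one headerless TSV whose column order is defined by
the row order of the companion `channels.tsv`. The channel-type vocabulary
is closed at ten codes (POS, ORNT, VEL, ACCEL, ANGACC, GYRO, MAGN, JNTANG,
LATENCY, MISC), each in bijection with a `<CODE>ChannelCount` sidecar
field. A channel's `component` is a Cartesian axis (`x`/`y`/`z`), a
quaternion element (`quat_x`/`quat_y`/`quat_z`/`quat_w`), or `n/a` for
non-spatial channels.

Internal conventions: time is always seconds; angle values keep each
channel's declared units (`deg`/`rad`) with explicit unit arguments on
conversion functions — nothing is converted silently; missing TSV cells
(the `MissingValues` string, default `n/a`) become NaN in the sample
matrix; `status` defaults to `good` when absent; LATENCY channels carry
component `n/a` and units `s`.

Structural invariants (column/channel count agreement, unique channel
names) are enforced at construction. The remaining invariants — latency
monotonicity, reference-frame label resolution — are enforced by
`TrackingSystem.validate()`, which strict loading calls; the validator
loads leniently instead so that violations in untrusted trees surface as
ordered findings rather than exceptions.

## Validator

Requirement levels map fixedly to severities: REQUIRED→error,
RECOMMENDED→warning, OPTIONAL→info. Findings are sorted by (path,
rule id, message), with paths relative to the dataset root, making reports
byte-identical across runs and machines. Two matrices the standard leaves
open are treated conservatively:

- **Component/type compatibility** (e.g. GYRO with `quat_x`) violations
  are warnings, not errors, since no normative table exists. The matrix
  used: POS/VEL/ACCEL/GYRO/ANGACC/MAGN → {x,y,z}; ORNT → {x,y,z} ∪
  {quat_*}; JNTANG → {x,y,z,n/a}; LATENCY/MISC → n/a.
- **Quaternion-group completeness** is checked per (tracked point,
  reference frame) at warning severity: the component labels are
  normative, the grouping is not.
- `MotionChannelCount` is compared against the count of non-LATENCY
  channels; LATENCY is counted by its own field. The `tracked_point`
  column is REQUIRED (error when empty). Unrecognized unit strings only
  warn, as no units vocabulary is prescribed. Header-only `events.tsv`
  files are valid.

## Rotations

Euler input is restricted to the six extrinsic Tait-Bryan sequences;
repeated-axis orders (XYX, …) are rejected. For order P→Q→R the matrix is
`R_R(θ₃)·R_Q(θ₂)·R_P(θ₁)` with right-hand elemental rotations; the
left-hand rule sign-flips all angles before composition, so the two rules
are related by angle negation (a tested identity). Conversions are
computed with `scipy.spatial.transform.Rotation` (lowercase = extrinsic);
the test suite checks them against an independently hand-rolled
elemental-matrix composition, keeping implementation and oracle on
separate routes.

Quaternions are Hamilton, scalar-first `(w, x, y, z)` internally, mapped
to the `quat_w`/`quat_x`/`quat_y`/`quat_z` channel labels on I/O, and
canonicalized to `w ≥ 0` so round trips are deterministic (q and −q denote
the same rotation). The handedness rule is assumed to govern only the
Euler-angle interpretation; quaternion channels are always read as
right-hand Hamilton. This is an assumption, not a prescription of the
standard.

At gimbal lock (|middle angle| = 90°, detected by scipy's threshold on the
coupling matrix element) the third angle is set to zero and the degenerate
degree of freedom folded into the first angle; the condition is reported
through a boolean flag so callers can mark affected samples.

## SpatialAxes remapping

A `SpatialAxes` string assigns one letter per axis slot: A/P
(anterior-posterior), L/R (left-right), S/I (superior-inferior), `_` for
unused. Internally A, R, S are the positive ends of the three anatomical
dimensions; the map between two conventions is the exact signed
permutation M with `M[i,j] = ±1` where target axis i and source axis j
name the same (opposite) letter. Composition and inversion are exact
integer identities — no floating-point rotation is involved. Orientation
channels are conjugated, `R ↦ M·R·Mᵀ`; when det(M) = −1 the conjugated
matrix is still a proper rotation but the positive sense of rotation about
every axis flips, so the frame's RotationRule is toggled and the flip
reported. Partial (1D/2D) axes strings support position remapping onto the
available dimensions only; orientation remapping requires full 3-axis
source and target.

## Timing and alignment

Per-sample times come from, in order of precedence: the LATENCY channel
verbatim; a uniform grid at `SamplingFrequencyEffective`; a uniform grid
at the nominal `SamplingFrequency`. When a LATENCY channel disagrees with
the nominal rate by more than 5 % the package warns and proceeds with the
LATENCY channel — the recorded timestamps are taken as ground truth.
Effective rate is the endpoint estimator `(n−1)/(t_{n−1}−t_0)`.

The shared clock is built from `scans.tsv` `acq_time` values
(ISO-8601, optional fractional seconds, timezone-naive permitted and
compared only within one dataset); the earliest acquisition defines global
zero, keeping all global times non-negative. Recordings without an
`acq_time` fall back to offset 0 with a recorded warning.

Resampling uses linear interpolation per channel, with NaN outside the
recorded span and duplicate timestamps collapsed to the first occurrence.
Quaternion quadruples are interpolated as 4-vectors and renormalized
(normalized lerp). For the small inter-sample rotations typical of
≥ 60 Hz motion capture, nlerp and slerp differ by O(Δθ²) within a sample
step; slerp was deliberately not implemented. This is a documented
limitation for low-rate recordings of fast rotations.

## Synthetic data

The generator emulates four study layouts at desk scale (6–10 s, 60–120
Hz, one subject): a gait IMU with heel-strike events; dual
virtual/optical head tracking with jittered per-sample latencies and a
0.25 s acquisition-onset offset; one tracking system per tracked body
part; and an IMU/optical pair with distinct `local`/`global` reference
frames. Trajectories are smooth closed forms — sinusoidal yaw
`θ(t) = A·sin(2πft)` about the vertical axis for head rotation;
constant-velocity walking with a small sinusoidal vertical bob — so
angular velocity and acceleration have analytic references. Inertial
signals follow from the trajectory: gyroscope readings are body-frame
angular velocity from finite-difference relative rotations; accelerometer
readings are world linear acceleration plus the gravity vector
(0, 0, −9.81 m/s²) rotated into the body frame (norm 9.81 at rest);
magnetometer readings are a fixed unit field along the anterior axis in
the body frame. Timestamp jitter is Gaussian (default σ = 1 ms), sorted
and pinned to start at zero. The global frame uses SpatialAxes `ARI`.
Heel-strike events sit at stride-phase zero crossings. Default problem
sizes (≤ 1000 samples per system) keep the full test suite and the
acceptance script in the seconds range.

What the generator does **not** emulate: soft-tissue artifact, marker
occlusion and dropout beyond uniform missing values, sensor bias and
drift, clock drift between systems, biomechanically realistic gait.
Passing tests therefore demonstrate the correctness of the data
organization, conversion and alignment machinery — not robustness to the
messiness of real capture hardware.

## Known limitations

- Derived-data layouts and proprietary source formats (.mvnx, .c3d) are
  out of scope; only raw BIDS trees are read and written.
- Nested or interrelated reference frames are not represented; each frame
  is independent.
- Alignment uses `scans.tsv` timestamps only; no cross-correlation or
  clock-drift estimation.
- Anatomical nomenclature for sensor placement is free text.
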