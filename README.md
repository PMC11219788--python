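# motionbids

Tools for reading, writing, validating and harmonizing motion-capture
datasets organized under the Brain Imaging Data Structure (BIDS).

Motion data — positions and orientations of tracked body parts or virtual
objects, and their derivatives from IMU-based systems — is increasingly
recorded alongside EEG, fNIRS and other neuroimaging modalities. Under the
motion extension of BIDS, each *tracking system* (a group of channels that
synchronously sample motion data) is stored as one headerless tab-separated
time series `sub-<label>_task-<label>_tracksys-<label>_motion.tsv`, whose
column order matches the row order of the companion `*_channels.tsv`, with
required metadata (sampling rate, channel counts, reference-frame
descriptions) in JSON sidecars. This package implements that organization
as a library plus a command-line tool, for researchers who convert,
curate, or jointly analyze such datasets.

## What it does

- **Filename grammar** — parse and build entity-based names
  (`sub`, `ses`, `task`, `tracksys`, `run` + suffix), with strict entity
  order and round-trip fidelity.
- **I/O** — headerless numeric `motion.tsv`, headered `channels.tsv`
  (10-code channel-type vocabulary: POS, ORNT, VEL, ACCEL, ANGACC, GYRO,
  MAGN, JNTANG, LATENCY, MISC), JSON sidecars including the
  `reference_frame.Levels` structure, `events.tsv` and `scans.tsv`.
- **Validation** — 18 rules mapping REQUIRED / RECOMMENDED / OPTIONAL
  clauses to error / warning / info findings: required columns and fields,
  vocabulary closure, channel/column count agreement, `SpatialAxes`
  grammar, rotation-order keywords, latency monotonicity, scans
  resolution, and more.
- **Rotations** — extrinsic Tait-Bryan Euler angles ↔ quaternions for all
  six axis orders (XYZ … ZYX) and both rotation rules. For order
  P→Q→R with angles θ₁,θ₂,θ₃ the rotation matrix is
  R = R_R(θ₃)·R_Q(θ₂)·R_P(θ₁) about the *fixed* axes; the left-hand rule
  negates all angles. Gimbal lock (middle angle ±90°) is detected and
  flagged; the degenerate degree of freedom is folded into the first angle.
- **Axis remapping** — exact signed-permutation changes of basis between
  `SpatialAxes` conventions (e.g. `"ARI"`: X-anterior, Y-right,
  Z-inferior), including quaternion conjugation q ↦ M·R(q)·Mᵀ and
  automatic handedness-rule toggling for improper (det = −1) maps.
- **Synchronization** — per-sample latency reconstruction (`i/fs`),
  effective-sampling-rate estimation `(n−1)/(tₙ₋₁−t₀)`, shared timelines
  from `scans.tsv` acquisition times, and resampling of multiple systems
  onto a common grid (normalized linear interpolation for quaternion
  quadruples).
- **Synthetic datasets** — a deterministic generator of small, fully valid
  dataset trees (gait IMU with heel-strike events, dual virtual/optical
  head tracking with offset onsets, per-body-part systems, IMU + optical
  with local/global frames) used throughout the test suite.

## Worked example

```sh
$ motionbids generate demo --scenario fig1_gait --seed 42
demo
$ motionbids inspect demo
sub-001_task-walk_tracksys-imu_motion.tsv
  tracksys: imu, fs: 100.0 Hz, samples: 1000, duration: 9.99 s
  channels: ACCEL:3, GYRO:3
$ motionbids validate demo
0 error(s), 0 warning(s)
```

The generated tree holds one subject walking for 10 s while a wearable IMU
on the left ankle samples three accelerometer and three gyroscope channels
at 100 Hz, with heel-strike events and a `scans.tsv` acquisition time. The
validator confirms the tree satisfies every rule.

The same from Python, aligning two tracking systems recorded with a 0.25 s
onset difference:

```python
from motionbids import (generate_dataset, scan_dataset,
                        load_tracking_system, build_timeline)
from motionbids.timing import recording_id

inv = generate_dataset("demo2", "spotrotation_like", seed=42)
systems = [load_tracking_system(inv.root, r.entities) for r in inv.recordings]
timeline = build_timeline(systems, inv.scans["001"][1])
print(timeline.offsets)
# {'sub-001_task-rotation_tracksys-optical_motion.tsv': 0.25,
#  'sub-001_task-rotation_tracksys-virtual_motion.tsv': 0.0}
```

The 0.25 s offset injected through `scans.tsv` acquisition timestamps is
recovered exactly.

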