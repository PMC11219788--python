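"""Deterministic generator of ground-truth motion trajectories and complete,
valid motion datasets for testing and demonstration.

The generator produces small BIDS trees covering the typical study layouts:
a single wearable IMU with gait events; head rotation recorded concurrently
by a virtual (quaternion) and an optical (position + Euler) system with
offset acquisition onsets; one tracking system per tracked body part; and an
IMU/optical combination with distinct local/global reference frames.

All trajectories are smooth closed forms, so derived quantities (angular
velocity, acceleration) have analytic references, and the same seed always
produces a byte-identical tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .model import (
    Channel,
    ChannelType,
    Component,
    EntitySet,
    EventTable,
    ReferenceFrame,
    ScansTable,
    Suffix,
    TrackingSystem,
    TrackingSystemMeta,
    channel_count_field_name,
)
from . import bids_io
from .bids_io import DatasetInventory, relative_data_path, save_tracking_system
from .spatial import euler_to_quat, quat_to_euler

import pandas as pd

__all__ = [
    "TrajectoryConfig",
    "simulate_rigid_body",
    "simulate_imu",
    "jittered_latency",
    "generate_dataset",
    "SCENARIOS",
]

#: Gravitational acceleration applied along the world −Z axis, m/s².
GRAVITY = 9.81

#: World magnetic field: unit vector along the anterior (X) axis.
MAGNETIC_FIELD = np.array([1.0, 0.0, 0.0])

#: SpatialAxes of the generated global frame: X-anterior, Y-right, Z-inferior.
GLOBAL_AXES = "ARI"


@dataclass
class TrajectoryConfig:
    """Parameters of one simulated rigid-body recording.

    ``amplitude`` is degrees for ``head_rotation`` (peak yaw) and m/s for
    ``straight_walk`` (walking speed); ``frequency`` is the oscillation or
    stride rate in Hz.  ``jitter_sd`` is the per-sample timestamp jitter in
    seconds (0 disables the latency channel jitter).
    """

    duration: float = 10.0
    fs: float = 100.0
    trajectory: str = "head_rotation"
    amplitude: float = 60.0
    frequency: float = 0.25
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.trajectory not in ("head_rotation", "straight_walk", "static"):
            raise ValueError(f"unknown trajectory {self.trajectory!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def simulate_rigid_body(cfg: TrajectoryConfig):
    """Simulate a tracked rigid point: returns ``(times, positions,
    quaternions)`` with positions (n, 3) in meters and scalar-first unit
    quaternions (n, 4).

    * ``head_rotation``: sinusoidal yaw θ(t) = A·sin(2πft) about the
      vertical (Z) axis at a fixed position.
    * ``straight_walk``: constant-velocity translation along the anterior
      (X) axis with a small sinusoidal vertical bob; identity orientation.
    * ``static``: constant position and orientation.
    """
    times = np.arange(cfg.n_samples) / cfg.fs
    n = times.size
    positions = np.zeros((n, 3))
    if cfg.trajectory == "head_rotation":
        positions[:, 2] = -1.7  # head height above the floor (Z points down)
        yaw = cfg.amplitude * np.sin(2 * np.pi * cfg.frequency * times)
        angles = np.zeros((n, 3))
        angles[:, 0] = yaw  # first (and only) rotation, about Z
        quats = euler_to_quat(angles, order="ZYX", degrees=True)
    elif cfg.trajectory == "straight_walk":
        positions[:, 0] = cfg.amplitude * times
        positions[:, 2] = -1.0 + 0.02 * np.sin(2 * np.pi * cfg.frequency * times)
        quats = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    else:  # static
        positions[:] = (0.1, 0.2, -1.0)
        quats = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    return times, positions, quats


def simulate_imu(times, positions, quats, noise_sd: float = 0.0, rng=None):
    """Derive body-frame inertial/magnetic signals from a trajectory:
    returns ``(accel, gyro, magn)``, each (n, 3).

    * GYRO: body-frame angular velocity from finite differences of the
      orientation (relative-rotation vectors divided by the sample step).
    * ACCEL: world linear acceleration plus the gravity vector
      (0, 0, −9.81) m/s², rotated into the body frame — at rest the
      reading is gravity with norm 9.81.
    * MAGN: the fixed world field rotated into the body frame.

    Gaussian noise of standard deviation ``noise_sd`` (per component, in
    each signal's own units) is added when a generator is supplied.
    """
    times = np.asarray(times, dtype=float)
    rot = Rotation.from_quat(np.roll(np.asarray(quats, dtype=float), -1, axis=1))
    n = times.size

    # world-frame linear acceleration by twice-applied central differences
    vel = np.gradient(positions, times, axis=0)
    acc = np.gradient(vel, times, axis=0)
    specific_force = acc + np.array([0.0, 0.0, -GRAVITY])
    accel = rot.inv().apply(specific_force)

    gyro = np.zeros((n, 3))
    if n > 1:
        dt = np.diff(times)
        rel = rot[:-1].inv() * rot[1:]
        gyro[:-1] = rel.as_rotvec() / dt[:, None]
        gyro[-1] = gyro[-2]

    magn = rot.inv().apply(np.tile(MAGNETIC_FIELD, (n, 1)))

    if rng is not None and noise_sd > 0:
        accel = accel + rng.normal(0.0, noise_sd, accel.shape)
        gyro = gyro + rng.normal(0.0, noise_sd, gyro.shape)
        magn = magn + rng.normal(0.0, noise_sd, magn.shape)
    return accel, gyro, magn


def jittered_latency(n_samples: int, fs: float, jitter_sd: float, rng) -> np.ndarray:
    """Per-sample timestamps with Gaussian jitter around the nominal grid,
    shifted to start at 0 and forced strictly increasing."""
    latency = np.arange(n_samples) / fs
    if jitter_sd > 0:
        latency = latency + rng.normal(0.0, jitter_sd, n_samples)
        latency = np.sort(latency)
        latency -= latency[0]
        diffs = np.diff(latency)
        if np.any(diffs <= 0):  # astronomically rare at sane jitter levels
            latency = np.concatenate([[0.0], np.cumsum(np.maximum(diffs, 1e-9))])
    return latency


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------


def _triax_channels(point: str, ctype: ChannelType, units: str,
                    reference_frame=None) -> list:
    return [
        Channel(name=f"{point}_{ctype.value}_{axis}", component=Component(axis),
                type=ctype, tracked_point=point, units=units,
                reference_frame=reference_frame)
        for axis in ("x", "y", "z")
    ]


def _latency_channel(point: str) -> Channel:
    return Channel(name=f"{point}_LATENCY", component=Component.na,
                   type=ChannelType.LATENCY, tracked_point=point, units="s")


def _meta(fs: float, channels, tracked_points: int, name: str,
          latency=None) -> TrackingSystemMeta:
    counts: dict = {}
    for c in channels:
        key = channel_count_field_name(c.type)
        counts[key] = counts.get(key, 0) + 1
    motion = sum(v for k, v in counts.items() if k != "LATENCYChannelCount")
    counts["MotionChannelCount"] = motion
    meta = TrackingSystemMeta(
        sampling_frequency=fs,
        tracking_system_name=name,
        tracked_points_count=tracked_points,
        channel_counts=counts,
    )
    if latency is not None and len(latency) >= 2:
        from .timing import effective_fs

        meta.sampling_frequency_effective = round(float(effective_fs(latency)), 6)
    return meta


def _scans_table(entries) -> ScansTable:
    frame = pd.DataFrame(entries, columns=["filename", "acq_time"])
    return ScansTable(frame)


def _events(onsets, trial_type: str, durations=None) -> EventTable:
    frame = pd.DataFrame({
        "onset": np.round(np.asarray(onsets, dtype=float), 6),
        "duration": durations if durations is not None else 0.0,
        "trial_type": trial_type,
    })
    return EventTable(frame)


def _build_fig1_gait(seed: int):
    """One wearable IMU on the left ankle during straight walking, with
    heel-strike events at stride-phase zero crossings."""
    rng = np.random.default_rng(seed)
    cfg = TrajectoryConfig(duration=10.0, fs=100.0, trajectory="straight_walk",
                           amplitude=1.2, frequency=1.0, seed=seed)
    times, pos, quats = simulate_rigid_body(cfg)
    accel, gyro, _ = simulate_imu(times, pos, quats, noise_sd=0.05, rng=rng)

    point = "LeftAnkle"
    channels = (_triax_channels(point, ChannelType.ACCEL, "m/s^2")
                + _triax_channels(point, ChannelType.GYRO, "rad/s"))
    samples = np.hstack([accel, gyro])
    entities = EntitySet(subject="001", task="walk", tracksys="imu",
                         suffix=Suffix.motion, extension="tsv")
    system = TrackingSystem(entities=entities,
                            meta=_meta(cfg.fs, channels, 1, "wearable IMU"),
                            channels=channels, samples=np.round(samples, 6))
    strikes = np.arange(1, int(cfg.duration * cfg.frequency)) / cfg.frequency
    events = _events(strikes, "heel_strike")
    scans = _scans_table([(relative_data_path(entities), "2024-01-15T10:00:00")])
    return [(system, events)], scans


def _build_spotrotation_like(seed: int):
    """Head rotation captured by two systems: the headset's own tracker
    (quaternions) and an optical system (positions + Euler angles), with a
    0.25 s acquisition-onset offset between them."""
    rng = np.random.default_rng(seed)
    frames = {
        "global": ReferenceFrame(
            label="global", spatial_axes=GLOBAL_AXES, rotation_rule="right-hand",
            rotation_order="ZYX",
            description="lab space; origin at the floor center below the participant",
        )
    }

    def head_cfg(fs):
        return TrajectoryConfig(duration=8.0, fs=fs, trajectory="head_rotation",
                                amplitude=60.0, frequency=0.25, jitter_sd=0.001,
                                seed=seed)

    systems = []

    # virtual (headset) system: quaternion orientations + latency
    cfg_v = head_cfg(90.0)
    times_v, _, quats_v = simulate_rigid_body(cfg_v)
    latency_v = jittered_latency(cfg_v.n_samples, cfg_v.fs, cfg_v.jitter_sd, rng)
    point = "Head"
    chan_v = [
        Channel(name=f"{point}_ORNT_{comp}", component=Component(comp),
                type=ChannelType.ORNT, tracked_point=point, units="n/a",
                reference_frame="global")
        for comp in ("quat_x", "quat_y", "quat_z", "quat_w")
    ] + [_latency_channel(point)]
    samples_v = np.column_stack([
        quats_v[:, 1], quats_v[:, 2], quats_v[:, 3], quats_v[:, 0], latency_v
    ])
    ent_v = EntitySet(subject="001", task="rotation", tracksys="virtual",
                      suffix=Suffix.motion, extension="tsv")
    sys_v = TrackingSystem(entities=ent_v,
                           meta=_meta(cfg_v.fs, chan_v, 1, "headset tracker",
                                      latency=latency_v),
                           channels=chan_v, samples=np.round(samples_v, 6),
                           reference_frames=dict(frames))
    peaks_v = (np.arange(2) + 0.25) / cfg_v.frequency  # yaw maxima
    systems.append((sys_v, _events(peaks_v, "rotation_peak")))

    # optical system: one tracked point, 3 POS + 3 Euler ORNT + latency = 7
    cfg_o = head_cfg(120.0)
    times_o, pos_o, quats_o = simulate_rigid_body(cfg_o)
    latency_o = jittered_latency(cfg_o.n_samples, cfg_o.fs, cfg_o.jitter_sd, rng)
    euler_zyx, _ = quat_to_euler(quats_o, order="ZYX", degrees=True)
    # angle-about-axis layout: components x/y/z hold the rotations about X/Y/Z
    euler_xyz_components = euler_zyx[:, ::-1]
    chan_o = (
        _triax_channels(point, ChannelType.POS, "m", reference_frame="global")
        + [Channel(name=f"{point}_ORNT_{axis}", component=Component(axis),
                   type=ChannelType.ORNT, tracked_point=point, units="deg",
                   reference_frame="global")
           for axis in ("x", "y", "z")]
        + [_latency_channel(point)]
    )
    samples_o = np.column_stack([pos_o, euler_xyz_components, latency_o])
    ent_o = ent_v.with_(tracksys="optical")
    sys_o = TrackingSystem(entities=ent_o,
                           meta=_meta(cfg_o.fs, chan_o, 1, "optical capture",
                                      latency=latency_o),
                           channels=chan_o, samples=np.round(samples_o, 6),
                           reference_frames=dict(frames))
    # same physical peaks, expressed relative to the later optical onset
    systems.append((sys_o, _events(peaks_v - 0.25, "rotation_peak")))

    scans = _scans_table([
        (relative_data_path(ent_v), "2024-03-01T09:30:00.000"),
        (relative_data_path(ent_o), "2024-03-01T09:30:00.250"),
    ])
    return systems, scans


def _build_dualtask_like(seed: int):
    """Optical tracking of several body parts with different temporal
    profiles — one tracking system (one motion.tsv) per tracked point."""
    parts = [("head", 60.0, -1.7), ("lankle", 100.0, -0.1)]
    systems = []
    entries = []
    for label, fs, height in parts:
        cfg = TrajectoryConfig(duration=6.0, fs=fs, trajectory="straight_walk",
                               amplitude=1.0, frequency=0.9, seed=seed)
        times, pos, _ = simulate_rigid_body(cfg)
        pos = pos + np.array([0.0, 0.0, height + 1.0])
        point = label.capitalize()
        channels = _triax_channels(point, ChannelType.POS, "m")
        ent = EntitySet(subject="001", task="dualtask", tracksys=label,
                        suffix=Suffix.motion, extension="tsv")
        system = TrackingSystem(entities=ent,
                                meta=_meta(fs, channels, 1, "optical capture"),
                                channels=channels, samples=np.round(pos, 6))
        strikes = np.arange(1, int(cfg.duration * cfg.frequency)) / cfg.frequency
        systems.append((system, _events(strikes, "heel_strike")))
        entries.append((relative_data_path(ent), "2024-05-20T14:00:00"))
    return systems, _scans_table(entries)


def _build_imu_plus_optical(seed: int):
    """A body-worn IMU reporting in its local sensor frame alongside an
    optical system reporting positions in the global lab frame."""
    rng = np.random.default_rng(seed)
    cfg = TrajectoryConfig(duration=6.0, fs=100.0, trajectory="head_rotation",
                           amplitude=45.0, frequency=0.5, seed=seed)
    times, pos, quats = simulate_rigid_body(cfg)
    accel, gyro, magn = simulate_imu(times, pos, quats, noise_sd=0.02, rng=rng)

    point = "Head"
    local = ReferenceFrame(
        label="local",
        description="sensor-fixed frame moving with the tracked point",
    )
    global_frame = ReferenceFrame(
        label="global", spatial_axes=GLOBAL_AXES, rotation_rule="right-hand",
        rotation_order="ZYX", description="lab space",
    )

    chan_imu = (_triax_channels(point, ChannelType.ACCEL, "m/s^2", "local")
                + _triax_channels(point, ChannelType.GYRO, "rad/s", "local")
                + _triax_channels(point, ChannelType.MAGN, "uT", "local"))
    ent_imu = EntitySet(subject="001", task="freewalk", tracksys="imu",
                        suffix=Suffix.motion, extension="tsv")
    sys_imu = TrackingSystem(
        entities=ent_imu, meta=_meta(cfg.fs, chan_imu, 1, "wearable IMU"),
        channels=chan_imu,
        samples=np.round(np.hstack([accel, gyro, magn]), 6),
        reference_frames={"local": local},
    )

    cfg_o = TrajectoryConfig(duration=6.0, fs=60.0, trajectory="head_rotation",
                             amplitude=45.0, frequency=0.5, seed=seed)
    _, pos_o, _ = simulate_rigid_body(cfg_o)
    chan_opt = _triax_channels(point, ChannelType.POS, "m", "global")
    ent_opt = ent_imu.with_(tracksys="optical")
    sys_opt = TrackingSystem(
        entities=ent_opt, meta=_meta(cfg_o.fs, chan_opt, 1, "optical capture"),
        channels=chan_opt, samples=np.round(pos_o, 6),
        reference_frames={"global": global_frame},
    )
    scans = _scans_table([
        (relative_data_path(ent_imu), "2024-06-10T11:00:00"),
        (relative_data_path(ent_opt), "2024-06-10T11:00:00.500"),
    ])
    return [(sys_imu, None), (sys_opt, None)], scans


SCENARIOS = {
    "fig1_gait": _build_fig1_gait,
    "spotrotation_like": _build_spotrotation_like,
    "dualtask_like": _build_dualtask_like,
    "imu_plus_optical": _build_imu_plus_optical,
}


def build_scenario(scenario: str, seed: int = 0):
    """In-memory form of a scenario: ``([(TrackingSystem, events|None), ...],
    ScansTable)``."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    return SCENARIOS[scenario](seed)


def generate_dataset(root, scenario: str, seed: int = 0) -> DatasetInventory:
    """Write a complete dataset tree for the scenario under ``root`` and
    return its inventory.  The same seed always yields a byte-identical
    tree."""
    root = Path(root)
    systems, scans = build_scenario(scenario, seed)
    for system, events in systems:
        save_tracking_system(system, root, events=events)
    subject = systems[0][0].entities.subject
    sub_dir = root / f"sub-{subject}"
    sub_dir.mkdir(parents=True, exist_ok=True)
    bids_io.write_scans_tsv(scans, sub_dir / f"sub-{subject}_scans.tsv")
    bids_io._dump_json(
        {"Name": f"synthetic motion dataset ({scenario})", "BIDSVersion": "1.9.0"},
        root / "dataset_description.json",
    )
    return bids_io.scan_dataset(root)
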