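"""Domain types and controlled vocabularies for motion recordings in BIDS.

The central abstraction is the *tracking system*: a group of channels that
synchronously sample motion data from one or more tracked points, stored as
one headerless ``*_motion.tsv`` whose column order matches the row order of
the companion ``*_channels.tsv``.  Sidecar metadata (sampling rate, channel
counts, reference-frame descriptions) lives in JSON files next to the TSVs.

Everything here is an in-memory type; file I/O lives in :mod:`.bids_io` and
rule checking in :mod:`.validator`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ModelError",
    "EntitySet",
    "Suffix",
    "ChannelType",
    "Component",
    "Channel",
    "ReferenceFrame",
    "TrackingSystemMeta",
    "TrackingSystem",
    "EventTable",
    "ScansTable",
    "ValidationFinding",
    "Severity",
    "channel_count_field_name",
    "ROTATION_ORDERS",
    "ROTATION_RULES",
    "QUATERNION_COMPONENTS",
]


class ModelError(ValueError):
    """An in-memory object violates one of the structural invariants."""


_LABEL_RE = re.compile(r"^[a-zA-Z0-9]+$")

#: The six Tait-Bryan sequences accepted for ``RotationOrder`` — extrinsic
#: rotations about three distinct axes.  Repeated-axis sequences (XYX, ...)
#: are classic Euler conventions and are deliberately not accepted.
ROTATION_ORDERS = ("XYZ", "XZY", "YXZ", "YZX", "ZXY", "ZYX")

#: Handedness of a positive rotation about an axis.
ROTATION_RULES = ("left-hand", "right-hand")

#: Component labels for quaternion orientation channels.
QUATERNION_COMPONENTS = ("quat_x", "quat_y", "quat_z", "quat_w")


class Suffix(str, Enum):
    """BIDS suffix of a motion-related file."""

    motion = "motion"
    channels = "channels"
    events = "events"
    scans = "scans"


class ChannelType(str, Enum):
    """The ten controlled channel-type codes.

    Each code corresponds to exactly one ``<CODE>ChannelCount`` field in the
    ``motion.json`` sidecar.
    """

    ACCEL = "ACCEL"  # acceleration
    ANGACC = "ANGACC"  # angular acceleration
    GYRO = "GYRO"  # angular velocity
    JNTANG = "JNTANG"  # joint angle
    LATENCY = "LATENCY"  # per-sample timestamps relative to onset
    MAGN = "MAGN"  # magnetic field strength
    MISC = "MISC"
    ORNT = "ORNT"  # orientation (Euler angles or quaternion)
    POS = "POS"  # position
    VEL = "VEL"  # velocity


def channel_count_field_name(ctype: ChannelType) -> str:
    """Sidecar key holding the number of channels of the given type,
    e.g. ``ACCEL`` -> ``"ACCELChannelCount"``."""
    return f"{ChannelType(ctype).value}ChannelCount"


class Component(str, Enum):
    """Spatial component of a channel: a Cartesian axis, a quaternion
    element, or ``n/a`` for non-spatial channels (latency, misc)."""

    x = "x"
    y = "y"
    z = "z"
    quat_x = "quat_x"
    quat_y = "quat_y"
    quat_z = "quat_z"
    quat_w = "quat_w"
    na = "n/a"


#: Components conventionally compatible with each channel type.  The
#: standard itself does not pin this matrix down, so violations are
#: reported as warnings, not errors.
COMPONENT_COMPATIBILITY = {
    ChannelType.POS: {Component.x, Component.y, Component.z},
    ChannelType.VEL: {Component.x, Component.y, Component.z},
    ChannelType.ACCEL: {Component.x, Component.y, Component.z},
    ChannelType.GYRO: {Component.x, Component.y, Component.z},
    ChannelType.ANGACC: {Component.x, Component.y, Component.z},
    ChannelType.MAGN: {Component.x, Component.y, Component.z},
    ChannelType.ORNT: {
        Component.x,
        Component.y,
        Component.z,
        Component.quat_x,
        Component.quat_y,
        Component.quat_z,
        Component.quat_w,
    },
    ChannelType.JNTANG: {Component.x, Component.y, Component.z, Component.na},
    ChannelType.LATENCY: {Component.na},
    ChannelType.MISC: {Component.na},
}


@dataclass(frozen=True)
class EntitySet:
    """Parsed BIDS filename entities for a motion-related file.

    Entity order in filenames is fixed: ``sub``, ``ses``, ``task``,
    ``tracksys``, ``run``, then the suffix and extension.
    """

    subject: str
    task: Optional[str] = None
    session: Optional[str] = None
    tracksys: Optional[str] = None
    run: Optional[int] = None
    suffix: Suffix = Suffix.motion
    extension: str = "tsv"

    def __post_init__(self) -> None:
        for attr in ("subject", "task", "session", "tracksys"):
            value = getattr(self, attr)
            if value is not None and not _LABEL_RE.match(value):
                raise ModelError(
                    f"{attr} label {value!r} must be non-empty and alphanumeric"
                )
        if self.run is not None and self.run < 1:
            raise ModelError(f"run index must be a positive integer, got {self.run}")
        if self.extension not in ("tsv", "json"):
            raise ModelError(f"unsupported extension {self.extension!r}")
        suffix = Suffix(self.suffix)
        if suffix in (Suffix.motion, Suffix.channels):
            if self.tracksys is None:
                raise ModelError(f"suffix {suffix.value!r} requires a tracksys entity")
            if self.task is None:
                raise ModelError(f"suffix {suffix.value!r} requires a task entity")
        if suffix is Suffix.events and self.task is None:
            raise ModelError("suffix 'events' requires a task entity")
        if suffix is Suffix.scans:
            for attr in ("task", "tracksys", "run"):
                if getattr(self, attr) is not None:
                    raise ModelError(f"suffix 'scans' forbids the {attr} entity")

    def with_(self, **kwargs) -> "EntitySet":
        """Return a copy with the given fields replaced."""
        import dataclasses

        return dataclasses.replace(self, **kwargs)

    @property
    def recording_key(self) -> tuple:
        """Identity of the recording this file belongs to (suffix-free)."""
        return (self.subject, self.session, self.task, self.tracksys, self.run)


@dataclass
class ReferenceFrame:
    """Spatial context of position/orientation channels.

    ``spatial_axes`` assigns anatomical directions to the X, Y, Z axes as a
    three-character string over A/P (anterior-posterior), L/R (left-right),
    S/I (superior-inferior), with ``_`` for an unused axis — e.g. ``"ARI"``
    for X-anterior, Y-right, Z-inferior.
    """

    label: str
    spatial_axes: Optional[str] = None
    rotation_rule: Optional[str] = None
    rotation_order: Optional[str] = None
    description: Optional[str] = None

    _PAIRS = ({"A", "P"}, {"L", "R"}, {"S", "I"})

    def __post_init__(self) -> None:
        if self.spatial_axes is not None:
            self.check_spatial_axes(self.spatial_axes)
        if self.rotation_rule is not None and self.rotation_rule not in ROTATION_RULES:
            raise ModelError(
                f"RotationRule must be one of {ROTATION_RULES}, got {self.rotation_rule!r}"
            )
        if self.rotation_order is not None and self.rotation_order not in ROTATION_ORDERS:
            raise ModelError(
                f"RotationOrder must be one of {ROTATION_ORDERS}, got {self.rotation_order!r}"
            )

    @staticmethod
    def check_spatial_axes(axes: str) -> None:
        """Raise :class:`ModelError` unless ``axes`` is a valid SpatialAxes
        string: 3 characters over {A,P,L,R,S,I,_}, at most one character
        drawn from each opposing pair."""
        if not isinstance(axes, str) or len(axes) != 3:
            raise ModelError(f"SpatialAxes must be a 3-character string, got {axes!r}")
        allowed = {"A", "P", "L", "R", "S", "I", "_"}
        bad = set(axes) - allowed
        if bad:
            raise ModelError(f"SpatialAxes {axes!r} contains invalid characters {bad}")
        for pair in ReferenceFrame._PAIRS:
            used = [c for c in axes if c in pair]
            if len(used) > 1:
                raise ModelError(
                    f"SpatialAxes {axes!r} assigns the {'/'.join(sorted(pair))} "
                    "dimension to more than one axis"
                )


@dataclass
class Channel:
    """One column of a motion recording.

    The first five fields are the REQUIRED columns of ``channels.tsv``; the
    rest are recommended/optional columns.  Unknown extra columns read from
    disk are preserved verbatim in ``extra``.
    """

    name: str
    component: Component
    type: ChannelType
    tracked_point: str
    units: str
    placement: Optional[str] = None
    reference_frame: Optional[str] = None
    description: Optional[str] = None
    sampling_frequency: Optional[float] = None
    status: str = "good"
    status_description: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.component = Component(self.component)
        self.type = ChannelType(self.type)
        for attr in ("name", "tracked_point", "units"):
            if not getattr(self, attr):
                raise ModelError(f"channel field {attr!r} must be non-empty")
        if self.status not in ("good", "bad"):
            raise ModelError(f"status must be 'good' or 'bad', got {self.status!r}")


@dataclass
class TrackingSystemMeta:
    """Metadata of one tracking system (the ``motion.json`` sidecar).

    ``sampling_frequency`` is the nominal device rate in Hz and is the only
    required field.  ``sampling_frequency_effective`` is the realized rate
    computed from recorded latencies.  ``missing_values`` is the literal
    string used for missing cells in the TSV.
    """

    sampling_frequency: float
    sampling_frequency_effective: Optional[float] = None
    tracking_system_name: Optional[str] = None
    tracked_points_count: Optional[int] = None
    missing_values: str = "n/a"
    subject_artefact_description: Optional[str] = None
    channel_counts: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (isinstance(self.sampling_frequency, (int, float))
                and math.isfinite(self.sampling_frequency)
                and self.sampling_frequency > 0):
            raise ModelError(
                f"SamplingFrequency must be a positive number, got "
                f"{self.sampling_frequency!r}"
            )
        for key, count in self.channel_counts.items():
            if not (isinstance(count, int) and count >= 0):
                raise ModelError(f"channel count {key} must be a non-negative integer")


@dataclass
class TrackingSystem:
    """A synchronously sampled channel group with its metadata and samples.

    ``samples`` has one row per time point and one column per channel, in
    the exact order of ``channels``; missing values are NaN.
    """

    entities: EntitySet
    meta: TrackingSystemMeta
    channels: list
    samples: np.ndarray
    reference_frames: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            self.samples = self.samples.reshape(self.samples.shape[0] if self.samples.size else 0,
                                                len(self.channels))
        if self.samples.shape[1] != len(self.channels):
            raise ModelError(
                f"sample matrix has {self.samples.shape[1]} columns but "
                f"{len(self.channels)} channels are defined"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelError(f"duplicate channel names within tracking system: {dupes}")

    # -- derived views -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def channels_of_type(self, ctype: ChannelType) -> list:
        return [c for c in self.channels if c.type is ChannelType(ctype)]

    def column(self, name: str) -> np.ndarray:
        for j, c in enumerate(self.channels):
            if c.name == name:
                return self.samples[:, j]
        raise KeyError(name)

    def latency_channel_index(self) -> Optional[int]:
        idx = [j for j, c in enumerate(self.channels) if c.type is ChannelType.LATENCY]
        if len(idx) > 1:
            raise ModelError(f"more than one LATENCY channel: {len(idx)}")
        return idx[0] if idx else None

    def unresolved_reference_frames(self) -> list:
        """Reference-frame labels used by channels but absent from the
        ``channels.json`` Levels mapping."""
        return sorted(
            {c.reference_frame for c in self.channels
             if c.reference_frame and c.reference_frame not in self.reference_frames}
        )

    def validate(self) -> None:
        """Enforce the full invariant set; raises :class:`ModelError`.

        Construction only checks structural shape; this adds the latency
        monotonicity and reference-frame resolution checks that the
        validator reports as findings on untrusted input.
        """
        j = self.latency_channel_index()
        if j is not None:
            lat = self.samples[:, j]
            lat = lat[~np.isnan(lat)]
            if lat.size and np.any(np.diff(lat) < 0):
                raise ModelError("LATENCY channel values must be non-decreasing")
        unresolved = self.unresolved_reference_frames()
        if unresolved:
            raise ModelError(
                f"reference_frame labels {unresolved} do not resolve to a "
                "described reference frame"
            )


class EventTable:
    """Tabular events: ``onset`` (seconds relative to recording onset),
    ``duration`` (seconds or missing), plus free additional columns."""

    def __init__(self, frame: pd.DataFrame):
        if "onset" not in frame.columns:
            raise ModelError("events table requires an 'onset' column")
        onset = pd.to_numeric(frame["onset"], errors="coerce")
        if onset.isna().any() or not np.isfinite(onset).all():
            raise ModelError("event onsets must be finite numbers")
        if "duration" in frame.columns:
            dur = pd.to_numeric(frame["duration"], errors="coerce")
            if (dur.dropna() < 0).any():
                raise ModelError("event durations must be >= 0 or n/a")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self.frame.equals(other.frame)

    @property
    def onsets(self) -> np.ndarray:
        return pd.to_numeric(self.frame["onset"]).to_numpy(dtype=float)

    def shifted(self, offset: float) -> "EventTable":
        frame = self.frame.copy()
        frame["onset"] = pd.to_numeric(frame["onset"]) + offset
        return EventTable(frame)


class ScansTable:
    """Per-subject acquisition log: relative ``filename`` plus optional
    ISO-8601 ``acq_time`` used to align recordings on a shared clock."""

    def __init__(self, frame: pd.DataFrame):
        if "filename" not in frame.columns:
            raise ModelError("scans table requires a 'filename' column")
        if frame["filename"].duplicated().any():
            raise ModelError("scans table filenames must be unique")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, ScansTable) and self.frame.equals(other.frame)

    def acq_time(self, filename: str):
        """Acquisition datetime for a relative path, or None when absent."""
        from .bids_io import parse_acq_time  # local import avoids a cycle

        if "acq_time" not in self.frame.columns:
            return None
        rows = self.frame[self.frame["filename"] == filename]
        if rows.empty:
            return None
        raw = rows.iloc[0]["acq_time"]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "n/a":
            return None
        return parse_acq_time(str(raw))


class Severity(str, Enum):
    error = "error"
    warning = "warning"
    info = "info"


@dataclass(frozen=True)
class ValidationFinding:
    """One finding of the rule engine, tied to a rule id and a file path."""

    rule_id: str
    severity: Severity
    path: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity.value:7s}] {self.rule_id} {self.path}: {self.message}"
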