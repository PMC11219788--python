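"""Filename entity codec, TSV/JSON readers and writers, dataset scanner.

File conventions follow BIDS throughout: UTF-8 TSV with a tab separator and
``.`` decimal point, no quoting, ``n/a`` for missing cells.  ``motion.tsv``
is headerless — the column order is defined by the row order of the
companion ``channels.tsv`` — while all other TSV files carry a header row.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    Channel,
    ChannelType,
    Component,
    EntitySet,
    EventTable,
    ModelError,
    ReferenceFrame,
    ScansTable,
    Suffix,
    TrackingSystem,
    TrackingSystemMeta,
    channel_count_field_name,
)

__all__ = [
    "FormatError",
    "parse_filename",
    "build_filename",
    "read_motion_tsv",
    "write_motion_tsv",
    "read_channels_tsv",
    "write_channels_tsv",
    "read_motion_json",
    "write_motion_json",
    "read_channels_json",
    "write_channels_json",
    "read_events_tsv",
    "write_events_tsv",
    "read_scans_tsv",
    "write_scans_tsv",
    "parse_acq_time",
    "scan_dataset",
    "load_tracking_system",
    "save_tracking_system",
    "DatasetInventory",
    "RecordingFiles",
]

MISSING = "n/a"


class FormatError(ValueError):
    """A file on disk does not conform to the expected format."""


# ---------------------------------------------------------------------------
# filename entity grammar
# ---------------------------------------------------------------------------

_ENTITY_ORDER = ("sub", "ses", "task", "tracksys", "run")
_SUFFIXES = {s.value for s in Suffix}

_REQUIRED_BY_SUFFIX = {
    Suffix.motion: ("sub", "task", "tracksys"),
    Suffix.channels: ("sub", "task", "tracksys"),
    Suffix.events: ("sub", "task"),
    Suffix.scans: ("sub",),
}


def parse_filename(name: str) -> EntitySet:
    """Parse a basename like ``sub-001_task-walk_tracksys-imu_motion.tsv``
    into an :class:`EntitySet`.

    Entities must appear in the fixed order sub, ses, task, tracksys, run;
    unknown entities and unknown suffixes are rejected.
    """
    stem, dot, ext = name.partition(".")
    if not dot or ext not in ("tsv", "json"):
        raise FormatError(f"{name!r}: expected a .tsv or .json extension")
    tokens = stem.split("_")
    if len(tokens) < 2:
        raise FormatError(f"{name!r}: expected entity tokens followed by a suffix")
    suffix_token = tokens[-1]
    if suffix_token not in _SUFFIXES:
        raise FormatError(f"{name!r}: unknown suffix {suffix_token!r}")
    suffix = Suffix(suffix_token)

    entities: dict = {}
    position = 0
    for token in tokens[:-1]:
        key, dash, value = token.partition("-")
        if not dash or not value:
            raise FormatError(f"{name!r}: malformed entity token {token!r}")
        if key not in _ENTITY_ORDER:
            raise FormatError(f"{name!r}: unknown entity {key!r}")
        idx = _ENTITY_ORDER.index(key)
        if idx < position:  # also rejects duplicates
            raise FormatError(f"{name!r}: entity {key!r} out of order")
        position = idx + 1
        entities[key] = value

    for key in _REQUIRED_BY_SUFFIX[suffix]:
        if key not in entities:
            raise FormatError(f"{name!r}: missing required entity {key!r}")

    run: Optional[int] = None
    if "run" in entities:
        if not entities["run"].isdigit():
            raise FormatError(f"{name!r}: run index {entities['run']!r} is not an integer")
        run = int(entities["run"])

    try:
        return EntitySet(
            subject=entities["sub"],
            session=entities.get("ses"),
            task=entities.get("task"),
            tracksys=entities.get("tracksys"),
            run=run,
            suffix=suffix,
            extension=ext,
        )
    except ModelError as exc:
        raise FormatError(f"{name!r}: {exc}") from exc


def build_filename(entities: EntitySet) -> str:
    """Inverse of :func:`parse_filename`."""
    parts = [f"sub-{entities.subject}"]
    if entities.session is not None:
        parts.append(f"ses-{entities.session}")
    if entities.task is not None:
        parts.append(f"task-{entities.task}")
    if entities.tracksys is not None:
        parts.append(f"tracksys-{entities.tracksys}")
    if entities.run is not None:
        parts.append(f"run-{entities.run}")
    parts.append(entities.suffix.value)
    return "_".join(parts) + "." + entities.extension


def relative_data_path(entities: EntitySet) -> str:
    """Path of a recording file relative to the subject directory,
    e.g. ``motion/sub-001_task-walk_tracksys-imu_motion.tsv``."""
    name = build_filename(entities)
    if entities.suffix is Suffix.scans:
        return name
    prefix = f"ses-{entities.session}/" if entities.session else ""
    return prefix + "motion/" + name


# ---------------------------------------------------------------------------
# numeric TSV (motion.tsv)
# ---------------------------------------------------------------------------


def _format_number(value: float) -> str:
    """Shortest round-trippable decimal representation."""
    if value == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(float(value))


def read_motion_tsv(path, channels=None, missing_values: str = MISSING,
                    n_channels: Optional[int] = None) -> np.ndarray:
    """Read a headerless ``motion.tsv`` into an (n_samples, n_channels)
    float matrix; cells equal to ``missing_values`` become NaN.

    Either ``channels`` (the companion channel list) or ``n_channels`` must
    be given so an empty file still yields a well-shaped matrix.  Ragged
    rows raise :class:`FormatError` naming the offending 1-based row.
    """
    if channels is not None:
        n_channels = len(channels)
    if n_channels is None:
        raise ValueError("either channels or n_channels is required")
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if line == "" and i == 1 and fh.read(1) == "":
                break  # empty file
            fields = line.split("\t")
            if len(fields) != n_channels:
                raise FormatError(
                    f"{path}: row {i} has {len(fields)} fields, expected {n_channels}"
                )
            row = np.empty(n_channels)
            for j, cell in enumerate(fields):
                if cell == missing_values or cell == "":
                    row[j] = np.nan
                else:
                    try:
                        row[j] = float(cell)
                    except ValueError:
                        raise FormatError(
                            f"{path}: row {i}, column {j + 1}: "
                            f"cannot parse {cell!r} as a number"
                        ) from None
            rows.append(row)
    if not rows:
        return np.empty((0, n_channels))
    return np.vstack(rows)


def write_motion_tsv(matrix: np.ndarray, path, missing_values: str = MISSING) -> None:
    """Write a headerless tab-delimited numeric matrix; NaN cells are
    rendered as ``missing_values``."""
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in matrix:
            cells = [
                missing_values if math.isnan(v) else _format_number(v) for v in row
            ]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# channels.tsv
# ---------------------------------------------------------------------------

_REQUIRED_CHANNEL_COLUMNS = ("name", "component", "type", "tracked_point", "units")
_OPTIONAL_CHANNEL_COLUMNS = (
    "placement",
    "reference_frame",
    "description",
    "sampling_frequency",
    "status",
    "status_description",
)


def read_channels_tsv(path) -> list:
    """Read a headered ``channels.tsv`` into an ordered list of
    :class:`Channel`.  Unknown extra columns are preserved in
    ``Channel.extra``."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in _REQUIRED_CHANNEL_COLUMNS:
        if column not in table.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    channels = []
    extra_columns = [
        c for c in table.columns
        if c not in _REQUIRED_CHANNEL_COLUMNS and c not in _OPTIONAL_CHANNEL_COLUMNS
    ]
    for i, row in table.iterrows():
        for column in _REQUIRED_CHANNEL_COLUMNS:
            if row[column] == "":
                raise FormatError(
                    f"{path}: row {i + 1}: required column {column!r} is empty"
                )
        kwargs = {}
        for column in _OPTIONAL_CHANNEL_COLUMNS:
            if column in table.columns and row[column] not in ("", MISSING):
                kwargs[column] = row[column]
        if "sampling_frequency" in kwargs:
            kwargs["sampling_frequency"] = float(kwargs["sampling_frequency"])
        extra = {c: row[c] for c in extra_columns}
        try:
            channels.append(
                Channel(
                    name=row["name"],
                    component=Component(row["component"]),
                    type=ChannelType(row["type"]),
                    tracked_point=row["tracked_point"],
                    units=row["units"],
                    extra=extra,
                    **kwargs,
                )
            )
        except (ValueError, ModelError) as exc:
            raise FormatError(f"{path}: row {i + 1}: {exc}") from exc
    return channels


def write_channels_tsv(channels, path) -> None:
    """Write channels in order; optional columns appear only when some
    channel sets them, with ``n/a`` filling the gaps."""
    records = []
    for c in channels:
        record = {
            "name": c.name,
            "component": c.component.value,
            "type": c.type.value,
            "tracked_point": c.tracked_point,
            "units": c.units,
        }
        for column in _OPTIONAL_CHANNEL_COLUMNS:
            value = getattr(c, column)
            if column == "status" and value == "good":
                value = None  # default; only written when any channel is bad
            record[column] = value
        record.update(c.extra)
        records.append(record)
    table = pd.DataFrame.from_records(records)
    if any(c.status == "bad" for c in channels):
        table["status"] = [c.status for c in channels]
    for column in list(table.columns):
        if column not in _REQUIRED_CHANNEL_COLUMNS and table[column].isna().all():
            table = table.drop(columns=[column])
    table = table.fillna(MISSING)
    table.to_csv(path, sep="\t", index=False, na_rep=MISSING, lineterminator="\n")


# ---------------------------------------------------------------------------
# JSON sidecars
# ---------------------------------------------------------------------------

_META_KEYS = {
    "SamplingFrequency": "sampling_frequency",
    "SamplingFrequencyEffective": "sampling_frequency_effective",
    "TrackingSystemName": "tracking_system_name",
    "TrackedPointsCount": "tracked_points_count",
    "MissingValues": "missing_values",
    "SubjectArtefactDescription": "subject_artefact_description",
}
_COUNT_KEYS = tuple(channel_count_field_name(t) for t in ChannelType) + (
    "MotionChannelCount",
)


def read_motion_json(path) -> TrackingSystemMeta:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if "SamplingFrequency" not in data:
        raise FormatError(f"{path}: missing required key 'SamplingFrequency'")
    kwargs = {}
    counts = {}
    extra = {}
    for key, value in data.items():
        if key in _META_KEYS:
            kwargs[_META_KEYS[key]] = value
        elif key in _COUNT_KEYS:
            counts[key] = value
        else:
            extra[key] = value
    try:
        return TrackingSystemMeta(channel_counts=counts, extra=extra, **kwargs)
    except ModelError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_motion_json(meta: TrackingSystemMeta, path) -> None:
    data = {}
    for key, attr in _META_KEYS.items():
        value = getattr(meta, attr)
        if value is not None:
            data[key] = value
    data.update(meta.channel_counts)
    data.update({k: v for k, v in meta.extra.items() if not k.startswith("_")})
    _dump_json(data, path)


def read_channels_json(path) -> tuple:
    """Read ``channels.json`` → (reference-frame map, passthrough dict).

    Only ``reference_frame.Levels`` is interpreted; all other keys are
    preserved verbatim in the passthrough dict.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    frames = {}
    levels = data.get("reference_frame", {}).get("Levels", {})
    if not isinstance(levels, dict):
        raise FormatError(f"{path}: reference_frame.Levels must be an object")
    for label, desc in levels.items():
        try:
            frames[label] = ReferenceFrame(
                label=label,
                spatial_axes=desc.get("SpatialAxes"),
                rotation_rule=desc.get("RotationRule"),
                rotation_order=desc.get("RotationOrder"),
                description=desc.get("Description"),
            )
        except ModelError as exc:
            raise FormatError(f"{path}: reference frame {label!r}: {exc}") from exc
    passthrough = {k: v for k, v in data.items() if k != "reference_frame"}
    return frames, passthrough


def write_channels_json(frames: dict, path, passthrough: Optional[dict] = None) -> None:
    levels = {}
    for label, frame in frames.items():
        desc = {}
        if frame.spatial_axes is not None:
            desc["SpatialAxes"] = frame.spatial_axes
        if frame.rotation_rule is not None:
            desc["RotationRule"] = frame.rotation_rule
        if frame.rotation_order is not None:
            desc["RotationOrder"] = frame.rotation_order
        if frame.description is not None:
            desc["Description"] = frame.description
        levels[label] = desc
    data = dict(passthrough or {})
    data["reference_frame"] = {"Levels": levels}
    _dump_json(data, path)


def _dump_json(data: dict, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# events.tsv / scans.tsv
# ---------------------------------------------------------------------------


def read_events_tsv(path) -> EventTable:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = table.replace(MISSING, np.nan)
    for column in ("onset", "duration"):
        if column in table.columns:
            table[column] = pd.to_numeric(table[column], errors="coerce")
    try:
        return EventTable(table)
    except ModelError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_events_tsv(events: EventTable, path) -> None:
    events.frame.to_csv(path, sep="\t", index=False, na_rep=MISSING,
                        lineterminator="\n")


def parse_acq_time(raw: str) -> datetime:
    """Parse an ISO-8601 ``acq_time`` value (optional fractional seconds,
    timezone-naive values permitted)."""
    try:
        return datetime.fromisoformat(raw)
    except ValueError as exc:
        raise FormatError(f"cannot parse acq_time {raw!r} as ISO-8601") from exc


def read_scans_tsv(path) -> ScansTable:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    try:
        return ScansTable(table)
    except ModelError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_scans_tsv(scans: ScansTable, path) -> None:
    scans.frame.to_csv(path, sep="\t", index=False, na_rep=MISSING,
                       lineterminator="\n")


# ---------------------------------------------------------------------------
# dataset tree
# ---------------------------------------------------------------------------


@dataclass
class RecordingFiles:
    """Paths of the files belonging to one motion recording."""

    entities: EntitySet  # suffix=motion, ext=tsv; identity of the recording
    motion_tsv: Optional[Path] = None
    motion_json: Optional[Path] = None
    channels_tsv: Optional[Path] = None
    channels_json: Optional[Path] = None
    events_tsv: Optional[Path] = None
    events_json: Optional[Path] = None


@dataclass
class DatasetInventory:
    """Result of scanning a dataset root: recordings grouped by entity set,
    per-subject scans tables, and files that failed to parse."""

    root: Path
    recordings: list = field(default_factory=list)
    scans: dict = field(default_factory=dict)  # subject -> (path, ScansTable)
    parse_failures: list = field(default_factory=list)  # (path, message)
    misplaced: list = field(default_factory=list)  # motion-suffix files not in motion/

    def recording(self, entities: EntitySet) -> RecordingFiles:
        key = entities.recording_key
        for rec in self.recordings:
            if rec.entities.recording_key == key:
                return rec
        raise KeyError(f"no recording with entities {entities}")


_SUBJECT_DIR_RE = re.compile(r"^sub-[a-zA-Z0-9]+$")
_SESSION_DIR_RE = re.compile(r"^ses-[a-zA-Z0-9]+$")


def scan_dataset(root) -> DatasetInventory:
    """Walk ``sub-<label>/[ses-<label>/]motion/`` directories and group the
    files of each recording.  Non-conforming filenames are recorded as
    parse failures rather than raised."""
    root = Path(root)
    inv = DatasetInventory(root=root)
    groups: dict = {}

    def visit_motion_dir(motion_dir: Path) -> None:
        for path in sorted(motion_dir.iterdir()):
            if not path.is_file():
                continue
            try:
                entities = parse_filename(path.name)
            except FormatError as exc:
                inv.parse_failures.append((str(path), str(exc)))
                continue
            key = entities.recording_key
            if key not in groups:
                try:
                    # normalize to the motion.tsv identity when possible;
                    # shared events files (no tracksys) keep their own suffix
                    ident = entities.with_(suffix=Suffix.motion, extension="tsv")
                except ModelError:
                    ident = entities
                groups[key] = RecordingFiles(entities=ident)
            rec = groups[key]
            slot = f"{entities.suffix.value}_{entities.extension}"
            setattr(rec, slot, path)

    for sub_dir in sorted(root.iterdir() if root.is_dir() else []):
        if not sub_dir.is_dir() or not _SUBJECT_DIR_RE.match(sub_dir.name):
            continue
        subject = sub_dir.name.split("-", 1)[1]
        scans_path = sub_dir / f"sub-{subject}_scans.tsv"
        if scans_path.exists():
            try:
                inv.scans[subject] = (scans_path, read_scans_tsv(scans_path))
            except FormatError as exc:
                inv.parse_failures.append((str(scans_path), str(exc)))
        session_dirs = [d for d in sorted(sub_dir.iterdir())
                        if d.is_dir() and _SESSION_DIR_RE.match(d.name)]
        for base in session_dirs or [sub_dir]:
            motion_dir = base / "motion"
            if motion_dir.is_dir():
                visit_motion_dir(motion_dir)
            # motion-suffix files outside a motion/ subdirectory
            for path in sorted(base.glob("*_motion.tsv")) + sorted(base.glob("*_motion.json")):
                inv.misplaced.append(str(path))

    # deterministic recording order
    inv.recordings = [groups[k] for k in sorted(groups, key=lambda k: tuple(
        "" if v is None else str(v) for v in k))]
    return inv


def load_tracking_system(root, entities: EntitySet, strict: bool = True) -> TrackingSystem:
    """Assemble a :class:`TrackingSystem` from the files of one recording.

    The sample-column ↔ channel-row correspondence is positional.  With
    ``strict`` (default) the full model invariants are enforced; the
    validator loads leniently and reports violations as findings instead.
    """
    root = Path(root)
    sub_dir = root / f"sub-{entities.subject}"
    base = sub_dir / f"ses-{entities.session}" if entities.session else sub_dir
    motion_dir = base / "motion"

    def path_for(suffix: Suffix, ext: str) -> Path:
        e = entities.with_(suffix=suffix, extension=ext)
        if suffix in (Suffix.events,) and entities.tracksys is None:
            e = e.with_(tracksys=None)
        return motion_dir / build_filename(e)

    motion_tsv = path_for(Suffix.motion, "tsv")
    channels_tsv = path_for(Suffix.channels, "tsv")
    motion_json = path_for(Suffix.motion, "json")
    for required in (motion_tsv, channels_tsv, motion_json):
        if not required.exists():
            raise FormatError(f"missing companion file {required}")

    meta = read_motion_json(motion_json)
    channels = read_channels_tsv(channels_tsv)
    first_line = None
    with open(motion_tsv, "r", encoding="utf-8") as fh:
        first_line = fh.readline().rstrip("\n\r")
    if first_line:
        n_cols = len(first_line.split("\t"))
        if n_cols != len(channels):
            raise FormatError(
                f"{motion_tsv}: {n_cols} data columns ≠ {len(channels)} channel rows"
            )
    samples = read_motion_tsv(motion_tsv, channels=channels,
                              missing_values=meta.missing_values)

    frames: dict = {}
    channels_json = path_for(Suffix.channels, "json")
    if channels_json.exists():
        frames, passthrough = read_channels_json(channels_json)
        if passthrough:
            meta.extra.setdefault("_channels_json_passthrough", passthrough)

    system = TrackingSystem(
        entities=entities.with_(suffix=Suffix.motion, extension="tsv"),
        meta=meta,
        channels=channels,
        samples=samples,
        reference_frames=frames,
    )
    if strict:
        system.validate()
    return system


def save_tracking_system(system: TrackingSystem, root,
                         events: Optional[EventTable] = None) -> Path:
    """Write motion.tsv / channels.tsv / motion.json (and channels.json,
    events.tsv when applicable) for one tracking system; returns the
    motion directory."""
    root = Path(root)
    entities = system.entities
    sub_dir = root / f"sub-{entities.subject}"
    base = sub_dir / f"ses-{entities.session}" if entities.session else sub_dir
    motion_dir = base / "motion"
    motion_dir.mkdir(parents=True, exist_ok=True)

    write_motion_tsv(system.samples,
                     motion_dir / build_filename(entities.with_(suffix=Suffix.motion,
                                                                extension="tsv")),
                     missing_values=system.meta.missing_values)
    write_channels_tsv(system.channels,
                       motion_dir / build_filename(entities.with_(suffix=Suffix.channels,
                                                                  extension="tsv")))
    write_motion_json(system.meta,
                      motion_dir / build_filename(entities.with_(suffix=Suffix.motion,
                                                                 extension="json")))
    if system.reference_frames:
        passthrough = system.meta.extra.get("_channels_json_passthrough")
        write_channels_json(system.reference_frames,
                            motion_dir / build_filename(
                                entities.with_(suffix=Suffix.channels,
                                               extension="json")),
                            passthrough=passthrough)
    if events is not None:
        write_events_tsv(events,
                         motion_dir / build_filename(entities.with_(suffix=Suffix.events,
                                                                    extension="tsv")))
    return motion_dir
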