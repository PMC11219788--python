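"""Rule engine over a motion dataset tree.

Requirement levels map directly onto finding severities: REQUIRED/MUST
clauses produce errors, RECOMMENDED/SHOULD clauses warnings, OPTIONAL
clauses info.  Validation is pure — the same tree always yields the same
ordered report (findings sorted by path, then rule id; paths relative to
the dataset root) — and unreadable files become findings, never exceptions.

Rules
-----
R01  filename grammar and required entities
R02  motion/ placement and required companion files per recording
R03  motion.tsv well-formedness and channel/column count match
R04  required channels.tsv columns present and non-empty
R05  channel type within the ten-code vocabulary
R06  component within vocabulary (error) and consistent with type (warning)
R07  quaternion component groups complete per tracked point (warning)
R08  SamplingFrequency present and positive
R09  *ChannelCount sidecar fields consistent with actual counts (warning)
R10  SpatialAxes grammar
R11  RotationRule keyword
R12  RotationOrder keyword (six distinct-axis sequences only)
R13  reference_frame labels resolve to channels.json Levels (warning)
R14  at most one LATENCY channel, values non-decreasing
R15  events files carry a tracksys entity when several systems exist (warning)
R16  scans.tsv rows: resolvable filename, parseable acq_time
R17  unit string recognized (warning)
R18  events.tsv well-formedness (onset/duration)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    COMPONENT_COMPATIBILITY,
    ChannelType,
    Component,
    ModelError,
    QUATERNION_COMPONENTS,
    ReferenceFrame,
    ROTATION_ORDERS,
    ROTATION_RULES,
    Severity,
    ValidationFinding,
)
from . import bids_io
from .bids_io import FormatError, scan_dataset

__all__ = ["ValidationReport", "validate_dataset", "severity_for"]

_CHANNEL_TYPE_CODES = {t.value for t in ChannelType}
_COMPONENT_CODES = {c.value for c in Component}
_REQUIRED_COLUMNS = ("name", "component", "type", "tracked_point", "units")

#: Unit strings the validator recognizes without comment.  The standard
#: fixes no units vocabulary, so anything else is only a warning.
KNOWN_UNITS = {
    "m", "mm", "cm", "m/s", "m/s^2", "g",
    "rad", "deg", "rad/s", "deg/s", "rad/s^2", "deg/s^2",
    "T", "uT", "nT", "s", "ms", "n/a",
}


def severity_for(requirement_level: str) -> Severity:
    """REQUIRED → error, RECOMMENDED → warning, OPTIONAL → info."""
    mapping = {
        "REQUIRED": Severity.error,
        "RECOMMENDED": Severity.warning,
        "OPTIONAL": Severity.info,
    }
    try:
        return mapping[requirement_level]
    except KeyError:
        raise ValueError(
            f"requirement level must be one of {sorted(mapping)}, "
            f"got {requirement_level!r}"
        ) from None


@dataclass
class ValidationReport:
    """Ordered list of findings over one dataset tree."""

    root: Path
    findings: list = field(default_factory=list)

    def add(self, rule_id: str, severity: Severity, path, message: str) -> None:
        path = Path(path)
        try:
            shown = path.relative_to(self.root).as_posix()
        except ValueError:
            shown = path.as_posix()
        self.findings.append(
            ValidationFinding(rule_id=rule_id, severity=severity,
                              path=shown, message=message)
        )

    def finalize(self) -> "ValidationReport":
        self.findings.sort(key=lambda f: (f.path, f.rule_id, f.message))
        return self

    @property
    def errors(self) -> list:
        return [f for f in self.findings if f.severity is Severity.error]

    @property
    def warnings(self) -> list:
        return [f for f in self.findings if f.severity is Severity.warning]

    def filtered(self, min_severity: str = "info") -> list:
        order = {"error": 0, "warning": 1, "info": 2}
        limit = order[min_severity]
        return [f for f in self.findings if order[f.severity.value] <= limit]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"rule_id": f.rule_id, "severity": f.severity.value,
                 "path": f.path, "message": f.message}
                for f in self.findings
            ],
            indent=2,
        )

    def __str__(self) -> str:
        if not self.findings:
            return "no findings"
        return "\n".join(str(f) for f in self.findings)


def validate_dataset(root) -> ValidationReport:
    """Run every rule over the dataset tree at ``root``."""
    root = Path(root)
    report = ValidationReport(root=root)
    if not root.is_dir():
        report.add("R01", Severity.error, root, "dataset root does not exist")
        return report.finalize()
    inventory = scan_dataset(root)

    for path, message in inventory.parse_failures:
        report.add("R01", Severity.error, path, message)
    for path in inventory.misplaced:
        report.add("R02", Severity.error, path,
                   "motion files must live in a 'motion' subdirectory")

    # recordings per (subject, session, task): needed for R15
    systems_per_group: dict = {}
    for rec in inventory.recordings:
        if rec.motion_tsv is not None:
            e = rec.entities
            key = (e.subject, e.session, e.task)
            systems_per_group[key] = systems_per_group.get(key, 0) + 1

    for rec in inventory.recordings:
        _check_recording(report, inventory, rec, systems_per_group)

    for subject, (scans_path, scans) in sorted(inventory.scans.items()):
        _check_scans(report, root, subject, scans_path, scans)

    return report.finalize()


# ---------------------------------------------------------------------------
# per-recording checks
# ---------------------------------------------------------------------------


def _check_recording(report, inventory, rec, systems_per_group) -> None:
    e = rec.entities
    is_events_only = rec.motion_tsv is None and rec.channels_tsv is None \
        and rec.motion_json is None

    if is_events_only:
        if rec.events_tsv is not None:
            _check_events(report, rec.events_tsv)
        return

    # R02: required companions of a motion recording
    anchor = rec.motion_tsv or rec.channels_tsv or rec.motion_json
    missing = [name for name, path in (
        ("motion.tsv", rec.motion_tsv),
        ("channels.tsv", rec.channels_tsv),
        ("motion.json", rec.motion_json),
    ) if path is None]
    if missing:
        report.add("R02", Severity.error, anchor,
                   f"recording is missing required companion file(s): "
                   f"{', '.join(missing)}")

    channels_table = None
    if rec.channels_tsv is not None:
        channels_table = _check_channels_tsv(report, rec.channels_tsv)

    meta_data = None
    if rec.motion_json is not None:
        meta_data = _check_motion_json(report, rec.motion_json, channels_table)

    if rec.motion_tsv is not None and channels_table is not None:
        missing_values = "n/a"
        if isinstance(meta_data, dict):
            missing_values = meta_data.get("MissingValues", "n/a")
        _check_motion_tsv(report, rec.motion_tsv, channels_table, missing_values)

    frames = None
    if rec.channels_json is not None:
        frames = _check_channels_json(report, rec.channels_json)
    if channels_table is not None and "reference_frame" in channels_table.columns:
        used = {v for v in channels_table["reference_frame"] if v not in ("", "n/a")}
        defined = set(frames or {})
        unresolved = sorted(used - defined)
        if unresolved:
            where = rec.channels_json or rec.channels_tsv
            report.add("R13", Severity.warning, where,
                       f"reference_frame label(s) {unresolved} not described "
                       "under channels.json reference_frame.Levels")

    if rec.events_tsv is not None:
        _check_events(report, rec.events_tsv)
        n_systems = systems_per_group.get((e.subject, e.session, e.task), 0)
        # events grouped under a recording always carry tracksys; the
        # shared-events case is events-only, handled below via entity check
    # R15 applies to events files without tracksys; those land in
    # events-only groups, checked here across the subject/task group
    if rec.motion_tsv is not None:
        key = (e.subject, e.session, e.task)
        if systems_per_group.get(key, 0) > 1:
            for other in inventory.recordings:
                oe = other.entities
                if (oe.subject, oe.session, oe.task) == key \
                        and oe.tracksys is None and other.events_tsv is not None:
                    report.add("R15", Severity.warning, other.events_tsv,
                               "multiple tracking systems exist; events "
                               "files should carry a tracksys entity")


def _check_channels_tsv(report, path):
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # unreadable file -> finding, not exception
        report.add("R04", Severity.error, path, f"cannot read channels.tsv: {exc}")
        return None

    ok = True
    for column in _REQUIRED_COLUMNS:
        if column not in table.columns:
            report.add("R04", Severity.error, path,
                       f"missing required column '{column}'")
            ok = False
    if not ok:
        return None

    for i, row in table.iterrows():
        for column in _REQUIRED_COLUMNS:
            value = row[column]
            # "n/a" is a vocabulary member for component and a legitimate
            # unit string (e.g. dimensionless quaternions), but means
            # missing in the other required columns
            empty = value == "" or (
                value == "n/a" and column in ("name", "type", "tracked_point"))
            if empty:
                report.add("R04", Severity.error, path,
                           f"row {i + 1}: required column '{column}' is empty")
        ctype, comp = row["type"], row["component"]
        if ctype not in _CHANNEL_TYPE_CODES:
            report.add("R05", Severity.error, path,
                       f"row {i + 1}: unknown channel type '{ctype}'")
        if comp not in _COMPONENT_CODES:
            report.add("R06", Severity.error, path,
                       f"row {i + 1}: unknown component '{comp}'")
        elif ctype in _CHANNEL_TYPE_CODES:
            allowed = COMPONENT_COMPATIBILITY[ChannelType(ctype)]
            if Component(comp) not in allowed:
                report.add("R06", Severity.warning, path,
                           f"row {i + 1}: component '{comp}' is unusual for "
                           f"channel type '{ctype}'")
        units = row["units"]
        if units and units not in KNOWN_UNITS:
            report.add("R17", Severity.warning, path,
                       f"row {i + 1}: unrecognized unit string '{units}'")

    # R07: quaternion quadruples complete per tracked point / frame
    quat_rows = table[table["component"].isin(QUATERNION_COMPONENTS)].copy()
    if not quat_rows.empty:
        if "reference_frame" not in quat_rows.columns:
            quat_rows["reference_frame"] = ""
        for (point, _), group in quat_rows.groupby(
                ["tracked_point", "reference_frame"]):
            present = set(group["component"])
            absent = sorted(set(QUATERNION_COMPONENTS) - present)
            if absent:
                report.add("R07", Severity.warning, path,
                           f"tracked point '{point}': quaternion group is "
                           f"missing component(s) {absent}")

    # R14: latency channel count (values checked against motion.tsv)
    n_latency = int((table["type"] == "LATENCY").sum())
    if n_latency > 1:
        report.add("R14", Severity.error, path,
                   f"{n_latency} LATENCY channels; at most one is allowed")
    return table


def _check_motion_json(report, path, channels_table):
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    except Exception as exc:
        report.add("R08", Severity.error, path, f"cannot read motion.json: {exc}")
        return None
    fs = data.get("SamplingFrequency")
    if fs is None:
        report.add("R08", Severity.error, path,
                   "missing required field 'SamplingFrequency'")
    elif not isinstance(fs, (int, float)) or isinstance(fs, bool) or not fs > 0:
        report.add("R08", Severity.error, path,
                   f"'SamplingFrequency' must be a positive number, got {fs!r}")

    # R09: declared channel counts vs actual rows (LATENCY counted apart;
    # MotionChannelCount covers all non-LATENCY channels)
    if channels_table is not None and "type" in channels_table.columns:
        actual = channels_table["type"].value_counts().to_dict()
        for ctype in ChannelType:
            key = f"{ctype.value}ChannelCount"
            if key in data and data[key] != actual.get(ctype.value, 0):
                report.add("R09", Severity.warning, path,
                           f"{key} is {data[key]} but channels.tsv defines "
                           f"{actual.get(ctype.value, 0)} {ctype.value} channel(s)")
        if "MotionChannelCount" in data:
            motion_actual = sum(v for k, v in actual.items() if k != "LATENCY")
            if data["MotionChannelCount"] != motion_actual:
                report.add("R09", Severity.warning, path,
                           f"MotionChannelCount is {data['MotionChannelCount']} "
                           f"but channels.tsv defines {motion_actual} "
                           "non-LATENCY channel(s)")
    return data


def _check_motion_tsv(report, path, channels_table, missing_values) -> None:
    n_channels = len(channels_table)
    try:
        matrix = bids_io.read_motion_tsv(path, n_channels=n_channels,
                                         missing_values=missing_values)
    except FormatError as exc:
        message = str(exc)
        if "fields, expected" in message and "row 1 " in message:
            # leading-row mismatch: a column-count mismatch, not raggedness
            first = message.split("has ")[1].split(" fields")[0]
            report.add("R03", Severity.error, path,
                       f"{first} data columns ≠ {n_channels} channel rows "
                       "in channels.tsv")
        else:
            report.add("R03", Severity.error, path, message)
        return
    except Exception as exc:
        report.add("R03", Severity.error, path, f"cannot read motion.tsv: {exc}")
        return

    # R14: latency values non-decreasing
    lat_idx = [j for j, t in enumerate(channels_table["type"]) if t == "LATENCY"]
    if len(lat_idx) == 1 and matrix.shape[0] > 1:
        lat = matrix[:, lat_idx[0]]
        lat = lat[~np.isnan(lat)]
        if lat.size > 1 and np.any(np.diff(lat) < 0):
            report.add("R14", Severity.error, path,
                       "LATENCY channel values are not non-decreasing")


def _check_channels_json(report, path):
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    except Exception as exc:
        report.add("R13", Severity.warning, path,
                   f"cannot read channels.json: {exc}")
        return None
    levels = data.get("reference_frame", {}).get("Levels", {})
    frames = {}
    for label, desc in levels.items():
        if not isinstance(desc, dict):
            report.add("R10", Severity.error, path,
                       f"reference frame '{label}' must be a JSON object")
            continue
        frames[label] = desc
        axes = desc.get("SpatialAxes")
        if axes is not None:
            try:
                ReferenceFrame.check_spatial_axes(axes)
            except ModelError as exc:
                report.add("R10", Severity.error, path,
                           f"reference frame '{label}': {exc}")
        rule = desc.get("RotationRule")
        if rule is not None and rule not in ROTATION_RULES:
            report.add("R11", Severity.error, path,
                       f"reference frame '{label}': RotationRule must be one "
                       f"of {list(ROTATION_RULES)}, got '{rule}'")
        order = desc.get("RotationOrder")
        if order is not None and order not in ROTATION_ORDERS:
            report.add("R12", Severity.error, path,
                       f"reference frame '{label}': RotationOrder must be one "
                       f"of the six distinct-axis sequences "
                       f"{list(ROTATION_ORDERS)}, got '{order}'")
    return frames


def _check_events(report, path) -> None:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        report.add("R18", Severity.error, path, f"cannot read events.tsv: {exc}")
        return
    if "onset" not in table.columns:
        report.add("R18", Severity.error, path, "missing required column 'onset'")
        return
    if len(table):  # header-only events files are valid
        onset = pd.to_numeric(table["onset"], errors="coerce")
        if onset.isna().any() or not np.isfinite(onset).all():
            report.add("R18", Severity.error, path,
                       "event onsets must be finite numbers")
        if "duration" in table.columns:
            dur = pd.to_numeric(
                table["duration"].replace("n/a", np.nan), errors="coerce")
            if (dur.dropna() < 0).any():
                report.add("R18", Severity.error, path,
                           "event durations must be >= 0 or n/a")


def _check_scans(report, root, subject, scans_path, scans) -> None:
    sub_dir = root / f"sub-{subject}"
    for i, row in scans.frame.iterrows():
        filename = row["filename"]
        if not (sub_dir / filename).exists():
            report.add("R16", Severity.error, scans_path,
                       f"row {i + 1}: filename '{filename}' does not resolve "
                       "within the dataset")
        raw = row.get("acq_time", "")
        if raw not in ("", "n/a"):
            try:
                bids_io.parse_acq_time(raw)
            except FormatError as exc:
                report.add("R16", Severity.error, scans_path,
                           f"row {i + 1}: {exc}")
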