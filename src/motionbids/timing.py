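"""Latency reconstruction and multi-system temporal alignment.

Each tracking system carries per-sample timing either explicitly, as a
LATENCY channel of seconds relative to recording onset, or implicitly via
its sampling frequency.  Recordings from different systems are placed on a
shared clock using the acquisition timestamps (``acq_time``) in the
per-subject ``scans.tsv``: the earliest acquisition defines global zero and
every other recording is offset by its acquisition-time difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import ChannelType, EventTable, ScansTable, TrackingSystem
from .bids_io import build_filename, relative_data_path

__all__ = [
    "TimingError",
    "reconstruct_latency",
    "effective_fs",
    "sample_times",
    "Timeline",
    "build_timeline",
    "resample_to",
    "events_to_global",
]


class TimingError(ValueError):
    """Timing information is missing or inconsistent."""


#: Relative disagreement between a LATENCY channel's effective rate and the
#: nominal rate above which a warning is emitted.
RATE_MISMATCH_TOLERANCE = 0.05


def reconstruct_latency(n_samples: int, fs: float) -> np.ndarray:
    """Uniform latency grid ``i / fs`` for a recording without per-sample
    timestamps (latency[0] = 0)."""
    if fs is None or not fs > 0:
        raise TimingError(f"sampling frequency must be positive, got {fs!r}")
    if n_samples < 1:
        raise TimingError("need at least one sample")
    return np.arange(n_samples) / fs


def effective_fs(latency) -> float:
    """Realized sampling rate (n−1) / (latency[n−1] − latency[0]) from a
    strictly increasing latency vector."""
    latency = np.asarray(latency, dtype=float)
    if latency.size < 2:
        raise TimingError("need at least two latency samples")
    if np.any(np.diff(latency) <= 0):
        raise TimingError("latency values must be strictly increasing")
    return (latency.size - 1) / (latency[-1] - latency[0])


def sample_times(system: TrackingSystem) -> np.ndarray:
    """Per-sample times of a recording, relative to its onset.

    Precedence: the LATENCY channel verbatim, when present; else a uniform
    grid from ``SamplingFrequencyEffective``, when present; else from the
    nominal ``SamplingFrequency``.
    """
    j = system.latency_channel_index()
    if j is not None:
        latency = system.samples[:, j]
        fs_nominal = system.meta.sampling_frequency
        if latency.size >= 2 and fs_nominal:
            try:
                realized = effective_fs(latency)
            except TimingError:
                realized = None
            if realized is not None and abs(realized - fs_nominal) / fs_nominal > RATE_MISMATCH_TOLERANCE:
                warnings.warn(
                    f"LATENCY channel implies {realized:.3f} Hz, more than "
                    f"{RATE_MISMATCH_TOLERANCE:.0%} away from the nominal "
                    f"{fs_nominal} Hz; using the LATENCY channel",
                    stacklevel=2,
                )
        return latency
    fs = system.meta.sampling_frequency_effective or system.meta.sampling_frequency
    if not fs:
        raise TimingError(
            "no LATENCY channel and no sampling frequency to reconstruct timing"
        )
    return reconstruct_latency(system.n_samples, fs)


@dataclass
class Timeline:
    """Shared clock for a set of recordings.

    ``offsets`` maps each recording id (its motion.tsv basename) to seconds
    since the earliest acquisition; sample ``i`` of recording ``k`` occurs
    at ``offsets[k] + latency_k[i]`` global seconds.
    """

    reference: str
    offsets: dict
    warnings: list = field(default_factory=list)

    def offset(self, recording_id: str) -> float:
        if recording_id not in self.offsets:
            raise TimingError(f"unknown recording id {recording_id!r}")
        return self.offsets[recording_id]

    def global_times(self, system: TrackingSystem) -> np.ndarray:
        return self.offset(recording_id(system)) + sample_times(system)


def recording_id(system: TrackingSystem) -> str:
    """Identity of a recording on the timeline: its motion.tsv basename."""
    return build_filename(system.entities)


def build_timeline(systems, scans: Optional[ScansTable]) -> Timeline:
    """Derive per-recording offsets from scans.tsv acquisition times.

    The earliest ``acq_time`` defines global zero, keeping all global times
    non-negative.  Recordings missing from scans.tsv (or scans.tsv missing
    entirely) fall back to offset 0 with a warning recorded on the
    timeline.
    """
    notes = []
    acq = {}
    for system in systems:
        rid = recording_id(system)
        when = None
        if scans is not None:
            # scans.tsv filenames are relative to the subject directory
            when = scans.acq_time(relative_data_path(system.entities))
            if when is None:
                when = scans.acq_time(rid)  # tolerate bare basenames
        if when is None:
            notes.append(f"{rid}: no acq_time in scans.tsv; assuming offset 0")
        acq[rid] = when

    known = [t for t in acq.values() if t is not None]
    t0 = min(known) if known else None
    offsets = {
        rid: (when - t0).total_seconds() if (when is not None and t0 is not None) else 0.0
        for rid, when in acq.items()
    }
    reference = min((rid for rid, off in offsets.items() if off == 0.0), default="")
    return Timeline(reference=reference, offsets=offsets, warnings=notes)


def _quat_groups(system: TrackingSystem):
    """Column-index groups of complete quaternion channel quadruples,
    keyed by (tracked_point, reference_frame)."""
    groups: dict = {}
    for j, c in enumerate(system.channels):
        if c.type is ChannelType.ORNT and c.component.value.startswith("quat_"):
            key = (c.tracked_point, c.reference_frame)
            groups.setdefault(key, {})[c.component.value] = j
    return [
        [g["quat_w"], g["quat_x"], g["quat_y"], g["quat_z"]]
        for g in groups.values()
        if len(g) == 4
    ]


def resample_to(system: TrackingSystem, timeline: Timeline, target_times) -> np.ndarray:
    """Linearly interpolate every channel onto ``target_times`` (global
    seconds, sorted).  Target times outside the recording span become NaN.

    Quaternion orientation quadruples are interpolated as 4-vectors and
    renormalized (normalized linear interpolation) rather than per-channel
    independently, so interpolated samples remain unit rotations.
    """
    target_times = np.asarray(target_times, dtype=float)
    if np.any(np.diff(target_times) < 0):
        raise TimingError("target times must be sorted")
    times = timeline.global_times(system)
    if times.size < 2:
        raise TimingError("need at least two samples to interpolate")
    if np.any(np.diff(times) <= 0):
        keep = np.concatenate([[True], np.diff(times) > 0])
        warnings.warn("duplicate latency values collapsed to first occurrence",
                      stacklevel=2)
        times = times[keep]
        samples = system.samples[keep]
    else:
        samples = system.samples

    out = np.empty((target_times.size, samples.shape[1]))
    for j in range(samples.shape[1]):
        out[:, j] = np.interp(target_times, times, samples[:, j])
    outside = (target_times < times[0]) | (target_times > times[-1])
    out[outside, :] = np.nan

    for group in _quat_groups(system):
        block = out[:, group]
        norms = np.linalg.norm(block, axis=1, keepdims=True)
        valid = np.isfinite(norms[:, 0]) & (norms[:, 0] > 0)
        block[valid] = block[valid] / norms[valid]
        out[:, group] = block
    return out


def events_to_global(events: EventTable, timeline: Timeline,
                     recording: str) -> EventTable:
    """Shift recording-relative event onsets onto the shared clock by the
    recording's acquisition offset."""
    return events.shifted(timeline.offset(recording))
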