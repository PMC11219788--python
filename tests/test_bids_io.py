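"""Filename codec round trips, TSV/JSON readers and writers, dataset
assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motionbids import bids_io
from motionbids.bids_io import (
    FormatError,
    build_filename,
    load_tracking_system,
    parse_filename,
    read_channels_tsv,
    read_motion_tsv,
    save_tracking_system,
    scan_dataset,
    write_channels_tsv,
    write_motion_tsv,
)
from motionbids.model import (
    Channel,
    ChannelType,
    Component,
    EntitySet,
    Suffix,
    TrackingSystemMeta,
)


# -- filename grammar -------------------------------------------------------

def test_parse_filename_examples():
    e = parse_filename("sub-001_task-walk_tracksys-imu_motion.tsv")
    assert (e.subject, e.task, e.tracksys) == ("001", "walk", "imu")
    assert e.suffix is Suffix.motion and e.extension == "tsv"

    e = parse_filename("sub-XX_task-YY_tracksys-optical_events.tsv")
    assert (e.subject, e.task, e.tracksys) == ("XX", "YY", "optical")
    assert e.suffix is Suffix.events

    e = parse_filename("sub-01_ses-vr_task-rot_tracksys-a_run-2_motion.json")
    assert e.session == "vr" and e.run == 2 and e.extension == "json"


@pytest.mark.parametrize("name, token", [
    ("sub-01_motion.tsv", "task"),           # required entities missing
    ("task-w_sub-01_tracksys-a_motion.tsv", "order"),
    ("sub-01_task-w_tracksys-a_wiggle.tsv", "wiggle"),
    ("sub-01_task-w_tracksys-a_motion.csv", "extension"),
    ("sub-01_acq-x_task-w_tracksys-a_motion.tsv", "acq"),
    ("sub-01_sub-02_task-w_tracksys-a_motion.tsv", "order"),
])
def test_parse_filename_rejects_malformed(name, token):
    with pytest.raises(FormatError, match=token):
        parse_filename(name)


def test_build_filename_examples():
    assert build_filename(EntitySet(subject="001", task="walk", tracksys="imu")) \
        == "sub-001_task-walk_tracksys-imu_motion.tsv"
    assert build_filename(EntitySet(subject="001", task="walk",
                                    suffix=Suffix.events)) \
        == "sub-001_task-walk_events.tsv"
    assert build_filename(EntitySet(subject="001", suffix=Suffix.scans)) \
        == "sub-001_scans.tsv"


label = st.text(alphabet="abcdefghijklmnopqrstuvwxyz0123456789", min_size=1,
                max_size=6)


@settings(max_examples=200, deadline=None)
@given(subject=label, session=st.none() | label, task=label, tracksys=label,
       run=st.none() | st.integers(1, 99),
       suffix=st.sampled_from([Suffix.motion, Suffix.channels, Suffix.events]),
       ext=st.sampled_from(["tsv", "json"]))
def test_parse_build_round_trip(subject, session, task, tracksys, run, suffix, ext):
    entities = EntitySet(subject=subject, session=session, task=task,
                         tracksys=tracksys, run=run, suffix=suffix, extension=ext)
    assert parse_filename(build_filename(entities)) == entities


# -- motion.tsv --------------------------------------------------------------

def test_motion_tsv_round_trip(tmp_path):
    path = tmp_path / "m.tsv"
    matrix = np.array([[0.0, 1.5, -2.25], [3.0, np.nan, 5.0]])
    write_motion_tsv(matrix, path)
    text = path.read_text()
    assert text == "0\t1.5\t-2.25\n3\tn/a\t5\n"
    back = read_motion_tsv(path, n_channels=3)
    np.testing.assert_array_equal(np.isnan(back), np.isnan(matrix))
    np.testing.assert_allclose(back[~np.isnan(back)], matrix[~np.isnan(matrix)])


def test_motion_tsv_ragged_row_reports_index(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("1\t2\t3\n4\t5\n6\t7\t8\n")
    with pytest.raises(FormatError, match="row 2"):
        read_motion_tsv(path, n_channels=3)


def test_motion_tsv_empty_file(tmp_path):
    path = tmp_path / "m.tsv"
    write_motion_tsv(np.empty((0, 4)), path)
    back = read_motion_tsv(path, n_channels=4)
    assert back.shape == (0, 4)


def test_motion_tsv_custom_missing_string(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("1\tNA\n2\t3\n")
    back = read_motion_tsv(path, n_channels=2, missing_values="NA")
    assert np.isnan(back[0, 1]) and back[1, 1] == 3


def test_motion_tsv_float_round_trip_is_exact(tmp_path):
    rng = np.random.default_rng(5)
    matrix = rng.standard_normal((20, 4))
    path = tmp_path / "m.tsv"
    write_motion_tsv(matrix, path)
    np.testing.assert_array_equal(read_motion_tsv(path, n_channels=4), matrix)


# -- channels.tsv ------------------------------------------------------------

def make_channels():
    channels = []
    for ctype, units in ((ChannelType.ACCEL, "m/s^2"), (ChannelType.GYRO, "rad/s")):
        for comp in ("x", "y", "z"):
            channels.append(Channel(
                name=f"t1_{ctype.value}_{comp}", component=Component(comp),
                type=ctype, tracked_point="t1", units=units))
    return channels


def test_channels_tsv_round_trip(tmp_path):
    path = tmp_path / "c.tsv"
    channels = make_channels()
    channels[0].placement = "left ankle"
    write_channels_tsv(channels, path)
    back = read_channels_tsv(path)
    assert len(back) == 6
    assert [c.name for c in back] == [c.name for c in channels]
    assert back[0].placement == "left ankle"
    assert back[1].placement is None
    assert all(c.status == "good" for c in back)  # default when column absent


def test_channels_tsv_missing_required_column(tmp_path):
    path = tmp_path / "c.tsv"
    path.write_text("name\tcomponent\ttype\ttracked_point\n"
                    "a\tx\tPOS\tHead\n")
    with pytest.raises(FormatError, match="units"):
        read_channels_tsv(path)


def test_channels_tsv_preserves_unknown_columns(tmp_path):
    path = tmp_path / "c.tsv"
    path.write_text(
        "name\tcomponent\ttype\ttracked_point\tunits\tvendor_id\n"
        "a\tx\tPOS\tHead\tm\tV123\n")
    back = read_channels_tsv(path)
    assert back[0].extra == {"vendor_id": "V123"}
    out = tmp_path / "c2.tsv"
    write_channels_tsv(back, out)
    assert "vendor_id" in out.read_text().splitlines()[0]


# -- JSON sidecars -----------------------------------------------------------

def test_motion_json_round_trip(tmp_path):
    path = tmp_path / "m.json"
    meta = TrackingSystemMeta(
        sampling_frequency=100, sampling_frequency_effective=99.87,
        tracking_system_name="imu rig", tracked_points_count=1,
        channel_counts={"ACCELChannelCount": 3, "MotionChannelCount": 3},
        extra={"Manufacturer": "ACME"})
    bids_io.write_motion_json(meta, path)
    text = path.read_text()
    assert '"SamplingFrequency": 100' in text
    back = bids_io.read_motion_json(path)
    assert back == meta


def test_motion_json_requires_sampling_frequency(tmp_path):
    path = tmp_path / "m.json"
    path.write_text("{\"TrackingSystemName\": \"x\"}")
    with pytest.raises(FormatError, match="SamplingFrequency"):
        bids_io.read_motion_json(path)


def test_channels_json_levels_round_trip(tmp_path):
    from motionbids.model import ReferenceFrame

    path = tmp_path / "c.json"
    frames = {"global": ReferenceFrame(label="global", spatial_axes="ARI",
                                       rotation_rule="right-hand",
                                       rotation_order="ZYX",
                                       description="lab space")}
    bids_io.write_channels_json(frames, path, passthrough={"Comment": "hi"})
    back, passthrough = bids_io.read_channels_json(path)
    assert back == frames
    assert passthrough == {"Comment": "hi"}


# -- events / scans ----------------------------------------------------------

def test_events_round_trip(tmp_path):
    import pandas as pd

    from motionbids.model import EventTable

    events = EventTable(pd.DataFrame(
        {"onset": [0.5, 1.5], "duration": [0.0, np.nan],
         "trial_type": ["a", "b"]}))
    path = tmp_path / "e.tsv"
    bids_io.write_events_tsv(events, path)
    assert "n/a" in path.read_text()
    back = bids_io.read_events_tsv(path)
    np.testing.assert_allclose(back.onsets, [0.5, 1.5])


def test_scans_acq_time_parsing(tmp_path):
    import pandas as pd

    from motionbids.model import ScansTable

    scans = ScansTable(pd.DataFrame({
        "filename": ["motion/a_motion.tsv"],
        "acq_time": ["2024-03-01T09:30:00.250"]}))
    path = tmp_path / "s.tsv"
    bids_io.write_scans_tsv(scans, path)
    back = bids_io.read_scans_tsv(path)
    when = back.acq_time("motion/a_motion.tsv")
    assert when.microsecond == 250000
    assert back.acq_time("nope") is None
    with pytest.raises(FormatError):
        bids_io.parse_acq_time("yesterday at noon")


# -- dataset assembly --------------------------------------------------------

def test_load_tracking_system_from_fixture(fig1_tree):
    inventory = scan_dataset(fig1_tree)
    assert len(inventory.recordings) == 1
    system = load_tracking_system(fig1_tree, inventory.recordings[0].entities)
    assert len(system.channels) == 6
    assert system.samples.shape == (1000, 6)
    assert system.meta.sampling_frequency == 100.0


def test_load_reports_column_count_mismatch(tmp_path, fig1_tree):
    import shutil

    root = tmp_path / "ds"
    shutil.copytree(fig1_tree, root)
    motion = next(root.rglob("*_motion.tsv"))
    lines = motion.read_text().splitlines()
    motion.write_text("\n".join("\t".join(l.split("\t")[:5]) for l in lines) + "\n")
    inventory = scan_dataset(root)
    with pytest.raises(FormatError, match="5 data columns ≠ 6"):
        load_tracking_system(root, inventory.recordings[0].entities)


def test_missing_companion_file(tmp_path, fig1_tree):
    import shutil

    root = tmp_path / "ds"
    shutil.copytree(fig1_tree, root)
    next(root.rglob("*_motion.json")).unlink()
    inventory = scan_dataset(root)
    with pytest.raises(FormatError, match="missing companion"):
        load_tracking_system(root, inventory.recordings[0].entities)


def test_two_tracking_systems_are_independent(spotrotation_tree):
    inventory = scan_dataset(spotrotation_tree)
    labels = sorted(r.entities.tracksys for r in inventory.recordings)
    assert labels == ["optical", "virtual"]
    systems = [load_tracking_system(spotrotation_tree, r.entities)
               for r in inventory.recordings]
    assert {len(s.channels) for s in systems} == {5, 7}


def test_dataset_round_trip_preserves_everything(tmp_path, spotrotation_tree):
    """dataset -> memory -> disk -> memory: metadata exact, samples exact."""
    inventory = scan_dataset(spotrotation_tree)
    copy_root = tmp_path / "copy"
    for rec in inventory.recordings:
        system = load_tracking_system(spotrotation_tree, rec.entities)
        save_tracking_system(system, copy_root)
        again = load_tracking_system(copy_root, rec.entities)
        assert again.meta == system.meta
        assert again.channels == system.channels
        assert again.reference_frames == system.reference_frames
        np.testing.assert_array_equal(again.samples, system.samples)
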