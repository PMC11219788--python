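"""Rule engine: clean fixtures pass, every corrupted REQUIRED element is
caught, vocabularies are closed, reports are deterministic."""

import itertools
import json
import shutil

import pytest

from motionbids.model import ROTATION_ORDERS, Severity
from motionbids.validator import severity_for, validate_dataset


def mutated(tree, tmp_path):
    root = tmp_path / "mutant"
    shutil.copytree(tree, root)
    return root


def find(root, pattern):
    return next(root.rglob(pattern))


def errors_for(root, path):
    report = validate_dataset(root)
    rel = path.relative_to(root).as_posix()
    return [f for f in report.errors if f.path == rel]


def test_severity_mapping():
    assert severity_for("REQUIRED") is Severity.error
    assert severity_for("RECOMMENDED") is Severity.warning
    assert severity_for("OPTIONAL") is Severity.info
    with pytest.raises(ValueError):
        severity_for("MANDATORY")


def test_clean_fixture_has_zero_errors(spotrotation_tree):
    report = validate_dataset(spotrotation_tree)
    assert report.errors == []


def test_validation_is_deterministic(spotrotation_tree):
    a = validate_dataset(spotrotation_tree).to_json()
    b = validate_dataset(spotrotation_tree).to_json()
    assert a == b


def test_missing_dataset_root(tmp_path):
    report = validate_dataset(tmp_path / "nope")
    assert report.errors


# -- mutation suite: every REQUIRED element, when corrupted, yields an
#    error naming the corrupted file ---------------------------------------


def test_deleting_motion_json_is_an_error(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    find(root, "*_motion.json").unlink()
    report = validate_dataset(root)
    assert any(f.rule_id == "R02" and "motion.json" in f.message
               for f in report.errors)


def test_missing_sampling_frequency(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_motion.json")
    data = json.loads(path.read_text())
    del data["SamplingFrequency"]
    path.write_text(json.dumps(data))
    assert any(f.rule_id == "R08" for f in errors_for(root, path))


def test_nonpositive_sampling_frequency(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_motion.json")
    data = json.loads(path.read_text())
    data["SamplingFrequency"] = 0
    path.write_text(json.dumps(data))
    assert any(f.rule_id == "R08" for f in errors_for(root, path))


@pytest.mark.parametrize("column",
                         ["name", "component", "type", "tracked_point", "units"])
def test_deleting_each_required_channels_column(fig1_tree, tmp_path, column):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_channels.tsv")
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    idx = header.index(column)
    out = ["\t".join(f for i, f in enumerate(line.split("\t")) if i != idx)
           for line in lines]
    path.write_text("\n".join(out) + "\n")
    findings = errors_for(root, path)
    assert any(f.rule_id == "R04" and column in f.message for f in findings)


def test_empty_required_cell(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_channels.tsv")
    lines = path.read_text().splitlines()
    fields = lines[1].split("\t")
    fields[3] = "n/a"  # tracked_point
    lines[1] = "\t".join(fields)
    path.write_text("\n".join(lines) + "\n")
    assert any(f.rule_id == "R04" and "tracked_point" in f.message
               for f in errors_for(root, path))


def test_column_count_mismatch(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_motion.tsv")
    lines = path.read_text().splitlines()
    path.write_text("\n".join("\t".join(l.split("\t")[:5]) for l in lines) + "\n")
    findings = errors_for(root, path)
    assert any(f.rule_id == "R03" and "5" in f.message and "6" in f.message
               for f in findings)


def test_ragged_row(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_motion.tsv")
    lines = path.read_text().splitlines()
    lines[4] = "\t".join(lines[4].split("\t")[:4])
    path.write_text("\n".join(lines) + "\n")
    assert any(f.rule_id == "R03" and "row 5" in f.message
               for f in errors_for(root, path))


def test_bad_filename_entity(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_motion.tsv")
    bad = path.with_name("sub-001_tracksys-imu_motion.tsv")  # task missing
    path.rename(bad)
    report = validate_dataset(root)
    assert any(f.rule_id == "R01" and bad.name in f.path for f in report.errors)


def test_unknown_type_and_component(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_channels.tsv")
    lines = path.read_text().splitlines()
    row1 = lines[1].split("\t")
    row1[1], row1[2] = "sideways", "WOBBLE"
    lines[1] = "\t".join(row1)
    path.write_text("\n".join(lines) + "\n")
    findings = errors_for(root, path)
    assert any(f.rule_id == "R05" for f in findings)
    assert any(f.rule_id == "R06" for f in findings)


def test_misplaced_motion_file(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_motion.tsv")
    stray = root / "sub-001" / path.name
    shutil.copy(path, stray)
    report = validate_dataset(root)
    assert any(f.rule_id == "R02" and "subdirectory" in f.message
               for f in report.errors)


def test_decreasing_latency(spotrotation_tree, tmp_path):
    root = mutated(spotrotation_tree, tmp_path)
    path = find(root, "*tracksys-virtual_motion.tsv")
    lines = path.read_text().splitlines()
    fields = lines[10].split("\t")
    fields[-1] = "-1.0"  # latency is the last column of this fixture
    lines[10] = "\t".join(fields)
    path.write_text("\n".join(lines) + "\n")
    assert any(f.rule_id == "R14" for f in errors_for(root, path))


def test_unresolvable_scans_filename(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_scans.tsv")
    text = path.read_text().replace("tracksys-imu", "tracksys-gone")
    path.write_text(text)
    assert any(f.rule_id == "R16" for f in errors_for(root, path))


# -- reference-frame vocabulary rules ---------------------------------------


def _set_frame_field(root, field, value):
    path = find(root, "*_channels.json")
    data = json.loads(path.read_text())
    data["reference_frame"]["Levels"]["global"][field] = value
    path.write_text(json.dumps(data))
    return path


def test_rotation_order_vocabulary_closure(spotrotation_tree, tmp_path):
    """Of the 27 three-letter strings over {X,Y,Z}, exactly the 6
    distinct-axis permutations are accepted; XYX-style sequences are not."""
    accepted = []
    for letters in itertools.product("XYZ", repeat=3):
        candidate = "".join(letters)
        root = tmp_path / candidate
        shutil.copytree(spotrotation_tree, root)
        path = _set_frame_field(root, "RotationOrder", candidate)
        report = validate_dataset(root)
        r12 = [f for f in report.errors if f.rule_id == "R12"]
        if not r12:
            accepted.append(candidate)
        shutil.rmtree(root)
    assert sorted(accepted) == sorted(ROTATION_ORDERS)
    assert len(accepted) == 6


def test_rotation_rule_keywords(spotrotation_tree, tmp_path):
    root = mutated(spotrotation_tree, tmp_path)
    path = _set_frame_field(root, "RotationRule", "counterclockwise")
    assert any(f.rule_id == "R11" for f in errors_for(root, path))


def test_spatial_axes_grammar_rules(spotrotation_tree, tmp_path):
    # "A_R" (unused Y axis) is valid; "AAR" assigns one dimension twice
    root = mutated(spotrotation_tree, tmp_path)
    path = _set_frame_field(root, "SpatialAxes", "A_R")
    assert not any(f.rule_id == "R10" for f in validate_dataset(root).errors)
    _set_frame_field(root, "SpatialAxes", "AAR")
    assert any(f.rule_id == "R10" for f in errors_for(root, path))


def test_unresolved_reference_frame_label_warns(spotrotation_tree, tmp_path):
    root = mutated(spotrotation_tree, tmp_path)
    path = find(root, "*tracksys-virtual_channels.json")
    data = json.loads(path.read_text())
    data["reference_frame"]["Levels"] = {"other": {}}
    path.write_text(json.dumps(data))
    report = validate_dataset(root)
    assert any(f.rule_id == "R13" and f.severity is Severity.warning
               for f in report.findings)


def test_events_without_tracksys_warns_with_multiple_systems(
        spotrotation_tree, tmp_path):
    root = mutated(spotrotation_tree, tmp_path)
    motion_dir = find(root, "*tracksys-virtual_motion.tsv").parent
    shared = motion_dir / "sub-001_task-rotation_events.tsv"
    shared.write_text("onset\tduration\n1.0\t0\n")
    report = validate_dataset(root)
    assert report.errors == []
    assert any(f.rule_id == "R15" and f.severity is Severity.warning
               for f in report.findings)


def test_channel_count_mismatch_warns(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_motion.json")
    data = json.loads(path.read_text())
    data["ACCELChannelCount"] = 7
    path.write_text(json.dumps(data))
    report = validate_dataset(root)
    assert report.errors == []
    assert any(f.rule_id == "R09" for f in report.warnings)


def test_header_only_events_file_is_valid(fig1_tree, tmp_path):
    root = mutated(fig1_tree, tmp_path)
    path = find(root, "*_events.tsv")
    path.write_text("onset\tduration\ttrial_type\n")
    assert validate_dataset(root).errors == []
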