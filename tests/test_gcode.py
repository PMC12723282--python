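"""G-code emission, parsing, wash routine, and the round-trip contract."""

import re

import numpy as np
import pytest

import scratchkit as sk
from scratchkit.errors import GcodeError
from scratchkit.gcode import _quantize_local

MOTION_RE = re.compile(r"^G[01]\b")


def motion_lines(program):
    return [ln for ln in program.lines if MOTION_RE.match(ln)]


def test_program_structure(single_line_program_24):
    lines = single_line_program_24.lines
    body = [ln for ln in lines if not ln.startswith(";")]
    assert body[0].startswith("G21")
    assert body[1].startswith("G90")
    assert body[2] == "G28"
    assert body[3] == "G29"  # auto-leveling on, as in the validated protocol
    assert lines[-3] == "; park"
    assert "Z" in lines[-2] and "X0.000" in lines[-1]


def test_every_motion_command_carries_6000_feed(single_line_program_24):
    for ln in motion_lines(single_line_program_24):
        assert ln.endswith("F6000"), ln


def test_two_cycles_traverse_each_polyline_back_and_forth(plate24, single_line_spec):
    parsed = sk.parse_program(single_line_program(plate24, single_line_spec, ["B2"]))
    scratch = parsed.scratch_segments("B2")
    assert len(scratch) == 2  # one chord, run twice
    # second traversal reverses the first
    assert scratch[1].start == scratch[0].end and scratch[1].end == scratch[0].start
    assert sk.traversal_counts(parsed.segments) == [("B2", 2)]


def single_line_program(plate, spec, wells):
    r = sk.safe_radius(plate, spec.tip_offset)
    return sk.emit_program(plate, wells, sk.generate_paths(spec, r), spec)


def test_single_cycle_n_point_polyline_emits_n_minus_1_scratch_moves(plate24):
    spec = sk.PatternSpec(mode="circle", inner_radius=2.0, radial_step=10.0,
                          scratch_cycles=1)
    r = sk.safe_radius(plate24, spec.tip_offset)
    (ring,) = sk.generate_paths(spec, r)
    program = sk.emit_program(plate24, ["A1"], [ring], spec)
    parsed = sk.parse_program(program)
    assert len(parsed.scratch_segments("A1")) == len(ring) - 1


def test_round_trip_recovers_planned_coordinates(plate6, mesh18_spec):
    r = sk.safe_radius(plate6, mesh18_spec.tip_offset)
    paths = sk.generate_paths(mesh18_spec, r)
    program = sk.emit_program(plate6, ["B3"], paths, mesh18_spec)
    parsed = sk.parse_program(program)
    center = sk.well_center(plate6, "B3")
    planned = np.vstack([_quantize_local(p.points) + center for p in paths])
    got = np.vstack([[s.start[:2], s.end[:2]] for s in parsed.scratch_segments("B3")])
    # every parsed endpoint matches a planned point to within a micron
    d = np.linalg.norm(got[:, None, :] - planned[None, :, :], axis=2)
    assert d.min(axis=1).max() <= 1e-6


def test_census_of_three_full_24well_plates_totals_72(plate24, single_line_spec):
    total = 0
    for _ in range(3):
        parsed = sk.parse_program(
            single_line_program(plate24, single_line_spec, sk.all_wells(plate24))
        )
        total += parsed.total_scratch_blocks
    assert total == 72


def test_mesh18_parser_recovers_18_distinct_lines(mesh18_program_6):
    parsed = sk.parse_program(mesh18_program_6)
    for well in ("A1", "B3"):
        assert sk.count_distinct_lines(parsed.segments, well) == 18


def test_no_scratch_motion_outside_well_blocks(mesh18_program_6):
    parsed = sk.parse_program(mesh18_program_6)
    assert all(s.well is not None for s in parsed.segments if s.kind == "scratch")
    assert "?" not in parsed.census


def test_prefix_stability_of_well_blocks(plate24, single_line_spec):
    def block(program, label):
        lines = program.lines
        start = lines.index(f"; well {label}")
        end = next(i for i in range(start + 1, len(lines))
                   if lines[i].startswith("; "))
        return lines[start:end]

    one = single_line_program(plate24, single_line_spec, ["A1"])
    two = single_line_program(plate24, single_line_spec, ["A1", "A2"])
    assert block(one, "A1") == block(two, "A1")


def test_feed_above_machine_limit_fails(plate24, single_line_spec):
    import dataclasses
    fast = dataclasses.replace(single_line_spec, scratch_feed=20000.0)
    with pytest.raises(GcodeError, match="max_feed"):
        single_line_program(plate24, fast, ["A1"])


def test_path_outside_safe_radius_refused(plate24, single_line_spec):
    far = [sk.Polyline([(-10.0, 0.0), (10.0, 0.0)])]
    with pytest.raises(GcodeError, match="safe radius"):
        sk.emit_program(plate24, ["A1"], far, single_line_spec)


WASHER = sk.MachineProfile(wash_station=sk.WashStation(10.0, 150.0, 2.0, 30.0))


def test_wash_both_emits_two_30s_dwells(plate24, single_line_spec):
    r = sk.safe_radius(plate24, single_line_spec.tip_offset)
    program = sk.emit_program(plate24, ["A1"], sk.generate_paths(single_line_spec, r),
                              single_line_spec, WASHER, wash="both")
    dwells = [ln for ln in program.lines if ln.startswith("G4")]
    assert dwells == ["G4 S30", "G4 S30"]
    parsed = sk.parse_program(program)
    assert [s.dwell_s for s in parsed.segments if s.kind == "dwell"] == [30.0, 30.0]
    # wash comes before the first well and after the last scratch
    assert program.lines.index("; wash") < program.lines.index("; well A1")


def test_insert_wash_before_on_empty_program():
    empty = sk.GCodeProgram.from_text(
        "; travel_z_mm = 6.200\n; travel_feed_mm_min = 6000\n"
        "; scratch_feed_mm_min = 6000\n"
        "G21\nG90\nG28\n; park\nG0 Z6.200 F6000\nG0 X0.000 Y0.000 F6000\n"
    )
    washed = sk.insert_wash(empty, WASHER, when="before")
    assert washed.lines.index("; wash") < washed.lines.index("; park")
    assert sum(1 for ln in washed.lines if ln.startswith("G4")) == 1


def test_zero_dwell_warns_and_emits_no_dwell(plate24, single_line_spec):
    profile = sk.MachineProfile(wash_station=sk.WashStation(10.0, 150.0, 2.0, 0.0))
    r = sk.safe_radius(plate24, single_line_spec.tip_offset)
    with pytest.warns(UserWarning, match="dwell"):
        program = sk.emit_program(plate24, ["A1"], sk.generate_paths(single_line_spec, r),
                                  single_line_spec, profile, wash="before")
    assert not any(ln.startswith("G4") for ln in program.lines)


def test_wash_station_inside_plate_footprint_fails(plate24, single_line_spec):
    inside = sk.MachineProfile(
        wash_station=sk.WashStation(plate24.a1_center_x, plate24.a1_center_y, 2.0)
    )
    r = sk.safe_radius(plate24, single_line_spec.tip_offset)
    with pytest.raises(GcodeError, match="collision"):
        sk.emit_program(plate24, ["A1"], sk.generate_paths(single_line_spec, r),
                        single_line_spec, inside, wash="before")


def test_wash_without_station_fails(plate24, single_line_spec):
    r = sk.safe_radius(plate24, single_line_spec.tip_offset)
    with pytest.raises(GcodeError, match="wash_station"):
        sk.emit_program(plate24, ["A1"], sk.generate_paths(single_line_spec, r),
                        single_line_spec, sk.GENERIC_PROFILE, wash="before")


def test_relative_mode_rejected(single_line_program_24):
    text = single_line_program_24.text.replace("G90 ; absolute positioning", "G91")
    with pytest.raises(GcodeError, match="G91"):
        sk.parse_program(text)


def test_unknown_command_reports_line_number(single_line_program_24):
    lines = list(single_line_program_24.lines)
    lines.insert(25, "G33 X1")
    with pytest.raises(GcodeError, match="line 26"):
        sk.parse_program("\n".join(lines))


def test_machine_profile_yaml_round_trip(tmp_path):
    doc = tmp_path / "prusa.yaml"
    doc.write_text(
        "name: prusa\nmax_feed: 9000\nwash_station: {x: 5, y: 190, z: 1, dwell_s: 45}\n"
    )
    profile = sk.load_machine_profile(doc)
    assert profile.name == "prusa" and profile.max_feed == 9000
    assert profile.wash_station.dwell_s == 45
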