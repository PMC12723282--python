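"""Swept-footprint rasterization against polygon oracles; constraint checks."""

import dataclasses

import numpy as np
import pytest
from shapely.geometry import LineString, Point
from shapely.ops import unary_union
from skimage.measure import label as cc_label

import scratchkit as sk
from scratchkit.errors import SimulationError

TIP200 = sk.TIP_PRESETS["200"]
TIP1000 = sk.TIP_PRESETS["1000"]


def stadium_oracle_area(segments, radius):
    """Independent union-of-stadia area via shapely round-capped buffers."""
    shapes = []
    for a in segments:
        a = np.asarray(a, dtype=float)
        geom = Point(a[0]) if np.allclose(a[0], a[1]) else LineString(a)
        shapes.append(geom.buffer(radius, quad_segs=256))
    return unary_union(shapes).area


def test_single_stadium_area_within_half_percent():
    seg = [np.array([[-5.0, 0.0], [5.0, 0.0]])]
    mask = sk.swept_mask(seg, TIP200, pixel_size=10.0, well_diameter=13.0)
    exact = 10.0 * 0.8 + np.pi * 0.4**2
    assert mask.wound_area_mm2 == pytest.approx(exact, rel=5e-3)


def test_zero_length_segment_sweeps_a_disk():
    seg = [np.array([[0.0, 0.0], [0.0, 0.0]])]
    mask = sk.swept_mask(seg, TIP200, pixel_size=10.0, well_diameter=3.0)
    assert mask.wound_area_mm2 == pytest.approx(np.pi * 0.4**2, rel=5e-3)


def test_crossing_segments_area_counts_overlap_once():
    segs = [np.array([[-4.0, 0.0], [4.0, 0.0]]), np.array([[0.0, -4.0], [0.0, 4.0]])]
    mask = sk.swept_mask(segs, TIP200, pixel_size=10.0, well_diameter=11.0)
    stadium = 8.0 * 0.8 + np.pi * 0.4**2
    assert mask.wound_area_mm2 < 2 * stadium
    assert mask.wound_area_mm2 == pytest.approx(stadium_oracle_area(segs, 0.4), rel=5e-3)


def test_raster_converges_to_polygon_oracle_with_pixel_size():
    segs = [np.array([[-3.0, -1.0], [3.0, 1.3]]), np.array([[-2.0, 2.0], [2.0, -2.0]])]
    exact = stadium_oracle_area(segs, 0.4)
    errs = []
    for px in (40.0, 20.0, 10.0):
        mask = sk.swept_mask(segs, TIP200, pixel_size=px, well_diameter=9.0)
        errs.append(abs(mask.wound_area_mm2 - exact))
    assert errs[2] <= errs[0]
    # error scales like O(pixel size): the finest raster is within 0.5%
    assert errs[2] / exact < 5e-3


def test_centered_line_mask_invariant_under_180_rotation():
    seg = [np.array([[-5.0, 0.0], [5.0, 0.0]])]
    mask = sk.swept_mask(seg, TIP200, pixel_size=20.0, well_diameter=12.0)
    assert np.array_equal(mask.grid, mask.grid[::-1, ::-1])


def test_mesh_leaves_bridges_of_line_distance_minus_width():
    # two adjacent mesh lines 1.6 mm apart swept by the 1.2 mm tip leave a
    # 0.4 mm cell bridge between them
    segs = [np.array([[-5.0, -0.8], [5.0, -0.8]]), np.array([[-5.0, 0.8], [5.0, 0.8]])]
    mask = sk.swept_mask(segs, TIP1000, pixel_size=10.0, well_diameter=13.0)
    mid = mask.grid[:, mask.grid.shape[1] // 2]
    ys = mask.y_coords()
    bridge = ~mid & (ys > -0.8) & (ys < 0.8)
    assert bridge.sum() * mask.pixel_mm == pytest.approx(0.4, abs=2 * mask.pixel_mm)


def test_grid_pattern_partitions_disk_into_islands():
    spec = sk.PatternSpec(mode="grid", line_number=3, line_distance=3.0, tip_offset=2.0)
    r_safe = 7.8  # 24-well geometry with 2 mm offset... offsets +/-3 < 7.8
    paths = sk.generate_paths(spec, r_safe)
    mask = sk.swept_mask_from_polylines(paths, sk.TipSpec("custom", 0.5),
                                        pixel_size=25.0, well_diameter=2 * r_safe + 1)
    coords = mask.x_coords()
    inside = (coords[None, :] ** 2 + coords[:, None] ** 2) < (r_safe - 0.05) ** 2
    islands = cc_label(~mask.grid & inside, connectivity=1)
    counts = np.bincount(islands.ravel())[1:]
    n_islands = (counts > 10).sum()  # ignore sliver artifacts at the rim
    assert n_islands == (3 + 1) ** 2


def test_undersampled_pixel_size_fails():
    with pytest.raises(SimulationError, match="undersample"):
        sk.swept_mask([np.array([[0.0, 0.0], [1.0, 0.0]])], TIP200,
                      pixel_size=500.0, well_diameter=4.0)


def test_empty_segments_fail():
    with pytest.raises(SimulationError, match="empty"):
        sk.swept_mask([], TIP200)


def test_non_scratch_segments_rejected():
    seg = sk.ToolpathSegment((0, 0, 6), (1, 0, 6), 6000.0, "travel")
    with pytest.raises(SimulationError, match="travel"):
        sk.swept_mask([seg], TIP200, well_diameter=4.0)


def test_mask_png_sidecar_round_trip(tmp_path):
    seg = [np.array([[-2.0, 0.0], [2.0, 0.0]])]
    mask = sk.swept_mask(seg, TIP200, pixel_size=20.0, well_diameter=6.0)
    sk.save_mask(mask, tmp_path / "w.png")
    back = sk.load_mask(tmp_path / "w.png")
    assert np.array_equal(mask.grid, back.grid)
    assert back.pixel_size == mask.pixel_size
    assert back.origin == pytest.approx(mask.origin)


# ---------------------------------------------------------------------------
# constraint checking

def test_validated_single_line_program_clears_wall_by_2mm(
        plate24, single_line_spec, single_line_program_24):
    parsed = sk.parse_program(single_line_program_24)
    report = sk.check_constraints(parsed.segments, plate24, single_line_spec)
    assert report.ok
    assert report.min_wall_clearance == pytest.approx(2.0, abs=1e-6)
    assert report.max_feed_seen == pytest.approx(6000.0)
    assert all(c == 2 for _, c in report.traversals_per_polyline)


def test_tampered_point_outside_safe_circle_is_flagged(
        plate24, single_line_spec, single_line_program_24):
    cx = plate24.a1_center_x
    bad = single_line_program_24.text.replace(
        f"X{cx - 5.8:.3f}", f"X{cx - 7.5:.3f}")
    parsed = sk.parse_program(bad)
    report = sk.check_constraints(parsed.segments, plate24, single_line_spec)
    assert not report.ok
    assert any("A1" in v and "clearance" in v for v in report.violations)


def test_edited_feed_above_configuration_is_flagged(
        plate24, single_line_spec, single_line_program_24):
    fast = single_line_program_24.text.replace("F6000", "F9000")
    parsed = sk.parse_program(fast)
    report = sk.check_constraints(parsed.segments, plate24, single_line_spec)
    assert any("feed" in v for v in report.violations)


def test_clearance_fuzz_never_below_tip_offset(plate6):
    """Emitted programs keep every scratch point at least tip_offset from
    the wall, over randomized patterns (quantization rounds toward the
    center, never outward)."""
    from conftest import random_pattern_spec
    rng = np.random.default_rng(42)
    for _ in range(40):
        spec = random_pattern_spec(rng, sk.safe_radius(plate6, 2.0))
        spec = dataclasses.replace(spec, tip_offset=2.0)
        paths = sk.generate_paths(spec, sk.safe_radius(plate6, 2.0))
        program = sk.emit_program(plate6, ["A2"], paths, spec)
        parsed = sk.parse_program(program)
        report = sk.check_constraints(parsed.segments, plate6, spec)
        assert report.min_wall_clearance >= 2.0 - 1e-9
        assert report.ok
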