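"""Wound metrics (area, width, straightness) and replicate statistics."""

import math

import numpy as np
import pytest

import scratchkit as sk
from scratchkit.errors import QuantError
from scratchkit.simulate import WoundMask


def rect_gap_mask(width_um=900.0, length_mm=3.0, pixel=10.0, frame_mm=5.0):
    """Hand-built mask with a perfect rectangular gap along x."""
    px = pixel / 1000.0
    n = int(round(frame_mm / px))
    coords = (np.arange(n) - n / 2 + 0.5) * px
    grid = np.zeros((n, n), dtype=bool)
    half_w = width_um / 2000.0
    cols = np.abs(coords) < length_mm / 2
    rows = np.abs(coords) < half_w
    grid[np.ix_(rows, cols)] = True
    return WoundMask(grid=grid, pixel_size=pixel, origin=(coords[0], coords[0]),
                     well_diameter=frame_mm)


def test_rectangular_gap_recovers_width_and_zero_sd():
    m = sk.wound_metrics(rect_gap_mask(), axis="x")
    assert m.mean_width == pytest.approx(900.0)
    assert m.sd_width == 0.0
    assert m.area == pytest.approx(0.9 * 3.0, rel=2e-2)


def test_simulated_stadium_interior_width_matches_tip():
    seg = [np.array([[-5.0, 0.0], [5.0, 0.0]])]
    mask = sk.swept_mask(seg, sk.TIP_PRESETS["200"], pixel_size=10.0, well_diameter=13.0)
    m = sk.wound_metrics(mask, axis="x", end_cap_mm=0.4)
    assert m.mean_width == pytest.approx(800.0, abs=mask.pixel_size)
    assert m.sd_width <= mask.pixel_size / math.sqrt(12)


def test_mean_width_equals_mean_of_profile():
    m = sk.wound_metrics(rect_gap_mask(), axis="x")
    assert m.mean_width == pytest.approx(float(np.mean(m.width_profile)))
    assert m.n_stations == len(m.width_profile)


def test_area_consistency_width_times_extent():
    m = sk.wound_metrics(rect_gap_mask(width_um=800, length_mm=4.0, frame_mm=6.0),
                         axis="x")
    extent_mm = m.n_stations * 10.0 / 1000.0
    assert m.mean_width / 1000.0 * extent_mm == pytest.approx(m.area, rel=2e-2)


def sine_edge_mask(amplitude_um, periods=8, width_um=900.0, pixel=10.0):
    """One edge perturbed by a*sin over whole periods, the other straight."""
    length_mm = 6.0
    px = pixel / 1000.0
    ncols = int(round(length_mm / px))
    n = int(round(8.0 / px))
    coords = (np.arange(n) - n / 2 + 0.5) * px
    grid = np.zeros((n, n), dtype=bool)
    x = np.arange(ncols) * px
    upper = width_um / 2000.0 + amplitude_um / 1000.0 * np.sin(
        2 * np.pi * periods * x / length_mm)
    lower = -width_um / 2000.0
    col0 = n // 2 - ncols // 2
    for j in range(ncols):
        grid[:, col0 + j] = (coords > lower) & (coords < upper[j])
    mask = WoundMask(grid=grid, pixel_size=pixel, origin=(coords[0], coords[0]),
                     well_diameter=8.0)
    return mask, upper - lower


def test_sinusoidal_edge_sd_matches_brute_force_profile():
    amplitude = 100.0
    mask, true_width_mm = sine_edge_mask(amplitude)
    m = sk.wound_metrics(mask, axis="x")
    # closed form: SD of w0 + a sin is a / sqrt(2) over whole periods
    assert m.sd_width == pytest.approx(amplitude / math.sqrt(2), rel=0.05)
    # and the brute-force SD of the generating profile agrees
    brute = float(np.std(true_width_mm * 1000.0, ddof=1))
    assert m.sd_width == pytest.approx(brute, rel=0.05)


def test_empty_mask_fails():
    m = rect_gap_mask()
    with pytest.raises(QuantError, match="no wound pixels"):
        sk.wound_metrics(WoundMask(grid=np.zeros_like(m.grid), pixel_size=10.0,
                                   origin=m.origin, well_diameter=5.0))


def test_wound_touching_border_warns():
    m = rect_gap_mask(length_mm=6.0, frame_mm=5.0)  # gap spans the frame
    with pytest.warns(UserWarning, match="border"):
        sk.wound_metrics(m, axis="x")


def test_auto_axis_matches_explicit_axis():
    m_auto = sk.wound_metrics(rect_gap_mask(), axis="auto")
    m_x = sk.wound_metrics(rect_gap_mask(), axis="x")
    assert m_auto.mean_width == pytest.approx(m_x.mean_width, abs=10.0)


# ---------------------------------------------------------------------------
# replicate statistics

def test_cv_of_identical_values_is_zero():
    assert sk.cv([5.0, 5.0, 5.0]).cv_percent == 0.0


def test_cv_hand_calculation():
    stats = sk.cv([9.0, 11.0])
    assert stats.mean == pytest.approx(10.0)
    assert stats.sd == pytest.approx(math.sqrt(2.0))
    assert stats.cv_percent == pytest.approx(14.142, abs=1e-3)


def test_cv_of_72_widths_with_1p6_percent_jitter():
    rng = np.random.default_rng(7)
    widths = 900.0 * (1.0 + rng.normal(0.0, 0.016, size=72))
    assert 1.1 <= sk.cv(widths).cv_percent <= 2.1


def test_cv_is_scale_invariant():
    rng = np.random.default_rng(11)
    values = rng.uniform(5, 15, size=20)
    assert sk.cv(values * 7.3).cv_percent == pytest.approx(sk.cv(values).cv_percent)


def test_cv_requires_two_values_and_positive_mean():
    with pytest.raises(QuantError):
        sk.cv([1.0])
    with pytest.raises(QuantError):
        sk.cv([-2.0, 0.0])


def test_relative_difference_reproduces_printer_comparison():
    # mean widths of the two printers: 925.7 vs 971.2 um -> 4.68 %
    assert sk.relative_difference(925.7, 971.2) == pytest.approx(4.68, abs=5e-3)
    assert sk.relative_difference(971.2, 925.7) == pytest.approx(4.68, abs=5e-3)


def test_relative_difference_definition():
    assert sk.relative_difference(3.3, 3.3) == 0.0
    assert sk.relative_difference(1.0, 2.0) == pytest.approx(50.0)
    with pytest.raises(QuantError):
        sk.relative_difference(0.0, 1.0)


def test_ratio_reproduces_migration_area_contrast():
    # FCS-containing vs FCS-free migration areas: 0.266 / 0.158 cm^2 -> 1.68x
    assert round(sk.ratio(0.266, 0.158), 2) == 1.68


def test_ratio_definition():
    assert sk.ratio(4.2, 4.2) == 1.0
    assert sk.ratio(0.0, 5.0) == 0.0
    with pytest.raises(QuantError):
        sk.ratio(1.0, 0.0)
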