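"""Wound metrics and replicate-reproducibility statistics from binary masks.

For a straight scratch the mask is sliced into *stations* — successive
pixel columns perpendicular to the scratch axis.  The width at a station
is the count of wound pixels in that column times the pixel size (runs of
a multiply-connected column sum), which for a clean straight scratch
equals the gap width.  The mean width characterizes the wound, and the
standard deviation of the width profile operationalizes *straightness*.
Stations within half a contact width of the wound's axial extremes are
excluded so the rounded stadium end caps do not bias the statistics.

Replicate statistics use the sample (n-1) standard deviation; the
coefficient of variation is ``100 * sd / mean``.  The relative difference
between two means normalizes by the larger value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import QuantError
from .simulate import WoundMask

__all__ = ["WoundMetrics", "ReplicateStats", "wound_metrics", "cv",
           "relative_difference", "ratio"]


@dataclass(frozen=True)
class WoundMetrics:
    """Geometry of a single wound: area (mm^2), width stats (um)."""

    area: float  # mm^2, all wound pixels
    mean_width: float  # um, over included stations
    sd_width: float  # um, sample SD over included stations (straightness)
    width_profile: np.ndarray  # um per included station, axial order
    n_stations: int

    def __post_init__(self) -> None:
        if self.area < 0 or self.sd_width < 0:
            raise QuantError("negative area or SD")


@dataclass(frozen=True)
class ReplicateStats:
    """Mean, SD and CV of a metric across replicate scratches."""

    n: int
    mean: float
    sd: float
    cv_percent: float


def _principal_axis(xs: np.ndarray, ys: np.ndarray) -> float:
    """Orientation (radians) of the principal axis of the wound pixels."""
    x = xs - xs.mean()
    y = ys - ys.mean()
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]
    return math.atan2(v[1], v[0])


def wound_metrics(
    mask: WoundMask,
    axis: "str | float" = "x",
    end_cap_mm: float = 0.0,
) -> WoundMetrics:
    """Measure a single straight scratch on a binary wound mask.

    ``axis`` is the scratch direction: ``"x"``, ``"y"``, an angle in
    degrees, or ``"auto"`` to estimate it as the principal axis of the
    wound pixels.  ``end_cap_mm`` excludes stations within that axial
    distance of the wound's extremes (use ``contact_width / 2`` for
    simulated stadium footprints).

    Area counts *all* wound pixels (caps included); width statistics use
    the included stations only.
    """
    grid = mask.grid
    iy, ix = np.nonzero(grid)
    if iy.size == 0:
        raise QuantError("no wound pixels in mask")
    if (iy.min() == 0 or ix.min() == 0
            or iy.max() == grid.shape[0] - 1 or ix.max() == grid.shape[1] - 1):
        warnings.warn("wound touches the mask border: metrics may be truncated",
                      stacklevel=2)

    px = mask.pixel_mm
    xs = mask.origin[0] + ix * px
    ys = mask.origin[1] + iy * px

    if axis == "auto":
        theta = _principal_axis(xs, ys)
    elif axis == "x":
        theta = 0.0
    elif axis == "y":
        theta = math.pi / 2.0
    else:
        theta = math.radians(float(axis))

    # axial coordinate of each wound pixel; bin into stations one pixel
    # wide, anchored at the wound's axial minimum so station indices land
    # on near-exact integers regardless of the grid's phase
    axial = xs * math.cos(theta) + ys * math.sin(theta)
    station = np.round((axial - axial.min()) / px).astype(np.int64)
    counts = np.bincount(station, minlength=int(station.max()) + 1)
    s_min, s_max = 0, int(station.max())

    cap_stations = int(round(end_cap_mm / px))
    included = counts[cap_stations : len(counts) - cap_stations] if cap_stations else counts
    included = included[included > 0]
    if included.size == 0:
        raise QuantError(
            f"no stations left after excluding {end_cap_mm} mm end caps "
            f"(wound axial extent {(s_max - s_min + 1) * px:.3f} mm)"
        )

    widths_um = included.astype(float) * mask.pixel_size
    area = float(grid.sum()) * mask.pixel_area_mm2
    mean_w = float(widths_um.mean())
    sd_w = float(widths_um.std(ddof=1)) if widths_um.size > 1 else 0.0
    return WoundMetrics(
        area=area,
        mean_width=mean_w,
        sd_width=sd_w,
        width_profile=widths_um,
        n_stations=int(widths_um.size),
    )


def cv(values) -> ReplicateStats:
    """Coefficient of variation of replicate measurements, in percent.

    Sample (n-1) standard deviation; requires at least two values and a
    positive mean.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise QuantError(f"need >= 2 values for a CV, got {arr.size}")
    mean = float(arr.mean())
    if mean <= 0:
        raise QuantError(f"CV undefined for non-positive mean ({mean})")
    sd = float(arr.std(ddof=1))
    return ReplicateStats(n=int(arr.size), mean=mean, sd=sd, cv_percent=100.0 * sd / mean)


def relative_difference(a: float, b: float) -> float:
    """Percent difference between two positive means, ``100 |a-b| / max(a, b)``.

    Normalizing by the larger value keeps the result symmetric and within
    [0, 100).
    """
    if a <= 0 or b <= 0:
        raise QuantError("relative_difference requires positive inputs")
    return 100.0 * abs(a - b) / max(a, b)


def ratio(a: float, b: float) -> float:
    """Plain ratio ``a / b`` (e.g. treated vs control migration area)."""
    if b <= 0:
        raise QuantError("ratio denominator must be > 0")
    if a < 0:
        raise QuantError("ratio numerator must be >= 0")
    return a / b
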