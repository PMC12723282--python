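"""Predict wound footprints from toolpaths and run safety/constraint checks.

The wound left by a scratch is modelled as the *swept footprint* of the
tip: a disk of the tip's contact width moved along each scratch segment,
i.e. the union of stadia (rectangle plus two half-disks per segment).
:func:`swept_mask` rasterizes that union onto a binary grid with a
pixel-center point-in-stadium test — no anti-aliasing, because the
downstream quantifier consumes binary masks.

The nominal contact width is used by default; on real plates the tip
vibrates and pushes a cluster of cells ahead of it, so realized scratches
are somewhat wider.  The effective width is therefore an explicit
parameter (pass a custom :class:`~scratchkit.plate.TipSpec`), never a
hidden calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SimulationError
from .gcode import ToolpathSegment, traversal_counts
from .paths import Polyline
from .patterns import PatternSpec
from .plate import PlateSpec, TipSpec, well_center

__all__ = ["WoundMask", "ConstraintReport", "swept_mask", "swept_mask_from_polylines",
           "check_constraints"]


@dataclass
class WoundMask:
    """Binary wound raster over one well.

    ``grid[iy, ix]`` is True where the monolayer has been removed.  Pixel
    (0, 0) has its *center* at ``origin`` (well-local mm); pixel centers
    advance by ``pixel_size`` micrometres along +x (columns) and +y (rows).
    """

    grid: np.ndarray  # bool, (ny, nx)
    pixel_size: float  # um
    origin: tuple[float, float]  # well-local mm of pixel (0, 0) center
    well_diameter: float  # mm

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise SimulationError("pixel_size must be > 0")
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise SimulationError("mask grid must be 2D")

    @property
    def pixel_mm(self) -> float:
        return self.pixel_size / 1000.0

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_mm ** 2

    @property
    def wound_area_mm2(self) -> float:
        return float(self.grid.sum()) * self.pixel_area_mm2

    def x_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.grid.shape[1]) * self.pixel_mm

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.grid.shape[0]) * self.pixel_mm


@dataclass
class ConstraintReport:
    """Outcome of checking a parsed program against plate and pattern."""

    min_wall_clearance: float  # mm, over all scratch-height coordinates
    max_feed_seen: float  # mm/min
    traversals_per_polyline: list[tuple[str, int]]
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _segments_to_xy(segments) -> list[np.ndarray]:
    out = []
    for s in segments:
        if isinstance(s, ToolpathSegment):
            out.append(s.xy)
        else:
            a = np.asarray(s, dtype=float)
            if a.shape != (2, 2):
                raise SimulationError(f"segment must be 2x2 [start, end], got {a.shape}")
            out.append(a)
    return out


def swept_mask(
    segments: Sequence[ToolpathSegment],
    tip: TipSpec,
    pixel_size: float = 10.0,
    well_diameter: float | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> WoundMask:
    """Rasterize the union of stadia swept by the tip along scratch segments.

    A pixel is wound iff its center lies within ``contact_width / 2`` of
    any segment.  ``center`` (machine mm) translates machine-frame
    segments into the well-local frame; the grid spans the full well disk
    and is *cell-centered*: pixel centers sit at half-integer multiples of
    the pixel size about the well center, so the raster is exactly
    symmetric under 180-degree rotation and the midpoint-rule area
    estimate carries no boundary-tie bias.  Wound pixels outside the well
    disk are clipped.

    ``pixel_size`` (um) must be at most half the contact width or the
    raster undersamples the footprint.
    """
    if not segments:
        raise SimulationError("empty segment list")
    for s in segments:
        if isinstance(s, ToolpathSegment) and s.kind != "scratch":
            raise SimulationError(f"non-scratch segment of kind {s.kind!r} passed to swept_mask")
    if tip.contact_width <= 0:
        raise SimulationError("tip contact width must be > 0")
    px_mm = pixel_size / 1000.0
    radius = tip.contact_width / 2.0
    if px_mm > radius:
        raise SimulationError(
            f"pixel size {pixel_size} um undersamples a {tip.contact_width} mm tip "
            f"(must be <= contact_width / 2)"
        )

    xy = [a - np.asarray(center, dtype=float) for a in _segments_to_xy(segments)]
    if well_diameter is None:
        allpts = np.vstack([a for a in xy])
        well_diameter = 2.0 * (float(np.hypot(*allpts.T).max()) + radius + px_mm)

    half_count = math.ceil(well_diameter / 2.0 / px_mm)
    n = 2 * half_count
    coords = (np.arange(n) - half_count + 0.5) * px_mm  # pixel centers, well-local mm
    grid = np.zeros((n, n), dtype=bool)

    r2 = radius * radius
    for a in xy:
        p0, p1 = a[0], a[1]
        lo = np.minimum(p0, p1) - radius - px_mm
        hi = np.maximum(p0, p1) + radius + px_mm
        ix0, ix1 = np.searchsorted(coords, [lo[0], hi[0]])
        iy0, iy1 = np.searchsorted(coords, [lo[1], hi[1]])
        ix1, iy1 = min(ix1 + 1, n), min(iy1 + 1, n)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        X = coords[ix0:ix1][None, :]
        Y = coords[iy0:iy1][:, None]
        d = p1 - p0
        L2 = float(d @ d)
        px_rel_x = X - p0[0]
        px_rel_y = Y - p0[1]
        if L2 == 0.0:
            dist2 = px_rel_x ** 2 + px_rel_y ** 2
        else:
            t = np.clip((px_rel_x * d[0] + px_rel_y * d[1]) / L2, 0.0, 1.0)
            dist2 = (px_rel_x - t * d[0]) ** 2 + (px_rel_y - t * d[1]) ** 2
        grid[iy0:iy1, ix0:ix1] |= dist2 <= r2

    # wound pixels only inside the well disk
    rr = (coords[None, :] ** 2 + coords[:, None] ** 2) <= (well_diameter / 2.0) ** 2
    grid &= rr

    origin = ((-half_count + 0.5) * px_mm, (-half_count + 0.5) * px_mm)
    return WoundMask(grid=grid, pixel_size=pixel_size, origin=origin,
                     well_diameter=well_diameter)


def swept_mask_from_polylines(
    polylines: Sequence[Polyline],
    tip: TipSpec,
    pixel_size: float = 10.0,
    well_diameter: float | None = None,
) -> WoundMask:
    """Convenience wrapper: sweep well-local polylines directly."""
    segs: list[np.ndarray] = []
    for p in polylines:
        segs.extend(p.segments())
    return swept_mask(segs, tip, pixel_size=pixel_size, well_diameter=well_diameter)


def check_constraints(
    segments: Sequence[ToolpathSegment],
    plate: PlateSpec,
    spec: PatternSpec,
) -> ConstraintReport:
    """Verify a parsed toolpath against the plate geometry and pattern spec.

    Reports the minimum wall clearance over all scratch-height coordinates
    (well radius minus distance from the well center — the endpoints
    suffice, since distance from the center is maximal at segment ends),
    the maximum feed seen, and per-block traversal counts.  Violations:
    clearance below ``tip_offset``, feeds above the configured feeds,
    traversal counts different from ``scratch_cycles``.
    """
    scratch = [s for s in segments if s.kind == "scratch"]
    if not scratch:
        raise SimulationError("no scratch segments to check")
    if any(s.well is None for s in scratch):
        raise SimulationError("scratch segments without well attribution")

    violations: list[str] = []
    min_clear = math.inf
    for s in scratch:
        c = well_center(plate, s.well)
        reach = max(
            float(np.hypot(s.start[0] - c[0], s.start[1] - c[1])),
            float(np.hypot(s.end[0] - c[0], s.end[1] - c[1])),
        )
        clear = plate.well_radius - reach
        if clear < min_clear:
            min_clear = clear
        if clear < spec.tip_offset - 1e-6:
            violations.append(
                f"well {s.well.label}: scratch point {plate.well_radius - clear:.3f} mm from "
                f"center, clearance {clear:.3f} mm < tip offset {spec.tip_offset:.3f} mm"
            )

    max_feed = max((s.feed for s in segments if s.kind in ("travel", "scratch")), default=0.0)
    allowed = max(spec.travel_feed, spec.scratch_feed)
    for s in segments:
        if s.kind in ("travel", "scratch") and s.feed > allowed + 1e-6:
            violations.append(
                f"feed {s.feed:.0f} mm/min exceeds configured {allowed:.0f} mm/min"
            )
            break

    traversals = traversal_counts(segments)
    bad = sorted({(w, c) for w, c in traversals if c != spec.scratch_cycles})
    for w, c in bad:
        violations.append(
            f"well {w}: polyline traversed {c}x, expected scratch_cycles={spec.scratch_cycles}"
        )

    return ConstraintReport(
        min_wall_clearance=min_clear,
        max_feed_seen=max_feed,
        traversals_per_polyline=traversals,
        violations=violations,
    )
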