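"""Well-local scratch pattern generators: mesh, grid, and concentric circles.

All geometry is generated in the well-local frame (origin at the well
center, mm) and must stay inside the *safe disk* of radius
``safe_radius = well_radius - tip_offset``.  The mesh is a set of parallel
chords of the safe circle; the grid is the mesh unioned with its 90-degree
rotation; circle mode emits concentric rings of increasing radius so that
cells across the whole well are stimulated to migrate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import PatternError
from .paths import Polyline

__all__ = ["PatternSpec", "mesh_lines", "grid_lines", "circle_rings", "mesh_offsets"]

_MODES = ("mesh", "grid", "circle", "svg")


@dataclass(frozen=True)
class PatternSpec:
    """Pattern variant plus the motion parameters shared by every mode.

    Defaults mirror the validated single-scratch protocol: a 2 mm tip
    offset, travel and scratch feeds of 6000 mm/min (100 mm/s), and 2
    scratch cycles (the tool runs each path back and forth once).
    """

    mode: str = "mesh"
    tip_offset: float = 2.0  # mm safety margin to the well wall
    line_number: int = 1  # mesh/grid: number of parallel lines
    line_distance: float = 0.0  # mm between adjacent lines
    rotation: int = 0  # mesh only: 0 or 90 degrees
    inner_radius: float = 1.6  # circle: radius of the innermost ring, mm
    radial_step: float = 1.6  # circle: ring-to-ring spacing, mm
    svg_source: str | None = None  # svg: document text or path
    svg_scale: float = 100.0  # svg: percent of the safe radius to fill
    flatten_tol: float = 0.05  # mm max chord deviation when flattening curves
    scratch_cycles: int = 2
    travel_feed: float = 6000.0  # mm/min
    scratch_feed: float = 6000.0  # mm/min

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise PatternError(f"unknown pattern mode {self.mode!r} (one of {_MODES})")
        if self.scratch_cycles < 1:
            raise PatternError("scratch_cycles must be >= 1")
        if self.travel_feed <= 0 or self.scratch_feed <= 0:
            raise PatternError("feeds must be > 0")
        if self.tip_offset < 0:
            raise PatternError("tip_offset must be >= 0")
        if self.flatten_tol <= 0:
            raise PatternError("flatten_tol must be > 0")
        if self.mode in ("mesh", "grid"):
            if self.line_number < 1:
                raise PatternError("line_number must be >= 1")
            if self.line_distance < 0:
                raise PatternError("line_distance must be >= 0")
            if self.line_number > 1 and self.line_distance == 0:
                raise PatternError("line_distance must be > 0 when line_number > 1")
            if self.rotation not in (0, 90):
                raise PatternError("rotation must be 0 or 90 degrees")
        if self.mode == "circle":
            if self.inner_radius <= 0 or self.radial_step <= 0:
                raise PatternError("inner_radius and radial_step must be > 0")
        if self.mode == "svg":
            if not (0 < self.svg_scale <= 100):
                raise PatternError("svg_scale must be in (0, 100] percent")


def mesh_offsets(line_number: int, line_distance: float) -> np.ndarray:
    """Perpendicular offsets of the mesh chords, centered on the well.

    ``o_i = (i - (L - 1) / 2) * d`` for ``i = 0 .. L-1``: symmetric about
    zero, so for even L no line passes through the center.
    """
    i = np.arange(line_number, dtype=float)
    return (i - (line_number - 1) / 2.0) * line_distance


def mesh_lines(spec: PatternSpec, r_safe: float, strict: bool = True) -> list[Polyline]:
    """Parallel full-width chords of the safe circle.

    Each line ``i`` sits at perpendicular offset ``o_i`` and spans the full
    chord, endpoints at ``x = +/- sqrt(r_safe^2 - o_i^2)``.  With
    ``rotation=90`` the axes exchange roles.  Lines are ordered serpentine
    (alternating start ends) to minimise travel moves.

    Offsets that fall on or outside the safe circle fail with the offending
    line indices; with ``strict=False`` they are dropped with a warning
    instead (silent clipping would corrupt replicate comparability, so this
    is opt-in).
    """
    if r_safe <= 0:
        raise PatternError(f"safe radius must be > 0, got {r_safe}")
    offsets = mesh_offsets(spec.line_number, spec.line_distance)
    bad = [i for i, o in enumerate(offsets) if abs(o) >= r_safe]
    if bad:
        if strict:
            raise PatternError(
                f"lines {bad} at offsets {[round(float(offsets[i]), 3) for i in bad]} mm "
                f"fall outside the safe radius {r_safe} mm"
            )
        warnings.warn(f"dropping {len(bad)} mesh line(s) outside the safe radius", stacklevel=2)
        offsets = np.array([o for i, o in enumerate(offsets) if i not in set(bad)])
        if offsets.size == 0:
            raise PatternError("all mesh lines fall outside the safe radius")

    lines: list[Polyline] = []
    for k, o in enumerate(offsets):
        half = math.sqrt(r_safe * r_safe - o * o)
        a, b = (-half, o), (half, o)
        if k % 2 == 1:  # serpentine: odd lines start at the far end
            a, b = b, a
        if spec.rotation == 90:
            a, b = (a[1], a[0]), (b[1], b[0])
        lines.append(Polyline([a, b]))
    return lines


def grid_lines(spec: PatternSpec, r_safe: float, strict: bool = True) -> list[Polyline]:
    """Mesh plus its 90-degree rotation: ``2 * line_number`` chords.

    The crossing chords partition the safe disk into roughly
    ``(line_number + 1)^2`` independent cell islands that migrate
    concentrically, which is the point of the grid mode.
    """
    base = mesh_lines(spec, r_safe, strict=strict)
    rotated = [Polyline(p.points[:, ::-1]) for p in base]
    return base + rotated


def _circle_points(radius: float, flatten_tol: float) -> np.ndarray:
    """Closed regular polygon approximating a circle within ``flatten_tol``.

    The subdivision targets a sagitta of half the tolerance, which keeps
    both the radial deviation and the perimeter deficit of the inscribed
    polygon well inside the tolerance class.
    """
    tol = min(flatten_tol / 2.0, radius)
    n = max(8, math.ceil(math.pi / math.acos(1.0 - tol / radius)))
    theta = np.linspace(0.0, 2.0 * math.pi, n + 1)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    pts[-1] = pts[0]  # bit-exact closure
    return pts


def circle_rings(spec: PatternSpec, r_safe: float) -> list[Polyline]:
    """Concentric closed rings ``r_k = inner_radius + k * radial_step <= r_safe``.

    Innermost ring first.  Each ring is flattened to chords whose sagitta
    (max deviation from the true circle) does not exceed ``flatten_tol``.
    """
    if r_safe <= 0:
        raise PatternError(f"safe radius must be > 0, got {r_safe}")
    if spec.inner_radius > r_safe:
        raise PatternError(
            f"inner_radius {spec.inner_radius} mm exceeds the safe radius {r_safe} mm"
        )
    radii = []
    k = 0
    while True:
        r = spec.inner_radius + k * spec.radial_step
        if r > r_safe + 1e-12:
            break
        radii.append(r)
        k += 1
    return [Polyline(_circle_points(r, spec.flatten_tol)) for r in radii]
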