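"""Polyline container shared by pattern generation, SVG import and G-code."""

from __future__ import annotations

import numpy as np

from .errors import PatternError

__all__ = ["Polyline"]


class Polyline:
    """An ordered sequence of 2D points (mm), the unit of scratch geometry.

    Points are well-local unless stated otherwise.  At least two points;
    consecutive points must be distinct (zero-length segments would emit
    degenerate G-code moves).
    """

    __slots__ = ("points",)

    def __init__(self, points) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise PatternError(f"polyline must be (N, 2), got shape {pts.shape}")
        if pts.shape[0] < 2:
            raise PatternError("polyline needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise PatternError("polyline contains non-finite coordinates")
        seg = np.diff(pts, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise PatternError("polyline has coincident consecutive points")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def __iter__(self):
        return iter(self.points)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Polyline({len(self)} pts, length={self.length():.3f} mm)"

    @property
    def is_closed(self) -> bool:
        return bool(np.allclose(self.points[0], self.points[-1]))

    def length(self) -> float:
        seg = np.diff(self.points, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def reversed(self) -> "Polyline":
        return Polyline(self.points[::-1])

    def translated(self, dx: float, dy: float) -> "Polyline":
        return Polyline(self.points + np.array([dx, dy]))

    def scaled(self, factor: float) -> "Polyline":
        if factor == 0:
            raise PatternError("scale factor must be nonzero")
        return Polyline(self.points * factor)

    def max_radius(self, center=(0.0, 0.0)) -> float:
        """Largest distance of any vertex from ``center``."""
        d = self.points - np.asarray(center, dtype=float)
        return float(np.hypot(d[:, 0], d[:, 1]).max())

    def segments(self) -> np.ndarray:
        """(N-1, 2, 2) array of [start, end] pairs."""
        return np.stack([self.points[:-1], self.points[1:]], axis=1)
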