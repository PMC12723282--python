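"""SVG import: parse a vector drawing, flatten curves, fit it into a well.

Supports the subset of SVG 1.1 that covers drawings exported from Inkscape
for scratching: ``path`` (M/L/H/V/C/Q/Z commands, absolute and relative),
``rect``, ``line``, ``polyline``, ``polygon``, ``circle`` and ``ellipse``,
with ``translate``/``scale`` transforms on groups.  Everything else —
``text``, ``image``, elliptical-arc path commands, other transforms — is
rejected with a clear error rather than silently approximated: the user
can always convert such content to plain paths in Inkscape.

Bezier segments are flattened by recursive de Casteljau subdivision until
the control polygon is within ``flatten_tol`` of the chord, which bounds
the true curve-to-chord deviation (the curve lies in the convex hull of
its control points).

Fitting scales the drawing uniformly so that the circumradius of its
bounding box (half-diagonal about the bbox center) equals
``svg_scale/100 * safe_radius`` and moves the bbox center to the well
center; every point of the drawing is then guaranteed to lie inside the
safe disk.  SVG's y axis points down, so y is flipped by default to keep
drawings upright when the plate is viewed from above.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree

import numpy as np

from .errors import SvgError
from .paths import Polyline

__all__ = ["FlattenedDrawing", "parse_and_flatten", "fit_to_well"]


@dataclass(frozen=True)
class FlattenedDrawing:
    """Polylines in the drawing's own coordinates plus their bounding box."""

    polylines: list[Polyline]
    bbox_min: np.ndarray  # (2,)
    bbox_max: np.ndarray  # (2,)
    source_units: str = "user"

    @property
    def bbox_center(self) -> np.ndarray:
        return (self.bbox_min + self.bbox_max) / 2.0

    @property
    def half_diagonal(self) -> float:
        return float(np.hypot(*((self.bbox_max - self.bbox_min) / 2.0)))


# ---------------------------------------------------------------------------
# path-data parsing

_NUM_RE = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")
_TOKEN_RE = re.compile(r"([A-Za-z])|" + _NUM_RE.pattern)

_SUPPORTED_CMDS = set("MmLlHhVvCcQqZz")


def _tokenize_path(d: str) -> list:
    tokens: list = []
    for m in _TOKEN_RE.finditer(d.replace(",", " ")):
        if m.group(1):
            tokens.append(m.group(1))
        else:
            tokens.append(float(m.group(0)))
    return tokens


def _flatten_bezier(ctrl: np.ndarray, tol: float, out: list, depth: int = 0) -> None:
    """Append interior+end points approximating the Bezier within ``tol``."""
    p0, pn = ctrl[0], ctrl[-1]
    chord = pn - p0
    norm = np.hypot(*chord)
    if norm < 1e-12:
        dev = float(np.hypot(*(ctrl - p0).T).max())
    else:
        # distance of each control point from the infinite chord line
        rel = ctrl[1:-1] - p0
        dev = float(np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]).max() / norm)
    if dev <= tol or depth >= 24:
        out.append(pn)
        return
    # de Casteljau split at t = 1/2
    left, right = [ctrl[0]], [ctrl[-1]]
    work = ctrl.copy()
    while len(work) > 1:
        work = (work[:-1] + work[1:]) / 2.0
        left.append(work[0])
        right.append(work[-1])
    _flatten_bezier(np.array(left), tol, out, depth + 1)
    _flatten_bezier(np.array(right[::-1]), tol, out, depth + 1)


def _parse_path_d(d: str, tol: float) -> list[np.ndarray]:
    tokens = _tokenize_path(d)
    subpaths: list[list[np.ndarray]] = []
    current: list[np.ndarray] = []
    pos = np.zeros(2)
    start = np.zeros(2)
    i = 0
    cmd: str | None = None

    def take(n: int) -> list[float]:
        nonlocal i
        if i + n > len(tokens) or any(isinstance(t, str) for t in tokens[i : i + n]):
            raise SvgError(f"path data: expected {n} numbers for command {cmd!r}")
        vals = tokens[i : i + n]
        i += n
        return vals  # type: ignore[return-value]

    def begin(pt: np.ndarray) -> None:
        nonlocal current, start
        if len(current) >= 2:
            subpaths.append(current)
        current = [pt.copy()]
        start = pt.copy()

    while i < len(tokens):
        t = tokens[i]
        if isinstance(t, str):
            if t in "Aa":
                raise SvgError("unsupported path command 'A' (elliptical arc); "
                               "convert arcs to Bezier paths in Inkscape")
            if t not in _SUPPORTED_CMDS:
                raise SvgError(f"unsupported path command {t!r}")
            cmd = t
            i += 1
            if cmd in "Zz":
                if current and not np.allclose(current[0], pos):
                    current.append(start.copy())
                pos = start.copy()
                if len(current) >= 2:
                    subpaths.append(current)
                current = []
                continue
        if cmd is None:
            raise SvgError("path data must start with a moveto command")

        rel = cmd.islower()
        base = pos if rel else np.zeros(2)
        c = cmd.upper()
        if c == "M":
            x, y = take(2)
            pos = base + np.array([x, y])
            begin(pos)
            cmd = "l" if rel else "L"  # implicit subsequent pairs are linetos
        elif c == "L":
            x, y = take(2)
            pos = base + np.array([x, y])
            current.append(pos.copy())
        elif c == "H":
            (x,) = take(1)
            pos = np.array([(pos[0] + x) if rel else x, pos[1]])
            current.append(pos.copy())
        elif c == "V":
            (y,) = take(1)
            pos = np.array([pos[0], (pos[1] + y) if rel else y])
            current.append(pos.copy())
        elif c in "CQ":
            n = 6 if c == "C" else 4
            vals = take(n)
            ctrl = [pos.copy()]
            for k in range(0, n, 2):
                ctrl.append(base + np.array(vals[k : k + 2]))
            pts: list[np.ndarray] = []
            _flatten_bezier(np.array(ctrl), tol, pts)
            current.extend(pts)
            pos = ctrl[-1]
    if len(current) >= 2:
        subpaths.append(current)
    return [np.array(sp) for sp in subpaths]


# ---------------------------------------------------------------------------
# element handling

_CONTAINERS = {"svg", "g", "a", "switch"}
_IGNORED = {"defs", "title", "desc", "metadata", "style", "namedview", "sodipodi"}

_TRANSFORM_RE = re.compile(r"(\w+)\s*\(([^)]*)\)")


def _parse_transform(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (scale2, translate2) for a translate/scale-only transform list."""
    scale = np.ones(2)
    shift = np.zeros(2)
    for name, args in _TRANSFORM_RE.findall(text):
        vals = [float(v) for v in _NUM_RE.findall(args)]
        if name == "translate":
            tx = vals[0] if vals else 0.0
            ty = vals[1] if len(vals) > 1 else 0.0
            shift = shift + scale * np.array([tx, ty])
        elif name == "scale":
            sx = vals[0] if vals else 1.0
            sy = vals[1] if len(vals) > 1 else sx
            scale = scale * np.array([sx, sy])
        else:
            raise SvgError(f"unsupported transform {name!r} (only translate/scale)")
    return scale, shift


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _shape_subpaths(el, tol: float) -> list[np.ndarray]:
    tag = _localname(el.tag)

    def fattr(name: str, default: float = 0.0) -> float:
        v = el.get(name)
        return float(v) if v is not None else default

    if tag == "path":
        d = el.get("d")
        if not d:
            raise SvgError("path element has no 'd' attribute")
        return _parse_path_d(d, tol)
    if tag == "rect":
        x, y = fattr("x"), fattr("y")
        w, h = fattr("width"), fattr("height")
        if w <= 0 or h <= 0:
            raise SvgError("rect with non-positive width/height")
        return [np.array([(x, y), (x + w, y), (x + w, y + h), (x, y + h), (x, y)])]
    if tag == "line":
        return [np.array([(fattr("x1"), fattr("y1")), (fattr("x2"), fattr("y2"))])]
    if tag in ("polyline", "polygon"):
        nums = [float(v) for v in _NUM_RE.findall(el.get("points", ""))]
        if len(nums) < 4 or len(nums) % 2:
            raise SvgError(f"{tag} needs an even list of >= 4 coordinates")
        pts = np.array(nums).reshape(-1, 2)
        if tag == "polygon":
            pts = np.vstack([pts, pts[:1]])
        return [pts]
    if tag in ("circle", "ellipse"):
        cx, cy = fattr("cx"), fattr("cy")
        if tag == "circle":
            rx = ry = fattr("r")
        else:
            rx, ry = fattr("rx"), fattr("ry")
        if rx <= 0 or ry <= 0:
            raise SvgError(f"{tag} with non-positive radius")
        tol_eff = min(tol, min(rx, ry))
        n = max(8, math.ceil(math.pi / math.acos(1.0 - tol_eff / max(rx, ry))))
        theta = np.linspace(0.0, 2.0 * math.pi, n + 1)
        pts = np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])
        pts[-1] = pts[0]
        return [pts]
    raise SvgError(f"unsupported SVG element <{tag}>")


def _walk(el, scale: np.ndarray, shift: np.ndarray, tol: float, out: list[np.ndarray]) -> None:
    tag = _localname(el.tag)
    if tag in _IGNORED:
        return
    tf = el.get("transform")
    if tf:
        s, t = _parse_transform(tf)
        shift = shift + scale * t
        scale = scale * s
    if tag in _CONTAINERS:
        for child in el:
            _walk(child, scale, shift, tol, out)
        return
    # leaf shape: flatten in local units fine enough to survive the transform
    local_tol = tol / max(abs(scale[0]), abs(scale[1]))
    for sp in _shape_subpaths(el, local_tol):
        out.append(sp * scale + shift)


def parse_and_flatten(svg_source: "str | Path", flatten_tol: float = 0.05) -> FlattenedDrawing:
    """Parse an SVG document (path or text) into flattened polylines.

    Each subpath becomes one polyline; closed subpaths repeat their first
    point at the end.  Bezier segments are subdivided until the chord
    deviation is at most ``flatten_tol`` (drawing units).
    """
    if flatten_tol <= 0:
        raise SvgError("flatten_tol must be > 0")
    text: str
    if isinstance(svg_source, Path):
        text = svg_source.read_text(encoding="utf-8")
    else:
        s = str(svg_source)
        if "<" in s:
            text = s
        else:
            p = Path(s)
            if not p.exists():
                raise SvgError(f"SVG file not found: {s}")
            text = p.read_text(encoding="utf-8")
    try:
        root = ElementTree.fromstring(text)
    except ElementTree.ParseError as exc:
        raise SvgError(f"malformed SVG: {exc}") from exc

    raw: list[np.ndarray] = []
    _walk(root, np.ones(2), np.zeros(2), flatten_tol, raw)
    polylines = []
    for pts in raw:
        # drop consecutive duplicates introduced by flattening/closure
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.hypot(*(np.diff(pts, axis=0)).T) > 1e-12
        pts = pts[keep]
        if len(pts) >= 2:
            polylines.append(Polyline(pts))
    if not polylines:
        raise SvgError("empty drawing: no drawable geometry found")
    allpts = np.vstack([p.points for p in polylines])
    return FlattenedDrawing(
        polylines=polylines,
        bbox_min=allpts.min(axis=0),
        bbox_max=allpts.max(axis=0),
    )


def fit_to_well(
    drawing: FlattenedDrawing,
    svg_scale: float,
    r_safe: float,
    flip_y: bool = True,
) -> list[Polyline]:
    """Scale and center a drawing into the safe disk of a well.

    The uniform scale is chosen so the half-diagonal of the drawing's
    bounding box equals ``svg_scale/100 * r_safe``; the bbox center lands
    on the well center.  Consequently every point lies within
    ``svg_scale/100 * r_safe`` of the center, for any drawing.
    """
    if not (0 < svg_scale <= 100):
        raise SvgError("svg_scale must be in (0, 100] percent")
    if r_safe <= 0:
        raise SvgError("safe radius must be > 0")
    half_diag = drawing.half_diagonal
    if half_diag <= 0:
        raise SvgError("degenerate drawing: bounding box collapses to a point")
    s = (svg_scale / 100.0) * r_safe / half_diag
    center = drawing.bbox_center
    flip = np.array([1.0, -1.0]) if flip_y else np.array([1.0, 1.0])
    return [Polyline((p.points - center) * s * flip) for p in drawing.polylines]
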