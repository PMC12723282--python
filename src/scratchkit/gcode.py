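"""Emit scratch programs as G-code and parse them back for verification.

Dialect: a Marlin-flavoured subset that runs on common FDM printers used
as plotters — ``G21`` (mm), ``G90`` (absolute), ``G28`` (home), a
configurable auto-leveling token (default ``G29``), ``G0`` rapids at the
travel feed, ``G1`` scratch moves at the scratch feed, ``G4`` dwells for
the ethanol wash, and ``;`` comments.  Feed words are repeated on every
motion line and coordinates use fixed 3-decimal mm, so output is
bit-stable and golden-file testable.

The program header echoes every parameter (plate, pattern, z heights,
feeds), making each file self-describing: :func:`parse_program` recovers
the z heights from the header when not given explicitly, reconstructs
positions by carrying modal state, classifies each motion as travel,
scratch, wash or dwell, and counts scratch blocks per well.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import GcodeError
from .paths import Polyline
from .patterns import PatternSpec
from .plate import PlateSpec, WellAddress, well_center

__all__ = [
    "WashStation",
    "MachineProfile",
    "GENERIC_PROFILE",
    "load_machine_profile",
    "GCodeProgram",
    "ToolpathSegment",
    "ParsedProgram",
    "emit_program",
    "parse_program",
    "insert_wash",
    "traversal_counts",
    "count_distinct_lines",
]

_Z_TOL = 1e-6


@dataclass(frozen=True)
class WashStation:
    """Machine-frame position of the ethanol bath plus the immersion dwell."""

    x: float
    y: float
    z: float
    dwell_s: float = 30.0  # disinfection dwell; protocol requires >= 30 s

    def __post_init__(self) -> None:
        if self.dwell_s < 0:
            raise GcodeError("wash dwell must be >= 0 s")


@dataclass(frozen=True)
class MachineProfile:
    """Printer-specific commands and limits."""

    name: str = "generic"
    homing_command: str = "G28"
    leveling_command: str = "G29"
    supports_autolevel: bool = True
    wash_station: WashStation | None = None
    max_feed: float = 12000.0  # mm/min

    def __post_init__(self) -> None:
        if not self.homing_command.strip():
            raise GcodeError("homing_command must be non-empty")
        if self.supports_autolevel and not self.leveling_command.strip():
            raise GcodeError("leveling_command must be non-empty when auto-level is supported")
        if self.max_feed <= 0:
            raise GcodeError("max_feed must be > 0")


GENERIC_PROFILE = MachineProfile()


def load_machine_profile(path: "str | Path") -> MachineProfile:
    """Load a machine profile from a small YAML document."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    station = None
    if "wash_station" in doc and doc["wash_station"] is not None:
        ws = doc["wash_station"]
        station = WashStation(
            x=float(ws["x"]), y=float(ws["y"]), z=float(ws["z"]),
            dwell_s=float(ws.get("dwell_s", 30.0)),
        )
    return MachineProfile(
        name=str(doc.get("name", Path(path).stem)),
        homing_command=str(doc.get("homing_command", "G28")),
        leveling_command=str(doc.get("leveling_command", "G29")),
        supports_autolevel=bool(doc.get("supports_autolevel", True)),
        wash_station=station,
        max_feed=float(doc.get("max_feed", 12000.0)),
    )


@dataclass
class GCodeProgram:
    """An emitted command sequence plus the parameter echo from its header."""

    lines: list[str]
    header: dict[str, str] = field(default_factory=dict)

    @property
    def text(self) -> str:
        return "\n".join(self.lines) + "\n"

    def write(self, path: "str | Path") -> None:
        Path(path).write_text(self.text, encoding="utf-8", newline="\n")

    @classmethod
    def from_text(cls, text: str) -> "GCodeProgram":
        lines = text.splitlines()
        return cls(lines=lines, header=_header_from_lines(lines))


@dataclass(frozen=True)
class ToolpathSegment:
    """One typed machine-frame motion reconstructed by the parser."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    feed: float
    kind: str  # travel | scratch | wash | dwell
    well: WellAddress | None = None
    dwell_s: float = 0.0

    @property
    def xy(self) -> np.ndarray:
        return np.array([[self.start[0], self.start[1]], [self.end[0], self.end[1]]])


@dataclass
class ParsedProgram:
    segments: list[ToolpathSegment]
    census: dict[str, int]  # well label -> number of scratch blocks
    header: dict[str, str]

    @property
    def total_scratch_blocks(self) -> int:
        return sum(self.census.values())

    def scratch_segments(self, well: "WellAddress | str | None" = None) -> list[ToolpathSegment]:
        addr = WellAddress.parse(well) if well is not None else None
        return [
            s for s in self.segments
            if s.kind == "scratch" and (addr is None or s.well == addr)
        ]


def _fmt(v: float) -> str:
    return f"{v:.3f}"


def _quantize_local(pts: np.ndarray) -> np.ndarray:
    """Snap well-local coordinates to the 1 um output grid, toward the center.

    Rounding each axis toward zero never increases a point's distance from
    the well center, so quantization cannot push a path across the safe
    circle.  Values already on the grid are preserved exactly.
    """
    return np.sign(pts) * np.floor(np.round(np.abs(pts) * 1000.0, 6)) / 1000.0


def _move(cmd: str, feed: float, x: float | None = None, y: float | None = None,
          z: float | None = None) -> str:
    words = [cmd]
    if x is not None:
        words.append(f"X{_fmt(x)}")
    if y is not None:
        words.append(f"Y{_fmt(y)}")
    if z is not None:
        words.append(f"Z{_fmt(z)}")
    words.append(f"F{feed:.0f}")
    return " ".join(words)


def _header_lines(plate: PlateSpec, wells: Sequence[WellAddress], spec: PatternSpec,
                  profile: MachineProfile) -> list[str]:
    items = {
        "generator": "scratchkit 0.1.0",
        "plate": plate.name,
        "mode": spec.mode,
        "tip_offset_mm": _fmt(spec.tip_offset),
        "line_number": str(spec.line_number),
        "line_distance_mm": _fmt(spec.line_distance),
        "rotation_deg": str(spec.rotation),
        "inner_radius_mm": _fmt(spec.inner_radius),
        "radial_step_mm": _fmt(spec.radial_step),
        "svg_scale_percent": _fmt(spec.svg_scale),
        "scratch_cycles": str(spec.scratch_cycles),
        "travel_feed_mm_min": f"{spec.travel_feed:.0f}",
        "scratch_feed_mm_min": f"{spec.scratch_feed:.0f}",
        "scratch_z_mm": _fmt(plate.scratch_z),
        "travel_z_mm": _fmt(plate.travel_z),
        "machine": profile.name,
        "wells": " ".join(w.label for w in wells),
    }
    return [f"; {k} = {v}" for k, v in items.items()]


_HEADER_RE = re.compile(r"^;\s*([A-Za-z_][\w]*)\s*=\s*(.*)$")


def _header_from_lines(lines: Iterable[str]) -> dict[str, str]:
    header: dict[str, str] = {}
    for line in lines:
        m = _HEADER_RE.match(line.strip())
        if m:
            header.setdefault(m.group(1), m.group(2).strip())
    return header


def _plate_footprint(plate: PlateSpec) -> tuple[float, float, float, float]:
    centers = np.array([
        well_center(plate, WellAddress(r, c))
        for r in range(plate.rows) for c in range(1, plate.cols + 1)
    ])
    pad = max(plate.pitch_x, plate.pitch_y)
    return (centers[:, 0].min() - pad, centers[:, 0].max() + pad,
            centers[:, 1].min() - pad, centers[:, 1].max() + pad)


def _wash_block(profile: MachineProfile, travel_z: float, travel_feed: float,
                scratch_feed: float) -> list[str]:
    ws = profile.wash_station
    assert ws is not None
    lines = [
        "; wash",
        _move("G0", travel_feed, z=travel_z),
        _move("G0", travel_feed, x=ws.x, y=ws.y),
        _move("G1", scratch_feed, z=ws.z),
    ]
    if ws.dwell_s > 0:
        lines.append(f"G4 S{ws.dwell_s:.0f}")
    else:
        warnings.warn("wash dwell is 0 s: no dwell command emitted", stacklevel=3)
    lines.append(_move("G0", travel_feed, z=travel_z))
    return lines


def emit_program(
    plate: PlateSpec,
    wells: Sequence["WellAddress | str"],
    per_well_paths: Sequence[Polyline],
    spec: PatternSpec,
    profile: MachineProfile = GENERIC_PROFILE,
    autolevel: bool = True,
    wash: str | None = None,
) -> GCodeProgram:
    """Compile well-local polylines into a complete scratch program.

    ``per_well_paths`` (well-local mm) is executed in every selected well.
    Per well: lift to ``travel_z``, rapid to the first point, plunge to
    ``scratch_z``, traverse each polyline ``scratch_cycles`` times
    alternating direction (back and forth — cycle 1 forward, cycle 2
    reverse, ...), lift between polylines.  ``wash`` may be ``"before"``,
    ``"after"`` or ``"both"`` to insert the ethanol-bath routine.  The
    program ends with a lift and a park at the machine origin.
    """
    addrs = [WellAddress.parse(w) for w in wells]
    if not addrs:
        raise GcodeError("no wells selected")
    if not per_well_paths:
        raise GcodeError("no scratch paths given")
    for feed_name in ("travel_feed", "scratch_feed"):
        feed = getattr(spec, feed_name)
        if feed > profile.max_feed:
            raise GcodeError(
                f"{feed_name} {feed:.0f} mm/min exceeds machine max_feed "
                f"{profile.max_feed:.0f} mm/min"
            )
    if wash is not None:
        if wash not in ("before", "after", "both"):
            raise GcodeError(f"wash must be before|after|both, got {wash!r}")
        _check_wash_station(plate, profile)

    r_allowed = plate.well_radius - spec.tip_offset
    for path in per_well_paths:
        if path.max_radius() > r_allowed + 1e-9:
            raise GcodeError(
                f"path exceeds the safe radius {r_allowed:.3f} mm "
                f"(max point radius {path.max_radius():.6f} mm); refusing to emit"
            )

    tz, sz = plate.travel_z, plate.scratch_z
    tf, sf = spec.travel_feed, spec.scratch_feed

    lines: list[str] = _header_lines(plate, addrs, spec, profile)
    lines += ["G21 ; millimeters", "G90 ; absolute positioning", profile.homing_command]
    if autolevel and profile.supports_autolevel:
        lines.append(profile.leveling_command)
    lines.append(_move("G0", tf, z=tz))

    if wash in ("before", "both"):
        lines += _wash_block(profile, tz, tf, sf)

    for addr in addrs:
        cx, cy = well_center(plate, addr)
        lines.append(f"; well {addr.label}")
        for path in per_well_paths:
            pts = _quantize_local(path.points) + np.array([cx, cy])
            lines.append(_move("G0", tf, z=tz))
            lines.append(_move("G0", tf, x=pts[0, 0], y=pts[0, 1]))
            lines.append(_move("G1", sf, z=sz))
            for cycle in range(spec.scratch_cycles):
                seq = pts[1:] if cycle % 2 == 0 else pts[::-1][1:]
                for x, y in seq:
                    lines.append(_move("G1", sf, x=x, y=y))
        lines.append(_move("G0", tf, z=tz))

    if wash in ("after", "both"):
        lines += _wash_block(profile, tz, tf, sf)

    lines += ["; park", _move("G0", tf, z=tz), _move("G0", tf, x=0.0, y=0.0)]
    return GCodeProgram(lines=lines, header=_header_from_lines(lines))


def _check_wash_station(plate: PlateSpec, profile: MachineProfile) -> None:
    if profile.wash_station is None:
        raise GcodeError("wash requested but the machine profile has no wash_station")
    ws = profile.wash_station
    x0, x1, y0, y1 = _plate_footprint(plate)
    if x0 <= ws.x <= x1 and y0 <= ws.y <= y1:
        raise GcodeError(
            f"wash station ({ws.x}, {ws.y}) lies within the plate footprint "
            f"[{x0:.1f}..{x1:.1f}] x [{y0:.1f}..{y1:.1f}] mm — collision risk"
        )


def insert_wash(
    program: GCodeProgram,
    profile: MachineProfile,
    when: str = "both",
    plate: PlateSpec | None = None,
) -> GCodeProgram:
    """Splice the wash routine into an existing program.

    ``before`` inserts ahead of the first well block (or the park block for
    an empty program), ``after`` ahead of the park block, ``both`` does
    both.  The routine travels to the station, plunges, dwells for the
    configured time (default 30 s), and lifts.
    """
    if when not in ("before", "after", "both"):
        raise GcodeError(f"when must be before|after|both, got {when!r}")
    if profile.wash_station is None:
        raise GcodeError("wash requested but the machine profile has no wash_station")
    if plate is not None:
        _check_wash_station(plate, profile)

    header = program.header
    try:
        tz = float(header["travel_z_mm"])
        tf = float(header["travel_feed_mm_min"])
        sf = float(header["scratch_feed_mm_min"])
    except KeyError as exc:
        raise GcodeError(f"program header missing {exc} — cannot place wash routine") from exc

    lines = list(program.lines)
    first_well = next((i for i, ln in enumerate(lines) if ln.startswith("; well ")), None)
    park = next((i for i, ln in enumerate(lines) if ln.strip() == "; park"), len(lines))
    block = _wash_block(profile, tz, tf, sf)
    if when in ("after", "both"):
        lines[park:park] = block
    if when in ("before", "both"):
        at = first_well if first_well is not None else park
        lines[at:at] = block
    return GCodeProgram(lines=lines, header=_header_from_lines(lines))


# ---------------------------------------------------------------------------
# parsing

_WORD_RE = re.compile(r"([A-Za-z])([-+]?[0-9]*\.?[0-9]+)")
_KNOWN_PLAIN = {"G21", "G90", "G28", "G29", "M420", "M84"}


def parse_program(
    program: "GCodeProgram | str",
    scratch_z: float | None = None,
    travel_z: float | None = None,
    strict: bool = True,
) -> ParsedProgram:
    """Reconstruct typed toolpath segments from an emitted program.

    Modal state (current position, last feed) is carried across lines.
    Motions at the scratch height under a well label are classified as
    ``scratch``; motions inside a wash block as ``wash``; ``G4`` becomes a
    ``dwell``; everything else is ``travel``.  A scratch *block* is a
    maximal run of consecutive scratch segments in one well; the census
    maps well labels to block counts.
    """
    text = program.text if isinstance(program, GCodeProgram) else str(program)
    lines = text.splitlines()
    header = _header_from_lines(lines)
    if scratch_z is None:
        if "scratch_z_mm" not in header:
            raise GcodeError("scratch_z not given and not found in the program header")
        scratch_z = float(header["scratch_z_mm"])
    if travel_z is None:
        travel_z = float(header["travel_z_mm"]) if "travel_z_mm" in header else scratch_z + 5.0

    pos = np.zeros(3)
    feed = 0.0
    context: str | None = None  # "well <label>" | "wash" | None
    current_well: WellAddress | None = None
    segments: list[ToolpathSegment] = []
    census: dict[str, int] = {}
    prev_was_scratch = False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(";"):
            body = line[1:].strip()
            if body.startswith("well "):
                context = "well"
                try:
                    current_well = WellAddress.parse(body[5:].strip())
                except Exception as exc:
                    raise GcodeError(f"line {lineno}: bad well label {body!r}") from exc
            elif body == "wash":
                context, current_well = "wash", None
            elif body == "park":
                context, current_well = None, None
            continue
        code = line.split(";", 1)[0].strip()
        if not code:
            continue
        words = _WORD_RE.findall(code)
        if not words:
            raise GcodeError(f"line {lineno}: unparseable command {code!r}")
        head = f"{words[0][0].upper()}{int(float(words[0][1]))}"

        if head == "G91":
            raise GcodeError(f"line {lineno}: relative positioning (G91) is unsupported")
        if head in ("G0", "G1"):
            new = pos.copy()
            for letter, value in words[1:]:
                letter = letter.upper()
                if letter == "X":
                    new[0] = float(value)
                elif letter == "Y":
                    new[1] = float(value)
                elif letter == "Z":
                    new[2] = float(value)
                elif letter == "F":
                    feed = float(value)
                elif strict:
                    raise GcodeError(f"line {lineno}: unknown word {letter!r} in {code!r}")
            if np.allclose(new, pos):
                continue
            xy_moved = not np.allclose(new[:2], pos[:2])
            at_scratch_z = (abs(pos[2] - scratch_z) <= _Z_TOL
                            and abs(new[2] - scratch_z) <= _Z_TOL)
            if context == "wash":
                kind = "wash"
            elif xy_moved and at_scratch_z:
                kind = "scratch"
            else:
                kind = "travel"
            well = current_well if context == "well" else None
            seg = ToolpathSegment(tuple(pos), tuple(new), feed, kind, well)
            segments.append(seg)
            if kind == "scratch":
                if not prev_was_scratch:
                    label = well.label if well is not None else "?"
                    census[label] = census.get(label, 0) + 1
                prev_was_scratch = True
            else:
                prev_was_scratch = False
            pos = new
        elif head == "G4":
            dwell = 0.0
            for letter, value in words[1:]:
                if letter.upper() == "S":
                    dwell = float(value)
                elif letter.upper() == "P":
                    dwell = float(value) / 1000.0
            segments.append(ToolpathSegment(tuple(pos), tuple(pos), 0.0,
                                            "dwell", None, dwell_s=dwell))
            prev_was_scratch = False
        elif head == "G28":
            pos = np.zeros(3)
            prev_was_scratch = False
        elif head in _KNOWN_PLAIN:
            prev_was_scratch = False
        elif strict:
            raise GcodeError(f"line {lineno}: unknown command {code!r}")

    return ParsedProgram(segments=segments, census=census, header=header)


def traversal_counts(segments: Sequence[ToolpathSegment]) -> list[tuple[str, int]]:
    """Traversals per scratch block: how many times each polyline was run.

    Within one block (one plunge) a polyline traversed ``c`` cycles
    produces each of its undirected segments ``c`` times, so the count is
    the run length divided by the number of distinct undirected segments.
    """
    out: list[tuple[str, int]] = []
    run: list[ToolpathSegment] = []

    def flush() -> None:
        if not run:
            return
        keys = set()
        for s in run:
            a = (round(s.start[0], 6), round(s.start[1], 6))
            b = (round(s.end[0], 6), round(s.end[1], 6))
            keys.add((a, b) if a <= b else (b, a))
        label = run[0].well.label if run[0].well is not None else "?"
        out.append((label, len(run) // len(keys)))
        run.clear()

    for s in segments:
        if s.kind == "scratch":
            if run and run[0].well != s.well:
                flush()
            run.append(s)
        else:
            flush()
    flush()
    return out


def count_distinct_lines(
    segments: Sequence[ToolpathSegment],
    well: "WellAddress | str | None" = None,
    tol: float = 1e-6,
) -> int:
    """Count distinct infinite lines carrying scratch segments.

    Collinear duplicate traversals (back-and-forth cycles, repeated plunges
    on the same chord) merge into a single line, so a mesh of L parallel
    scratches reports exactly L.
    """
    addr = WellAddress.parse(well) if well is not None else None
    keys = set()
    for s in segments:
        if s.kind != "scratch":
            continue
        if addr is not None and s.well != addr:
            continue
        dx = s.end[0] - s.start[0]
        dy = s.end[1] - s.start[1]
        norm = float(np.hypot(dx, dy))
        if norm == 0:
            continue
        dx, dy = dx / norm, dy / norm
        if dx < -tol or (abs(dx) <= tol and dy < 0):
            dx, dy = -dx, -dy
        # signed distance of the line from the origin along the unit normal
        c = -dy * s.start[0] + dx * s.start[1]
        digits = max(0, int(-np.log10(tol)))
        keys.add((round(dx, digits), round(dy, digits), round(c, digits)))
    return len(keys)
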