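"""Multiwell-plate geometry in machine coordinates.

A plate is described by a :class:`PlateSpec`: grid layout, well diameter,
well-to-well pitch, the machine-frame position of the center of well A1,
and the two z heights the tool uses (``scratch_z`` inside the well,
``travel_z`` above the plate walls).  All pattern mathematics elsewhere in
the package is done in a *well-local* frame (origin at the well center,
axes parallel to the machine axes, mm); placement into the machine frame
is a translation by :func:`well_center`.

Plate geometry is loaded from small plain-text ``key = value`` preset
files; presets for the common 6-, 12-, 24- and 96-well formats are bundled
with the package (SLAS footprint, standard pitches).  The A1 machine
offsets in the bundled files are placeholders for a centered plate mount
and are expected to be replaced by the user's bench calibration.
"""

from __future__ import annotations

import re
import string
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import PlateError

__all__ = [
    "PlateSpec",
    "CalibrationOffsets",
    "WellAddress",
    "TipSpec",
    "TIP_PRESETS",
    "load_plate_spec",
    "load_preset",
    "list_presets",
    "well_center",
    "all_wells",
    "select_wells",
    "safe_radius",
]


@dataclass(frozen=True)
class PlateSpec:
    """Geometric contract for one multiwell plate in the machine frame."""

    name: str
    rows: int
    cols: int
    well_diameter: float  # mm
    pitch_x: float  # mm, center-to-center along columns
    pitch_y: float  # mm, center-to-center along rows
    a1_center_x: float  # machine mm
    a1_center_y: float  # machine mm
    scratch_z: float  # machine mm, tip working height inside the well
    travel_z: float  # machine mm, safe height above the plate walls
    swap_xy: bool = False

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise PlateError(f"plate {self.name!r}: rows/cols must be >= 1")
        if self.well_diameter <= 0:
            raise PlateError(f"plate {self.name!r}: well_diameter must be > 0")
        if self.pitch_x < self.well_diameter or self.pitch_y < self.well_diameter:
            raise PlateError(
                f"plate {self.name!r}: pitch ({self.pitch_x}, {self.pitch_y}) mm "
                f"smaller than well diameter {self.well_diameter} mm — wells would overlap"
            )
        if not self.travel_z > self.scratch_z:
            raise PlateError(
                f"plate {self.name!r}: travel_z ({self.travel_z}) must be above "
                f"scratch_z ({self.scratch_z})"
            )
        for key in ("a1_center_x", "a1_center_y", "scratch_z", "travel_z"):
            if not np.isfinite(getattr(self, key)):
                raise PlateError(f"plate {self.name!r}: {key} is not finite")

    @property
    def well_radius(self) -> float:
        return self.well_diameter / 2.0

    @property
    def n_wells(self) -> int:
        return self.rows * self.cols

    def shifted(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "PlateSpec":
        """Return a copy with calibration offsets applied to A1 and z."""
        return replace(
            self,
            a1_center_x=self.a1_center_x + dx,
            a1_center_y=self.a1_center_y + dy,
            scratch_z=self.scratch_z + dz,
            travel_z=self.travel_z + dz,
        )

    def calibrated(self, offsets: "CalibrationOffsets") -> "PlateSpec":
        return self.shifted(offsets.x_offset, offsets.y_offset, offsets.z_offset)


@dataclass(frozen=True)
class CalibrationOffsets:
    """Bench-determined x/y/z offsets aligning the plate mount to the machine."""

    x_offset: float = 0.0
    y_offset: float = 0.0
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x_offset, self.y_offset, self.z_offset])):
            raise PlateError("calibration offsets must be finite")


_ADDR_RE = re.compile(r"^([A-Za-z])\s*([0-9]+)$")


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well label such as ``A1``: row letter (A = first row), 1-based column."""

    row: int  # 0-based row index (A = 0)
    col: int  # 1-based column number

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 1:
            raise PlateError(f"invalid well address indices row={self.row} col={self.col}")

    @classmethod
    def parse(cls, label: "str | WellAddress") -> "WellAddress":
        if isinstance(label, WellAddress):
            return label
        m = _ADDR_RE.match(label.strip())
        if not m:
            raise PlateError(f"cannot parse well address {label!r} (expected e.g. 'B3')")
        return cls(row=string.ascii_uppercase.index(m.group(1).upper()), col=int(m.group(2)))

    @property
    def label(self) -> str:
        return f"{string.ascii_uppercase[self.row]}{self.col}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class TipSpec:
    """A pipette tip modelled as an effective contact width at the monolayer."""

    volume_label: str
    contact_width: float  # mm

    def __post_init__(self) -> None:
        if self.contact_width <= 0:
            raise PlateError(f"tip {self.volume_label!r}: contact_width must be > 0")


#: Nominal contact widths of the three common tip sizes (mm).
TIP_PRESETS: dict[str, TipSpec] = {
    "1000": TipSpec("1000", 1.2),
    "200": TipSpec("200", 0.8),
    "10": TipSpec("10", 0.7),
}


_REQUIRED_KEYS = {
    "name": str,
    "rows": int,
    "cols": int,
    "well_diameter_mm": float,
    "pitch_x_mm": float,
    "pitch_y_mm": float,
    "a1_center_x_mm": float,
    "a1_center_y_mm": float,
    "scratch_z_mm": float,
}
_OPTIONAL_KEYS = {"travel_z_mm": float, "swap_xy": bool}


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "true", "yes", "on"):
        return True
    if v in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def load_plate_spec(source: "str | Path") -> PlateSpec:
    """Parse a plain-text plate preset (``key = value``, ``#`` comments).

    ``source`` may be a filesystem path or the document text itself.
    Missing required keys fail with the key name; unknown keys warn and are
    ignored; ``travel_z_mm`` defaults to ``scratch_z_mm + 5`` (clears plate
    walls) when omitted.
    """
    text: str
    if isinstance(source, Path) or ("=" not in str(source) and "\n" not in str(source)):
        path = Path(source)
        if not path.exists():
            raise PlateError(f"plate spec not found: {path}")
        text = path.read_text(encoding="utf-8")
    else:
        text = str(source)

    raw: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise PlateError(f"plate spec line {lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        raw[key] = value

    values: dict[str, object] = {}
    for key, typ in _REQUIRED_KEYS.items():
        if key not in raw:
            raise PlateError(f"plate spec missing required key {key!r}")
        try:
            values[key] = typ(raw.pop(key))
        except ValueError as exc:
            raise PlateError(f"plate spec key {key!r}: non-numeric value") from exc
    for key, typ in _OPTIONAL_KEYS.items():
        if key in raw:
            try:
                values[key] = _parse_bool(raw.pop(key)) if typ is bool else typ(raw.pop(key))
            except ValueError as exc:
                raise PlateError(f"plate spec key {key!r}: unparseable value") from exc
    if raw:
        warnings.warn(f"plate spec: ignoring unknown keys {sorted(raw)}", stacklevel=2)

    scratch_z = float(values["scratch_z_mm"])  # type: ignore[arg-type]
    travel_z = float(values.get("travel_z_mm", scratch_z + 5.0))  # type: ignore[arg-type]
    return PlateSpec(
        name=str(values["name"]),
        rows=int(values["rows"]),  # type: ignore[arg-type]
        cols=int(values["cols"]),  # type: ignore[arg-type]
        well_diameter=float(values["well_diameter_mm"]),  # type: ignore[arg-type]
        pitch_x=float(values["pitch_x_mm"]),  # type: ignore[arg-type]
        pitch_y=float(values["pitch_y_mm"]),  # type: ignore[arg-type]
        a1_center_x=float(values["a1_center_x_mm"]),  # type: ignore[arg-type]
        a1_center_y=float(values["a1_center_y_mm"]),  # type: ignore[arg-type]
        scratch_z=scratch_z,
        travel_z=travel_z,
        swap_xy=bool(values.get("swap_xy", False)),
    )


def _preset_dir():
    return resources.files("scratchkit") / "data" / "presets"


def list_presets() -> list[str]:
    """Names of the bundled plate presets (``6well``, ``12well``, ...)."""
    return sorted(p.name[: -len(".txt")] for p in _preset_dir().iterdir() if p.name.endswith(".txt"))


def load_preset(name: str) -> PlateSpec:
    """Load a bundled preset by name, or any preset file by path."""
    candidate = _preset_dir() / f"{name}.txt"
    if candidate.is_file():
        return load_plate_spec(candidate.read_text(encoding="utf-8"))
    if Path(name).exists():
        return load_plate_spec(Path(name))
    raise PlateError(f"plate spec not found: {name!r} (bundled: {', '.join(list_presets())})")


def _check_address(plate: PlateSpec, addr: WellAddress) -> None:
    if addr.row >= plate.rows or addr.col > plate.cols:
        raise PlateError(
            f"well {addr.label} out of range for plate {plate.name!r} "
            f"({plate.rows} rows x {plate.cols} cols)"
        )


def well_center(plate: PlateSpec, addr: "WellAddress | str") -> np.ndarray:
    """Machine-frame (x, y) of a well center.

    Row A is the row nearest the machine origin along +y.  With ``swap_xy``
    the pitch axes exchange roles: columns advance along y and rows along x,
    accommodating plates mounted rotated by 90 degrees.
    """
    addr = WellAddress.parse(addr)
    _check_address(plate, addr)
    if plate.swap_xy:
        return np.array(
            [plate.a1_center_x + addr.row * plate.pitch_x,
             plate.a1_center_y + (addr.col - 1) * plate.pitch_y]
        )
    return np.array(
        [plate.a1_center_x + (addr.col - 1) * plate.pitch_x,
         plate.a1_center_y + addr.row * plate.pitch_y]
    )


def all_wells(plate: PlateSpec) -> list[WellAddress]:
    """All wells in row-major order (A1 ... A{cols}, B1 ...)."""
    return [WellAddress(r, c) for r in range(plate.rows) for c in range(1, plate.cols + 1)]


def select_wells(
    plate: PlateSpec,
    include: "Sequence[WellAddress | str] | None" = None,
    exclude: "Sequence[WellAddress | str] | None" = None,
) -> list[WellAddress]:
    """Deterministic row-major well selection.

    Exactly one of ``include`` (keep these wells, in row-major order) or
    ``exclude`` (drop these from the full plate) may be given; both ``None``
    selects every well.  Duplicate or out-of-range addresses fail.
    """
    if include is not None and exclude is not None:
        raise PlateError("give either include or exclude, not both")

    def _parse_unique(items: Iterable["WellAddress | str"]) -> list[WellAddress]:
        parsed = [WellAddress.parse(a) for a in items]
        for a in parsed:
            _check_address(plate, a)
        if len(set(parsed)) != len(parsed):
            dupes = sorted({a.label for a in parsed if parsed.count(a) > 1})
            raise PlateError(f"duplicate well addresses: {dupes}")
        return parsed

    if include is not None:
        chosen = set(_parse_unique(include))
        return [w for w in all_wells(plate) if w in chosen]
    dropped = set(_parse_unique(exclude)) if exclude else set()
    return [w for w in all_wells(plate) if w not in dropped]


def safe_radius(plate: PlateSpec, tip_offset: float) -> float:
    """Radius of the scratchable disk: well radius minus the tip offset.

    The tip offset is the safety margin between the toolpath and the well
    wall (the validated protocol uses 2 mm).
    """
    if tip_offset < 0:
        raise PlateError(f"tip_offset must be >= 0, got {tip_offset}")
    r = plate.well_radius - tip_offset
    if r <= 0:
        raise PlateError(
            f"no scratchable area: tip_offset {tip_offset} mm >= well radius "
            f"{plate.well_radius} mm"
        )
    return r
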