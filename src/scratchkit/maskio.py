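"""Mask persistence: binary PNG plus a JSON sidecar with the geometry.

PNG stores only pixels; the pixel size (um), the well-local origin of
pixel (0, 0) and the well diameter travel in a ``<name>.json`` sidecar
next to the image so a mask file round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import SimulationError
from .simulate import WoundMask

__all__ = ["save_mask", "load_mask", "sidecar_path"]


def sidecar_path(png_path: "str | Path") -> Path:
    return Path(png_path).with_suffix(".json")


def save_mask(mask: WoundMask, png_path: "str | Path") -> None:
    """Write a mask as an 8-bit PNG (wound = 255) plus its JSON sidecar."""
    png_path = Path(png_path)
    img = Image.fromarray((mask.grid.astype(np.uint8)) * 255, mode="L")
    img.save(png_path, format="PNG")
    meta = {
        "pixel_size_um": mask.pixel_size,
        "origin_mm": [mask.origin[0], mask.origin[1]],
        "well_diameter_mm": mask.well_diameter,
    }
    sidecar_path(png_path).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def load_mask(png_path: "str | Path") -> WoundMask:
    """Read a PNG + sidecar pair back into a :class:`WoundMask`."""
    png_path = Path(png_path)
    side = sidecar_path(png_path)
    if not png_path.exists():
        raise SimulationError(f"mask image not found: {png_path}")
    if not side.exists():
        raise SimulationError(f"mask sidecar not found: {side}")
    grid = np.asarray(Image.open(png_path).convert("L")) > 127
    meta = json.loads(side.read_text(encoding="utf-8"))
    return WoundMask(
        grid=grid,
        pixel_size=float(meta["pixel_size_um"]),
        origin=(float(meta["origin_mm"][0]), float(meta["origin_mm"][1])),
        well_diameter=float(meta["well_diameter_mm"]),
    )
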