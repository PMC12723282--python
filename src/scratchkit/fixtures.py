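"""Synthetic test inputs: fixture SVGs and jittered wound masks.

The mask generator emulates the two reproducibility regimes seen in
scratch-assay practice without any imaging: a *robotic* regime (straight
edges, between-replicate width jitter around 1.6%) and a *manual* regime
(wavy edges, width jitter around 16%), so that the quantification
pipeline can be exercised and the two regimes separated statistically.

The noise model is the simplest smooth one that reproduces both regimes:
each wound edge is displaced by a stationary Gaussian process (white
noise convolved with a Gaussian kernel of the configured correlation
length, rescaled to the target SD), and the realized mean width of each
replicate is drawn around the base width with a configurable relative SD.
Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import SimulationError
from .simulate import WoundMask

__all__ = [
    "JitterModel",
    "ROBOTIC_JITTER",
    "MANUAL_JITTER",
    "make_fixture_svgs",
    "fixture_svg",
    "make_scratch_mask",
    "edge_profiles",
]


@dataclass(frozen=True)
class JitterModel:
    """Statistical model of scratch-to-scratch and within-scratch variation."""

    base_width: float = 900.0  # um, nominal gap width
    edge_sd: float = 0.0  # um, within-scratch edge waviness
    width_sd_percent: float = 0.0  # %, between-replicate width jitter
    correlation_length: float = 500.0  # um, smoothness of the edge noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_width <= 0:
            raise SimulationError("base_width must be > 0")
        if self.edge_sd < 0 or self.width_sd_percent < 0:
            raise SimulationError("noise SDs must be >= 0")
        if self.correlation_length <= 0:
            raise SimulationError("correlation_length must be > 0")

    def with_seed(self, seed: int) -> "JitterModel":
        return replace(self, seed=seed)


#: Robotic regime: straight edges, ~1.6% width CV between replicates.
ROBOTIC_JITTER = JitterModel(base_width=900.0, edge_sd=15.0, width_sd_percent=1.6)
#: Manual regime: wavy edges, ~16% width CV between replicates.
MANUAL_JITTER = JitterModel(base_width=900.0, edge_sd=80.0, width_sd_percent=16.0)


# ---------------------------------------------------------------------------
# fixture SVGs

_SVG_TEMPLATE = (
    '<svg xmlns="http://www.w3.org/2000/svg" width="100" height="100" '
    'viewBox="0 0 100 100">\n{body}\n</svg>\n'
)


def _square_svg() -> str:
    return _SVG_TEMPLATE.format(body='  <rect x="20" y="20" width="60" height="60"/>')


def _star_svg(points: int = 5, r_outer: float = 40.0, r_inner: float = 16.0) -> str:
    coords = []
    for k in range(2 * points):
        r = r_outer if k % 2 == 0 else r_inner
        a = math.pi / 2 + k * math.pi / points
        coords.append(f"{50 + r * math.cos(a):.4f},{50 - r * math.sin(a):.4f}")
    return _SVG_TEMPLATE.format(body=f'  <polygon points="{" ".join(coords)}"/>')


def _maze_svg() -> str:
    # rectangular spiral: a complex orthogonal toolpath in one open subpath
    d = ("M 5 5 H 95 V 95 H 5 V 15 H 85 V 85 H 15 V 25 H 75 V 75 H 25 "
         "V 35 H 65 V 65 H 35 V 45 H 55 V 55 H 45")
    return _SVG_TEMPLATE.format(body=f'  <path d="{d}"/>')


def _bezier_svg() -> str:
    return _SVG_TEMPLATE.format(body='  <path d="M 10 50 C 30 5 70 95 90 50"/>')


_FIXTURES = {
    "square": _square_svg,
    "star": _star_svg,
    "maze": _maze_svg,
    "bezier": _bezier_svg,
}


def fixture_svg(name: str) -> str:
    """Return the text of one fixture drawing (square, star, maze, bezier)."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise SimulationError(f"unknown fixture {name!r} (one of {sorted(_FIXTURES)})") from None


def make_fixture_svgs(outdir: "str | Path") -> list[Path]:
    """Write the deterministic fixture drawings to ``outdir``; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(_FIXTURES):
        p = outdir / f"{name}.svg"
        p.write_text(fixture_svg(name), encoding="utf-8", newline="\n")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# jittered wound masks

def _smooth_noise(n: int, sigma_px: float, target_sd: float, rng) -> np.ndarray:
    """Stationary Gaussian process on a 1D grid with empirical SD ``target_sd``."""
    if target_sd == 0.0:
        return np.zeros(n)
    raw = rng.standard_normal(n)
    sm = gaussian_filter1d(raw, sigma=sigma_px, mode="wrap")
    sm -= sm.mean()  # edge noise must not shift the replicate's mean width
    sd = sm.std()
    if sd == 0.0:
        return np.zeros(n)
    return sm * (target_sd / sd)


def edge_profiles(
    model: JitterModel,
    length: float,
    pixel_size: float,
    rng: "np.random.Generator | None" = None,
):
    """Generate the two edge displacement profiles of one scratch.

    Returns ``(x_mm, upper_mm, lower_mm)``: axial station coordinates and
    the y position of the two wound edges.  Exposed separately so tests
    can predict width statistics directly from the generating process.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    ncols = max(2, int(round(length * 1000.0 / pixel_size)))
    x = (np.arange(ncols) - (ncols - 1) / 2.0) * pixel_size / 1000.0
    width_um = model.base_width * (1.0 + rng.normal(0.0, model.width_sd_percent / 100.0))
    width_um = max(width_um, 4.0 * pixel_size)  # keep the gap resolvable
    sigma_px = model.correlation_length / pixel_size
    e_upper = _smooth_noise(ncols, sigma_px, model.edge_sd, rng)
    e_lower = _smooth_noise(ncols, sigma_px, model.edge_sd, rng)
    upper = (width_um / 2.0 + e_upper) / 1000.0
    lower = (-width_um / 2.0 + e_lower) / 1000.0
    return x, upper, lower


def make_scratch_mask(
    model: JitterModel,
    length: float = 8.0,
    pixel_size: float = 10.0,
    frame: float | None = None,
) -> WoundMask:
    """Rasterize one straight synthetic scratch with the model's jitter.

    ``length`` is the scratch extent in mm; the square frame (default
    ``length + 2`` mm) plays the role of the imaged field of view.  A
    pixel is wound iff its center lies strictly between the two generated
    edges.  Identical model + seed gives a bit-identical mask.
    """
    if model.base_width <= 4.0 * pixel_size:
        raise SimulationError(
            f"base_width {model.base_width} um must exceed 4 pixels "
            f"({4 * pixel_size} um) for a resolvable gap"
        )
    if length <= 0:
        raise SimulationError("length must be > 0")
    frame = frame if frame is not None else length + 2.0

    px_mm = pixel_size / 1000.0
    half_count = math.ceil(frame / 2.0 / px_mm)
    n = 2 * half_count
    coords = (np.arange(n) - half_count + 0.5) * px_mm  # cell-centered
    grid = np.zeros((n, n), dtype=bool)

    x, upper, lower = edge_profiles(model, length, pixel_size)
    # map the scratch columns onto the frame's central columns
    col0 = half_count - len(x) // 2
    for j in range(len(x)):
        c = col0 + j
        if c < 0 or c >= n:
            continue
        grid[:, c] = (coords > lower[j]) & (coords < upper[j])

    origin = ((-half_count + 0.5) * px_mm, (-half_count + 0.5) * px_mm)
    return WoundMask(grid=grid, pixel_size=pixel_size, origin=origin, well_diameter=frame)
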