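"""scratchkit: scratch-assay automation on 3D-printer plotters.

Compile scratch patterns (parallel-line mesh, crossed grid, concentric
circles, arbitrary SVG drawings) into G-code for multiwell culture
plates, verify the emitted toolpaths, simulate the swept wound footprint,
and quantify wound geometry and replicate reproducibility.
"""

from .errors import (
    GcodeError,
    PatternError,
    PlateError,
    QuantError,
    ScratchKitError,
    SimulationError,
    SvgError,
)
from .fixtures import (
    MANUAL_JITTER,
    ROBOTIC_JITTER,
    JitterModel,
    edge_profiles,
    fixture_svg,
    make_fixture_svgs,
    make_scratch_mask,
)
from .gcode import (
    GENERIC_PROFILE,
    GCodeProgram,
    MachineProfile,
    ParsedProgram,
    ToolpathSegment,
    WashStation,
    count_distinct_lines,
    emit_program,
    insert_wash,
    load_machine_profile,
    parse_program,
    traversal_counts,
)
from .maskio import load_mask, save_mask
from .paths import Polyline
from .patterns import PatternSpec, circle_rings, grid_lines, mesh_lines, mesh_offsets
from .plate import (
    TIP_PRESETS,
    CalibrationOffsets,
    PlateSpec,
    TipSpec,
    WellAddress,
    all_wells,
    list_presets,
    load_plate_spec,
    load_preset,
    safe_radius,
    select_wells,
    well_center,
)
from .quantify import (
    ReplicateStats,
    WoundMetrics,
    cv,
    ratio,
    relative_difference,
    wound_metrics,
)
from .simulate import (
    ConstraintReport,
    WoundMask,
    check_constraints,
    swept_mask,
    swept_mask_from_polylines,
)
from .svg import FlattenedDrawing, fit_to_well, parse_and_flatten

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def generate_paths(spec: PatternSpec, r_safe: float, strict: bool = True) -> list[Polyline]:
    """Dispatch a :class:`PatternSpec` to its generator, well-local mm."""
    if spec.mode == "mesh":
        return mesh_lines(spec, r_safe, strict=strict)
    if spec.mode == "grid":
        return grid_lines(spec, r_safe, strict=strict)
    if spec.mode == "circle":
        return circle_rings(spec, r_safe)
    if spec.mode == "svg":
        if spec.svg_source is None:
            raise SvgError("svg mode requires svg_source")
        drawing = parse_and_flatten(spec.svg_source, flatten_tol=spec.flatten_tol)
        return fit_to_well(drawing, spec.svg_scale, r_safe)
    raise PatternError(f"unknown mode {spec.mode!r}")  # pragma: no cover
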