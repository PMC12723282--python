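"""Exception hierarchy for scratchkit.

Every module raises a subclass of :class:`ScratchKitError`, so callers
(including the CLI) can distinguish toolkit failures from programming
errors with a single ``except``.
"""


class ScratchKitError(Exception):
    """Base class for all scratchkit failures."""


class PlateError(ScratchKitError):
    """Invalid plate specification, preset file, or well address."""


class PatternError(ScratchKitError):
    """Pattern parameters produce geometry outside the safe region."""


class SvgError(ScratchKitError):
    """Unparseable or unsupported SVG input."""


class GcodeError(ScratchKitError):
    """G-code emission or parsing failure."""


class SimulationError(ScratchKitError):
    """Toolpath simulation failure (bad segments, undersampled raster)."""


class QuantError(ScratchKitError):
    """Wound quantification failure (empty mask, degenerate statistics)."""
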