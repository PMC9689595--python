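"""Exception hierarchy shared across the pipeline stages."""


class ACCellScanError(Exception):
    """Base class for all pipeline errors."""


class InputError(ACCellScanError):
    """A referenced input file does not exist or cannot be read."""


class FormatError(ACCellScanError):
    """An input file exists but is not a supported image format."""


class ValidationError(ACCellScanError):
    """A manifest row or configuration value violates its contract."""


class SegmentationError(ACCellScanError):
    """No anterior-chamber candidate region could be found in a scan."""


class GateError(ACCellScanError):
    """The fibrin-gate probe regions do not intersect the chamber mask."""


class GenerationError(ACCellScanError):
    """A synthetic scan recipe is infeasible (e.g. too many spots)."""


class FitError(ACCellScanError):
    """Too few usable points, or a degenerate design, for calibration."""
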