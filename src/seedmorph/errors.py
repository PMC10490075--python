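"""Exception hierarchy for the seedmorph package."""


class SeedMorphError(Exception):
    """Base class for all seedmorph-specific errors."""


class ImageFormatError(SeedMorphError):
    """Raised when a file cannot be decoded as a supported raster."""


class ContractViolationError(SeedMorphError, ValueError):
    """An operation was called with input violating its contract."""


class NoSeedFoundError(SeedMorphError):
    """No contour above the configured noise floor was found."""


class InvalidCalibrationError(SeedMorphError, ValueError):
    """Degenerate calibration input (coincident points or non-positive distance)."""


class DegenerateFitError(SeedMorphError, ValueError):
    """Linear fit requested against a constant reference vector."""


class SceneConstructionError(SeedMorphError, ValueError):
    """A synthetic shape does not fit inside the requested frame."""


class ShortContourListWarning(UserWarning):
    """Fewer contours were available than requested."""
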