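"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: DataError -> 2, ConfigError -> 3.
"""


class BusFusionError(Exception):
    """Base class for all package errors."""


class DataError(BusFusionError):
    """Invalid or degenerate input data (empty mask, single-class labels, ...)."""


class FormatError(DataError):
    """Malformed files or mismatched image/mask geometry."""


class SizingError(DataError):
    """Geometry that cannot be realized (tumor does not fit, zero-size resample)."""


class DegenerateShapeError(DataError):
    """Mask too degenerate for shape analysis (single pixel, collinear region)."""


class ConfigError(BusFusionError):
    """Invalid configuration values or schema."""
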