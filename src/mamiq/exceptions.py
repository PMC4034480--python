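"""Exception hierarchy shared by the toolkit.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems (unreadable files, out-of-bounds regions, unsupported formats)
exit 3, and numerical failures exit 4.
"""


class MamiqError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(MamiqError):
    """Invalid configuration: unknown keys, out-of-range parameters."""


class DataError(MamiqError):
    """Invalid or unusable input data."""


class BoundsError(DataError):
    """A region of interest does not fit inside its frame."""


class UnsupportedFormatError(DataError):
    """File exists but is not a format the toolkit reads (multi-frame
    DICOM, colour images, unknown extensions)."""


class DegenerateDesignError(DataError):
    """Regression design with no spread in the independent variable."""


class NumericalError(MamiqError):
    """A computation failed numerically (division by a zero spectrum,
    undefined coefficient of variation, ...)."""
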