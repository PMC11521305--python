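"""Exception hierarchy.

Every error raised by the package derives from :class:`QeegError` so callers
can catch pipeline failures without masking programming errors.
"""


class QeegError(Exception):
    """Base class for all package errors."""


class FormatError(QeegError):
    """A file could not be parsed as the expected format."""


class ChannelNotFoundError(QeegError):
    """The named EEG channel is absent from the recording file."""


class SchemaError(QeegError):
    """A table is missing required columns."""


class ValidationError(QeegError):
    """Data violate an invariant (duplicates, non-finite samples, ...)."""


class UnsupportedRateError(QeegError):
    """Sampling rate below the 100 Hz target grid."""


class TooShortError(QeegError):
    """Recording shorter than one analysis window."""


class MissingEventError(QeegError):
    """A symbolic window was requested but no dose event exists."""


class InsufficientDataError(QeegError):
    """Not enough clean data (or subjects) to compute the quantity."""


class DegenerateSpectrumError(QeegError):
    """Total spectral power is zero; relative power undefined."""


class DesignError(QeegError):
    """Study design cannot support the requested model."""


class ConvergenceError(QeegError):
    """Variance-component optimisation failed to converge."""


class ConfigError(QeegError):
    """Invalid or inconsistent configuration."""
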