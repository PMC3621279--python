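"""Exception hierarchy for the mbdose pipeline.

All errors derive from :class:`MbdoseError` so callers can catch the package's
failures with a single except clause; most also derive from ``ValueError``
because they signal invalid inputs rather than internal faults.
"""


class MbdoseError(Exception):
    """Base class for all mbdose errors."""


class GeometryError(MbdoseError, ValueError):
    """A field, strip or sampling window does not fit the image/profile."""


class DomainError(MbdoseError, ValueError):
    """A parameter lies outside the physically/mathematically valid domain."""


class MetadataError(MbdoseError, ValueError):
    """Required scan metadata (e.g. pixel size) is missing or invalid."""


class FormatError(MbdoseError, ValueError):
    """Unsupported image format or bit depth."""


class ChannelError(MbdoseError, ValueError):
    """Wrong number of colour channels for the requested operation."""


class DetectionError(MbdoseError, ValueError):
    """No peaks exceed the prominence threshold."""


class FitError(MbdoseError, ValueError):
    """Calibration fit is rank deficient or otherwise impossible."""


class InversionError(MbdoseError, ValueError):
    """A response cannot be mapped back to a dose by the calibration curve."""


class ComputationError(MbdoseError, ValueError):
    """A ratio/aggregate is requested from empty or invalid inputs."""


class WidthError(MbdoseError, ValueError):
    """FWHM is undefined: no half-maximum crossing on one or both sides."""


class InputError(MbdoseError, ValueError):
    """Statistical input too small (e.g. group size < 2)."""


class ConfigError(MbdoseError, ValueError):
    """Pipeline configuration is incomplete or violates an invariant."""
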