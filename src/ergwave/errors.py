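"""Exception hierarchy.

Every error raised by the package derives from :class:`ErgwaveError` so
callers can catch pipeline failures with a single except clause.
"""


class ErgwaveError(Exception):
    """Base class for all ergwave errors."""


class ConfigurationError(ErgwaveError):
    """A spec/config value is invalid (bad duration, cutoff >= Nyquist, ...)."""


class SamplingError(ConfigurationError):
    """Sampling rate too low to resolve the requested signal content."""


class FormatError(ErgwaveError):
    """A file on disk does not conform to the expected text format."""


class ValidationError(ErgwaveError):
    """Parsed content violates a domain invariant (duplicate keys, bad step)."""


class DesignError(ValidationError):
    """A statistical design is unbalanced or otherwise unusable."""


class AlignmentError(ErgwaveError):
    """Traces cannot be combined because their grids/metadata disagree."""


class GeometryError(ErgwaveError):
    """A mask or retina-disk geometry is degenerate."""


class ResolutionError(GeometryError):
    """The requested area fraction cannot be realized at this image size."""


class InsufficientDataError(ErgwaveError):
    """Too few observations for the requested statistic."""


class UnresolvedFeatureError(ErgwaveError):
    """A fallback feature value cannot be resolved (no baseline latency)."""
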