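"""Exception hierarchy for the xbias pipeline.

Every stage raises a subclass of :class:`XBiasError` so callers (and the CLI)
can distinguish bad input files, bad metadata, and statistically degenerate
input from programming errors.
"""


class XBiasError(Exception):
    """Base class for all xbias errors."""


class FormatError(XBiasError):
    """A file does not conform to its declared tab-delimited format."""


class MetadataError(XBiasError):
    """Sample or probe metadata is missing or inconsistent with the data."""


class DegenerateInputError(XBiasError):
    """Input is statistically degenerate (zero variance, empty margin, ...)."""


class InsufficientDataError(XBiasError):
    """Too few observations for the requested statistic."""


class ConfigurationError(XBiasError):
    """A simulation or pipeline configuration is invalid or incomplete."""
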