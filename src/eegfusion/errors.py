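"""Exception hierarchy shared across the pipeline."""


class EEGFusionError(Exception):
    """Base class for all package errors."""


class FormatError(EEGFusionError):
    """A file does not conform to the expected on-disk dialect."""


class MissingChannelError(EEGFusionError):
    """A requested channel label is absent from a record."""


class BoundsError(EEGFusionError):
    """An interval or index lies outside the record."""


class ConfigError(EEGFusionError):
    """A configuration value is invalid for the data it is applied to."""


class LengthError(EEGFusionError):
    """An input sequence is too short for the requested operation."""


class SchemaError(EEGFusionError):
    """Feature matrices or segments disagree on their column/channel schema."""


class AlignmentError(EEGFusionError):
    """Row counts or row labels disagree between matrices to be fused."""


class MonotoneSignalError(EEGFusionError):
    """A signal has too few extrema to be decomposed further (trend/monotone)."""
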