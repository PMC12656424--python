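"""Exception hierarchy shared across the pipeline stages."""


class SwallowSenseError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(SwallowSenseError):
    """A domain-object invariant was violated (message names the invariant)."""


class SchemaError(SwallowSenseError):
    """An on-disk table or in-memory matrix has the wrong shape/columns."""


class ParseError(SwallowSenseError):
    """A file could not be parsed into the expected typed table."""


class ConfigError(SwallowSenseError):
    """A configuration value is outside its admissible range."""


class DegenerateInputError(SwallowSenseError):
    """An operation received input with zero scale (constant signal, empty spectrum...)."""


class DetectionError(SwallowSenseError):
    """Swallow detection could not produce a peak (e.g. all windows excluded)."""


class EpochError(SwallowSenseError):
    """An analysis epoch could not be cut from the trial."""


class JoinError(SwallowSenseError):
    """An epoch could not be matched to a clinical-table row."""
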