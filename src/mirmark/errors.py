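"""Exception types shared across the pipeline."""


class MirmarkError(Exception):
    """Base class for all package errors."""


class FormatError(MirmarkError, ValueError):
    """A tabular input file violates the expected format."""


class ParseError(FormatError):
    """A cell could not be parsed; the message names row and column."""


class ConfigError(MirmarkError, ValueError):
    """An invalid configuration value or combination."""


class DegenerateInputError(MirmarkError, ValueError):
    """Input is structurally valid but statistically degenerate
    (zero variance, single class, empty target set, ...)."""


class DegenerateFoldError(MirmarkError, RuntimeError):
    """A leave-one-out training fold contains a single class."""
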