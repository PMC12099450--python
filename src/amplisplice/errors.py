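"""Exception hierarchy: configuration problems exit with code 2 from the CLI,
data problems with code 3."""


class AmplispliceError(Exception):
    """Base class for all package errors."""


class ConfigError(AmplispliceError):
    """Invalid configuration, parameters or model definitions."""


class ParseError(AmplispliceError):
    """Malformed input file."""


class DataError(AmplispliceError):
    """Input data violates an analysis precondition (e.g. empty read set)."""
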