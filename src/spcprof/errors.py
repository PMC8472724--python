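"""Exception hierarchy shared by all spcprof modules.

``exit_code`` on each class maps the error onto the CLI's exit-code
contract: 2 for validation failures, 3 for unreadable/malformed input.
"""


class SpcprofError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(SpcprofError):
    """Input violates a documented invariant (duplicate keys, bad ranges...)."""

    exit_code = 2


class ConfigError(ValidationError):
    """A configuration value is missing or out of its allowed domain."""


class ParseError(SpcprofError):
    """A file could not be parsed in the documented dialect."""

    exit_code = 3


class FormatError(ParseError):
    """A file parses but lacks required columns/structure."""


class DegenerateRegressionError(ValidationError):
    """Regression requested on a constant predictor."""


class UndefinedFdrError(ValidationError):
    """FDR requested with zero target PSMs."""
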