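"""Exception hierarchy.

``FormatError`` signals a malformed input file (missing column, headerless
body); ``DataError`` signals well-formed input whose content violates a
contract (non-monotone timestamps, overlapping intervals); ``ConfigError``
signals an invalid or infeasible configuration.
"""


class SmiletraceError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SmiletraceError):
    """Input file does not conform to the expected dialect."""


class DataError(SmiletraceError):
    """Input content violates a data contract."""


class ConfigError(SmiletraceError):
    """Configuration is invalid or infeasible."""
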