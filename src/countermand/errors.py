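"""Exception hierarchy.

``ConfigurationError`` and ``ValidationError`` signal bad inputs (exit code 1
in the CLI); ``AnalysisError`` signals data that cannot support a requested
analysis, e.g. an empty trial group (exit code 2).
"""


class CountermandError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CountermandError):
    """Invalid simulation or pipeline parameters."""


class ValidationError(CountermandError):
    """Malformed or internally inconsistent session data."""


class AnalysisError(CountermandError):
    """An analysis cannot be carried out on the data provided."""
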