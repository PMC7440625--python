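"""Exception hierarchy.

Errors are split by who has to act: :class:`SchemaError` and
:class:`ConfigError` mean the inputs or settings are malformed (fix the
file/config), :class:`AnalysisError` means a statistic is undefined on
otherwise valid data (e.g. an anchor population is missing or degenerate).
The CLI maps these onto distinct exit codes.
"""


class StopleakError(Exception):
    """Base class for all package errors."""


class SchemaError(StopleakError):
    """An input table violates the documented schema (missing columns,
    duplicate wells, unknown role strings, non-finite numbers, ...)."""


class ConfigError(StopleakError):
    """Invalid configuration or usage (unknown keyword, missing blanks,
    invalid simulation parameters)."""


class AnalysisError(StopleakError):
    """A requested statistic is undefined on the given data."""
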