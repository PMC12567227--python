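"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`FaersError` so the CLI can abort
with the stage name and a nonzero exit status.
"""


class FaersError(Exception):
    """Base class for all package errors."""


class InputFileError(FaersError, OSError):
    """A required input file is missing or unreadable."""


class FormatError(FaersError, ValueError):
    """A file does not conform to the expected dialect/column set."""


class ConfigurationError(FaersError, ValueError):
    """An invalid option, mode, or run configuration."""


class UndefinedEstimateError(FaersError, ValueError):
    """A ratio estimate or test is undefined for the given table cells."""
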