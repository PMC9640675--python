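"""Exception hierarchy shared across the package.

Each error class maps to one CLI exit code (see ``cli.EXIT_CODES``), so a
shell caller can distinguish bad configuration from bad data.
"""


class TrichoprojError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TrichoprojError):
    """Invalid parameter or configuration value."""


class DomainError(TrichoprojError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ShapeError(TrichoprojError):
    """Gridded inputs do not share one geometry."""


class FormatError(TrichoprojError):
    """A file does not conform to the expected on-disk layout."""


class PairingError(TrichoprojError):
    """Replicates of a culture table cannot be paired across treatments."""


class DegenerateVarianceError(TrichoprojError):
    """All paired differences identical: the t statistic is undefined."""


class UndefinedFractionError(TrichoprojError):
    """Contribution fractions requested where the total rate is zero."""
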