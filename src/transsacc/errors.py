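"""Exception hierarchy shared across the package."""


class TranssaccError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TranssaccError):
    """An invalid task, observer, cohort or pipeline configuration."""


class DataError(TranssaccError):
    """Input data violate a precondition (shape, content, degeneracy)."""


class NoSaccadeError(DataError):
    """No suprathreshold velocity interval was found in an eye trace."""


class DegenerateDataError(DataError):
    """Response data carry no information for a psychometric fit."""


class NoThresholdError(DataError):
    """The percent-correct curve never attains the requested criterion."""


class NotTestableError(DataError):
    """A 2x2 contingency table has a degenerate margin and cannot be tested."""
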