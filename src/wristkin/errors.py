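"""Exception hierarchy shared across the package."""


class WristkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(WristkinError, ValueError):
    """A parameter is outside its documented domain."""


class WorkspaceViolationError(InvalidParameterError):
    """Requested geometry does not fit inside the 10 x 10 cm device workspace."""


class InsufficientDataError(WristkinError, ValueError):
    """Too few samples to carry out the requested computation."""


class DegenerateInputError(WristkinError, ValueError):
    """Input is structurally degenerate (e.g. a zero-length trajectory)."""


class DegenerateFeatureError(DegenerateInputError):
    """A feature column has zero variance and cannot be standardized."""


class ConfigurationError(WristkinError, ValueError):
    """Invalid or missing configuration (hyperparameters, normalization stats)."""


class ContractViolationError(WristkinError, ValueError):
    """Caller broke an interface contract (length mismatch, unstandardized input)."""


class WrongAlgorithmError(ConfigurationError):
    """An algorithm-specific operation was applied to the wrong model type."""


class UndefinedCorrelationError(DegenerateInputError):
    """Correlation requested on a constant vector or column."""
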