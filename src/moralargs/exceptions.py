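"""Exception hierarchy used across the package."""


class MoralArgsError(Exception):
    """Base class for all package errors."""


class ValidationError(MoralArgsError, ValueError):
    """An input value or table failed validation; the message names the field."""


class InsufficientDataError(MoralArgsError, ValueError):
    """Too few observations to compute the requested quantity."""


class DegenerateInputError(MoralArgsError, ValueError):
    """Input is formally valid but degenerate (e.g. zero-variance column)."""


class EstimationError(MoralArgsError, RuntimeError):
    """A model fit could not be carried out (separation, collinearity, ...)."""
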