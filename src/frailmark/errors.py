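"""Exception types shared across the package."""


class FrailmarkError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FrailmarkError, ValueError):
    """Invalid user input: bad specification values, malformed arguments."""


class SchemaError(FrailmarkError, ValueError):
    """A table is missing required columns or has inconsistent rows."""


class InsufficientDataError(FrailmarkError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateLabelsError(FrailmarkError, ValueError):
    """A binary outcome contains a single class."""


class ConvergenceError(FrailmarkError, RuntimeError):
    """Iterative fitting failed to converge."""
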