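"""Exception hierarchy for rshift."""


class RshiftError(Exception):
    """Base class for all rshift errors."""


class ConfigurationError(RshiftError):
    """A model or analysis configuration is malformed."""


class ConstraintError(RshiftError):
    """An equality constraint was applied or released illegally."""


class IdentificationError(RshiftError):
    """The model has negative degrees of freedom or is otherwise unidentified."""


class ConvergenceError(RshiftError):
    """An optimizer failed to converge and the result cannot be used downstream."""


class NumericalError(RshiftError):
    """A numerical operation (matrix inversion, decomposition) failed."""


class SchemaError(RshiftError):
    """An input file does not conform to the documented schema."""


class PipelineHalt(RshiftError):
    """The detection pipeline halted before completing (e.g. fit gate failed)."""

    def __init__(self, reason, partial=None):
        super().__init__(reason)
        self.reason = reason
        self.partial = partial
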