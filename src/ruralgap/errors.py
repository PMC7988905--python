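"""Exception hierarchy shared across the package.

Every stage raises a subclass of :class:`RuralGapError` so the CLI can map
error classes to exit codes without string matching.
"""


class RuralGapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RuralGapError):
    """A configuration value is invalid; the message names the field."""


class SchemaError(RuralGapError):
    """Input data is missing a required column or term; the message names it."""


class ParseError(RuralGapError):
    """A value in an input file could not be interpreted; cites the row."""


class EstimationError(RuralGapError):
    """An estimator was handed an empty or degenerate subset."""


class DegenerateTestError(RuralGapError):
    """A hypothesis test is undefined for the given inputs."""


class DegenerateTableError(RuralGapError):
    """A contingency table has a zero expected cell or too few levels."""


class DegenerateInputError(RuralGapError):
    """An input collection has no variation to work with."""


class PoolingError(RuralGapError):
    """Meta-analytic or stratified pooling is impossible."""


class FittingError(RuralGapError):
    """A regression fit failed (separation, rank deficiency, no variation)."""


class PipelineError(RuralGapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
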