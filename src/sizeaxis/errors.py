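"""Exception types raised across the package.

All input-validation failures derive from :class:`ParameterError` (a
``ValueError``) so callers can catch one type; the more specific subclasses
exist because several analyses need to distinguish *why* a stage refused to
run (e.g. an empty size-rank bin vs. a zero-norm channel).
"""


class ParameterError(ValueError):
    """Invalid argument value or combination."""


class DimensionError(ParameterError):
    """Array shapes or sizes are incompatible."""


class EmptyObjectError(ParameterError):
    """No foreground object could be found in an image."""


class BinningError(ParameterError):
    """A size-rank bin is empty or under-occupied."""


class NormalizationError(ParameterError):
    """A channel cannot be normalized (zero norm)."""


class UndefinedStatisticError(ParameterError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class FrozenReadoutError(RuntimeError):
    """Attempt to refit a readout that has been frozen."""


class UnfitReadoutError(RuntimeError):
    """A readout is required but has not been fitted."""


class SchemaError(ValueError):
    """A report or manifest does not conform to its schema."""
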