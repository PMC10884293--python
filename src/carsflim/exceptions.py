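"""Exception taxonomy shared across the package.

Two failure families are distinguished: caller errors (bad arguments,
shape mismatches) and degenerate inputs that are valid in type but carry
no usable signal (all-zero spectra, constant channels).  Degenerate
inputs are recoverable — pipeline code catches them, flags the pixel or
cell, and moves on.
"""


class CarsFlimError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CarsFlimError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(CarsFlimError, ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. an all-zero spectrum or a constant image channel)."""


class UndefinedStatisticError(DegenerateInputError):
    """A statistic (correlation, colocalization coefficient) is
    mathematically undefined for this input."""
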