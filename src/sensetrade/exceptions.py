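"""Exception hierarchy for sensetrade."""


class SensetradeError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(SensetradeError, ValueError):
    """A raw measurement violates its domain (non-positive length, area...)."""


class GeometryError(SensetradeError, ValueError):
    """A geometric construction produced an impossible result."""


class UndefinedStatisticError(SensetradeError, ValueError):
    """A statistic is undefined for the given input (zero variance, no flies...)."""


class NewickParseError(SensetradeError, ValueError):
    """Malformed Newick input."""


class AlignmentError(SensetradeError, ValueError):
    """Trait labels and tree tips cannot be reconciled."""


class RankDeficiencyError(SensetradeError, ValueError):
    """Design matrix is not of full column rank."""


class NumericalError(SensetradeError, ArithmeticError):
    """A matrix factorization or optimizer failed beyond recovery."""
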