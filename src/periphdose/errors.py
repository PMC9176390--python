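"""Exception hierarchy for periphdose.

Every error raised by the library derives from :class:`PeriphdoseError`, so
callers can catch one type at pipeline level while tests discriminate finer.
"""


class PeriphdoseError(Exception):
    """Base class for all periphdose errors."""


class InvalidDomainError(PeriphdoseError, ValueError):
    """An input value lies outside its physically valid domain."""


class DegenerateSpectrumError(PeriphdoseError, ValueError):
    """A spectrum with zero total fluence where a positive total is required."""


class OutOfRangeError(PeriphdoseError, ValueError):
    """An energy outside the valid range of a conversion table."""


class InconsistentPairError(PeriphdoseError, ValueError):
    """A TLD-600/700 pair whose net neutron signal is significantly negative."""


class InvalidFractionError(PeriphdoseError, ValueError):
    """A thermal fraction outside (0, 1]."""


class NormalizationError(PeriphdoseError, ValueError):
    """A spectrum with the wrong normalization flag for the operation."""


class GridMismatchError(PeriphdoseError, ValueError):
    """Two objects built on incompatible energy grids."""


class UnresolvedAssignmentError(PeriphdoseError, KeyError):
    """An organ assignment references a phantom point that is not available."""


class InsufficientVariabilityError(PeriphdoseError, RuntimeError):
    """Too few accepted replicates in a variability analysis."""
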