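"""Exception hierarchy.

All errors derive from :class:`SmoothsumError` so callers can catch the
package's failures with a single except clause; each also derives from the
matching builtin (ValueError / ArithmeticError) for idiomatic handling.
"""


class SmoothsumError(Exception):
    """Base class for all smoothsum errors."""


class ParameterError(SmoothsumError, ValueError):
    """A scalar parameter is outside its admissible range (e.g. mu < 0)."""


class ShapeError(SmoothsumError, ValueError):
    """Array dimensions are inconsistent with the problem."""


class DomainError(SmoothsumError, ValueError):
    """An input value is outside the function's domain (e.g. non-finite)."""


class SchemaError(SmoothsumError, ValueError):
    """A delimited input file is missing required columns."""


class NumericalError(SmoothsumError, ArithmeticError):
    """A computation produced a non-finite value; the message names the term."""


class HarmonizationError(SmoothsumError, ValueError):
    """Summary statistics and genotype panel share no usable variants."""


class CollinearityError(SmoothsumError, ValueError):
    """The covariate design matrix is rank deficient."""


class ConfigError(SmoothsumError, ValueError):
    """A simulation or run configuration is infeasible."""
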