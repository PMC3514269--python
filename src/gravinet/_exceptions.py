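"""Exception hierarchy shared across the package."""


class GravinetError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(GravinetError, ValueError):
    """Raised when user-supplied data or parameters violate a precondition."""


class DegenerateDataError(GravinetError, ValueError):
    """Raised when the expression data carry no usable signal (e.g. all
    singular values below the rank tolerance)."""


class DegenerateSpaceError(GravinetError, ValueError):
    """Raised when a search is requested over a zero-dimensional solution
    family (K = 0); callers short-circuit to the particular solution."""


class SimulationError(GravinetError, RuntimeError):
    """Raised when the synthetic ODE system cannot be stabilized."""


class ParseError(GravinetError, ValueError):
    """Raised on malformed input files; message carries the offending line."""
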