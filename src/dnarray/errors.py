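"""Exception hierarchy."""


class DnarrayError(Exception):
    """Base class for all package errors."""


class ParseError(DnarrayError):
    """Malformed trajectory or topology file; carries a line number when known."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ConsistencyError(DnarrayError):
    """Frames/topology disagree (particle counts, ids, base-pair counts)."""


class DomainError(DnarrayError):
    """Argument outside the physically admissible domain."""


class GeometryError(DnarrayError):
    """Lattice/membrane geometry cannot support the requested operation."""


class DegenerateInputError(DnarrayError):
    """Input too small for the statistic (e.g. single frame, short trace)."""


class NoCrossingError(DnarrayError):
    """A threshold crossing was requested but the series never brackets it."""

    def __init__(self, message, side=None):
        super().__init__(message)
        self.side = side


class StabilityError(DnarrayError):
    """Integrator step divergence; advise a smaller dt."""


class FitError(DnarrayError):
    """Too few usable points (or otherwise ill-posed) regression."""


class NumericalError(DnarrayError):
    """Root finding / numerical procedure failed; carries diagnostics."""
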