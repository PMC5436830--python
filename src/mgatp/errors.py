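"""Exception hierarchy shared by all mgatp modules."""


class MgatpError(Exception):
    """Base class for all package errors."""


class ParseError(MgatpError):
    """A text input (PDB, XVG) could not be parsed; carries a line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class StructureError(MgatpError):
    """A structure/trajectory violates a structural invariant."""


class FormatError(MgatpError):
    """A value cannot be represented in the requested output format."""


class SelectionError(MgatpError):
    """An atom selector matched nothing."""


class EmptySeriesError(MgatpError):
    """A sample series contains no data rows."""


class AnalysisError(MgatpError):
    """An analysis has no frames/samples left to operate on."""


class ConvergenceError(MgatpError):
    """An iterative estimator could not converge; carries a diagnostic."""

    def __init__(self, message: str, diagnostic: dict | None = None):
        super().__init__(message)
        self.diagnostic = diagnostic or {}


class ConstructionError(MgatpError):
    """A synthetic-geometry request is infeasible."""
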