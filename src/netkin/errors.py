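"""Exception hierarchy."""


class NetkinError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NetkinError, ValueError):
    """A physical or numerical parameter is out of its valid domain."""


class SchemeError(NetkinError, ValueError):
    """A kinetic scheme violates a structural invariant."""


class ResolutionError(SchemeError):
    """A species or rate-constant reference does not resolve."""


class SchemeSyntaxError(SchemeError):
    """Scheme file does not conform to the grammar."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ExportError(NetkinError, ValueError):
    """Netlist export failed (e.g. name collision after mangling)."""


class NetlistParseError(NetkinError, ValueError):
    """Netlist text is not in the supported dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SolverError(NetkinError, RuntimeError):
    """Base class for integration failures. Carries the failing time."""

    def __init__(self, message: str, time: float | None = None):
        self.time = time
        if time is not None:
            message = f"{message} (at t={time:g})"
        super().__init__(message)


class StiffnessError(SolverError):
    """Step size underflowed or Newton repeatedly failed to converge."""


class BlowupError(SolverError):
    """State or right-hand side became non-finite."""


class ConvergenceError(NetkinError, RuntimeError):
    """An algebraic (steady-state) solve did not converge."""

    def __init__(self, message: str, best_residual: float | None = None):
        self.best_residual = best_residual
        if best_residual is not None:
            message = f"{message} (best residual {best_residual:.3e})"
        super().__init__(message)
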