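"""Exception hierarchy for gaitkin."""


class GaitKinError(Exception):
    """Base class for all gaitkin errors."""


class InvalidParameterError(GaitKinError, ValueError):
    """A model or configuration parameter is out of its valid range."""


class ProtocolError(GaitKinError, ValueError):
    """Marker protocol is inconsistent or a required marker is missing."""


class UnderdeterminedError(GaitKinError):
    """The visible markers do not observe the full pose.

    Carries ``weak_dofs``, the names of degrees of freedom whose columns of
    the residual Jacobian are (numerically) in its null space.
    """

    def __init__(self, message: str, weak_dofs: list[str] | None = None):
        super().__init__(message)
        self.weak_dofs = weak_dofs or []


class ConvergenceError(GaitKinError):
    """An optimizer failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class TRCParseError(GaitKinError, ValueError):
    """A TRC file violates the expected dialect.

    Carries ``line`` (1-based) when the offending line is known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
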