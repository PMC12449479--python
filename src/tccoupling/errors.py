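"""Exception hierarchy shared across the package."""


class TCCouplingError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TCCouplingError, ValueError):
    """A supplied parameter violates its documented precondition."""


class StateError(TCCouplingError, RuntimeError):
    """Operation applied to an object in an incompatible state."""


class FormatError(TCCouplingError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DomainError(TCCouplingError, ValueError):
    """Location lies on a dendritic/axonal domain the operation excludes."""


class TreeLookupError(TCCouplingError, KeyError):
    """Unknown compartment or synapse identifier."""


class ConfigError(TCCouplingError, ValueError):
    """Inconsistent configuration (grids, domain masks, profiles...)."""


class CalibrationError(TCCouplingError, RuntimeError):
    """Conductance calibration could not bracket or converge."""


class NumericalError(TCCouplingError, RuntimeError):
    """Integration produced a non-finite state; carries diagnostics."""


class DegenerateTraceError(TCCouplingError, ValueError):
    """A trace does not admit the requested measurement."""
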