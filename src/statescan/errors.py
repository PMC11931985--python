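"""Exception hierarchy shared across modules."""


class StatescanError(Exception):
    """Base class for all package-specific errors."""


class ParseError(StatescanError, ValueError):
    """A file could not be parsed; message carries the offending line."""


class ShapeMismatchError(StatescanError, ValueError):
    """Frames/structures are not congruent (atom count or identity)."""


class MissingAtomError(StatescanError, KeyError):
    """A required atom (e.g. a residue's Cα) is absent from the topology."""


class EmptySelectionError(StatescanError, ValueError):
    """A selection resolved to zero atoms."""


class InvalidParameterError(StatescanError, ValueError):
    """A parameter violates an operation's preconditions."""


class DegenerateInputError(StatescanError, ValueError):
    """Geometry too degenerate for the requested operation (e.g. collinear)."""


class InsufficientFramesError(StatescanError, ValueError):
    """An operation needs more trajectory frames than were supplied."""


class ConvergenceError(StatescanError, RuntimeError):
    """An iterative solver failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConfigurationError(StatescanError, ValueError):
    """Pipeline configuration invalid or incomplete."""
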