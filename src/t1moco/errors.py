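"""Exception hierarchy.

Every error raised by this package derives from :class:`T1MocoError`, so
callers (and the CLI) can catch one type and exit non-zero.
"""


class T1MocoError(Exception):
    """Base class for all package errors."""


class ContractError(T1MocoError, ValueError):
    """A documented precondition of an operation was violated."""


class GeometryError(T1MocoError, ValueError):
    """Phantom geometry is degenerate or does not fit in the image."""


class DataError(T1MocoError, ValueError):
    """Input data is structurally valid but semantically inconsistent."""


class GenerationError(T1MocoError, RuntimeError):
    """A random displacement field could not be certified topology-preserving."""


class InversionError(T1MocoError, RuntimeError):
    """Fixed-point inversion of a displacement field did not converge."""

    def __init__(self, message: str, residual_px: float | None = None):
        super().__init__(message)
        self.residual_px = residual_px


class ConfigurationError(T1MocoError, ValueError):
    """A configuration object violates its invariants."""


class FormatError(T1MocoError, ValueError):
    """An on-disk input does not conform to a supported format."""


class TrainingError(T1MocoError, RuntimeError):
    """Training aborted (for example on a non-finite loss)."""
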