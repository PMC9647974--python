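"""Exception hierarchy shared across the package."""


class MetaHicError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MetaHicError, ValueError):
    """Malformed or out-of-contract input values."""


class FormatError(MetaHicError, ValueError):
    """A file does not follow the declared on-disk format."""


class UsageError(MetaHicError, ValueError):
    """Operations combined in an unsupported way (genome mismatch etc.)."""


class UnknownIdError(MetaHicError, KeyError):
    """Lookup of a gene / chromosome / variant id that does not exist."""


class ConvergenceError(MetaHicError, RuntimeError):
    """Iterative balancing failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateInputError(MetaHicError, ValueError):
    """Input is structurally empty (e.g. all-zero matrix rows)."""


class NoCompartmentsError(MetaHicError, RuntimeError):
    """Compartment calling failed for a chromosome (constant correlation)."""


class ConfigError(MetaHicError, ValueError):
    """Bad run configuration (unknown key, unparseable value)."""


class UndefinedAUCError(MetaHicError, ValueError):
    """AUROC is undefined (no positives or no negatives); callers skip."""
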