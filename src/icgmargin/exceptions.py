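"""Exception hierarchy shared across the package."""


class IcgMarginError(Exception):
    """Base class for all package errors."""


class DomainError(IcgMarginError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class ValidationError(IcgMarginError, ValueError):
    """A container violates its structural invariants (shape, range, dtype)."""


class FormatError(IcgMarginError, IOError):
    """A file cannot be decoded or its format is unsupported."""


class IntegrityError(IcgMarginError, IOError):
    """Decoded data is internally inconsistent (e.g. frames of differing shape)."""


class UndefinedContrastError(DomainError):
    """Michelson contrast is undefined (i_max + i_min == 0)."""


class UndefinedCorrelationError(DomainError):
    """NCC is undefined because one input has zero sample variance."""


class EmptyForegroundError(IcgMarginError, ValueError):
    """Thresholding or masking left no foreground pixels to analyse."""


class EmptyClusterError(IcgMarginError, RuntimeError):
    """k-means converged with at least one empty cluster despite restarts."""
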