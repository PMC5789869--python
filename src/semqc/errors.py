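"""Exception hierarchy shared by all semqc modules.

Every error carries a machine-readable ``category`` used by the CLI to map
failures onto exit codes: usage/schema problems exit 2, computation problems
exit 1.
"""


class SemqcError(Exception):
    """Base class for all package errors."""

    category = "error"
    exit_code = 1


class ValidationError(SemqcError):
    """An input value violates a documented invariant (negative area, ...)."""

    category = "validation"
    exit_code = 2


class FormatError(SemqcError):
    """A file is not in a supported format (multi-channel image, odd bit depth)."""

    category = "format"
    exit_code = 2


class SchemaError(SemqcError):
    """A CSV does not match the declared column schema."""

    category = "schema"
    exit_code = 2


class FitError(SemqcError):
    """Nonlinear fit failed to converge; carries the best residual seen."""

    category = "fit"
    exit_code = 1

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class EmptyHistogramError(SemqcError):
    """A histogram with no counts cannot support the requested statistic."""

    category = "empty-histogram"
    exit_code = 1


class AlignmentError(SemqcError):
    """A section thickness does not coincide with a depth-bin start."""

    category = "alignment"
    exit_code = 2
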