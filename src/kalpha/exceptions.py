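"""Exception and warning types shared across the package."""


class KalphaError(Exception):
    """Base class for all package errors."""


class ValidationError(KalphaError, ValueError):
    """Raised when input data or settings violate a contract (exit code 2 in the CLI)."""


class EstimationError(KalphaError, RuntimeError):
    """Raised when a coefficient cannot be estimated on the given data
    (e.g. fewer than two complete-case subjects for Fleiss' K, or no subject
    with at least two ratings for Krippendorff's alpha). Exit code 3 in the CLI.
    """

    def __init__(self, message: str, *, n_subjects_used: int | None = None):
        super().__init__(message)
        self.n_subjects_used = n_subjects_used


class DegenerateDataWarning(UserWarning):
    """Emitted when an estimate is defined only by convention (a single
    category used everywhere makes both coefficients 0/0; the package
    returns 1.0 with ``degenerate_flag`` set)."""
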