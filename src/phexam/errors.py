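"""Exception hierarchy shared across the package."""


class PhexamError(Exception):
    """Base class for all package-specific errors."""


class DataError(PhexamError):
    """Malformed or internally inconsistent input data."""


class EmptySelectionError(DataError):
    """A filter (sign, phase, examiner group) matched no assessments."""


class EstimationError(PhexamError):
    """A quantity is not estimable from the given data (degenerate margins,
    single disease class, empty posterior, ...)."""
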