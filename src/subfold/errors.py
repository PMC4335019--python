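"""Exception hierarchy shared across the package.

Each top-level error class maps to a distinct CLI exit code so shell
pipelines can distinguish bad input from bad constraints from I/O trouble.
"""


class SubfoldError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(SubfoldError):
    """Invalid sequence, structure, option value or malformed input."""

    exit_code = 2


class ConstraintConflictError(SubfoldError):
    """Mutually inconsistent experimental constraints (names positions)."""

    exit_code = 3


class ParameterError(ValidationError):
    """Malformed thermodynamic parameter file; message names the block."""


class EnumerationCapExceeded(SubfoldError):
    """The safety cap on emitted structures was reached."""
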