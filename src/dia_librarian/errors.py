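"""Exception hierarchy.

All readers reject malformed input with :class:`FormatError` rather than
silently coercing; user-supplied parameter problems raise
:class:`ConfigurationError`; violations of internal contracts raise
:class:`InternalError` (a bug, not a user error).
"""


class DiaLibrarianError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DiaLibrarianError):
    """Invalid user-supplied parameter or option."""


class FormatError(DiaLibrarianError):
    """Malformed or unsupported input file content."""


class DataError(DiaLibrarianError):
    """Input data that is well-formed but unusable (e.g. precursor outside
    every isolation window)."""


class ValidationError(DiaLibrarianError):
    """An output or intermediate object violates its contract."""


class StateError(DiaLibrarianError):
    """Operation called on an object in the wrong state (e.g. prediction
    from an untrained model)."""


class InternalError(DiaLibrarianError):
    """Internal invariant violated; indicates a bug."""


class TrainingError(DiaLibrarianError):
    """Model training diverged (non-finite loss)."""
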