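"""Exception hierarchy shared across the package."""


class GaitbenchError(Exception):
    """Base class for all package errors."""


class ValidationError(GaitbenchError, ValueError):
    """Invalid user input (parameters, subject data, configs)."""


class ConfigurationError(GaitbenchError):
    """Inconsistent or incomplete configuration (tables, marker sets, models)."""


class DegenerateContactError(GaitbenchError):
    """Contact Jacobian rank-deficient after redundancy reduction."""


class ScheduleError(GaitbenchError):
    """Gait-event sequence does not match the stride phase grammar."""


class EmptyMotionError(GaitbenchError):
    """No usable frames survived a trajectory fit."""


class SolverError(GaitbenchError):
    """An iterative solve failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class IOFormatError(GaitbenchError):
    """Unreadable or ambiguous input file."""


class UnsupportedFormatError(IOFormatError):
    """File format recognised but not supported by this build."""
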