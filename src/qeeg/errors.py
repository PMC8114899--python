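"""Exception hierarchy shared by all qeeg modules.

The CLI maps these onto exit codes (validation 2, input 3,
insufficient data 4), so library code should raise the most
specific class that applies.
"""


class QeegError(Exception):
    """Base class for all qeeg errors."""


class InputError(QeegError):
    """Missing files, empty recordings, malformed user input."""


class FormatError(InputError):
    """A file exists but cannot be parsed under its declared format."""


class ParameterError(QeegError):
    """A configuration value violates its documented constraints."""


class InsufficientDataError(QeegError):
    """Not enough clean (unmasked) data to compute the requested quantity."""

    def __init__(self, message: str, required: float | None = None,
                 available: float | None = None):
        super().__init__(message)
        self.required = required
        self.available = available


class ConfigValidationError(QeegError):
    """Raised by the pipeline when a config fails validation.

    Carries the complete list of violations, not just the first.
    """

    def __init__(self, violations: list[str]):
        super().__init__("; ".join(violations))
        self.violations = list(violations)
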