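"""Exception types shared across the package."""


class QsdoseError(Exception):
    """Base class for package errors."""


class ConfigurationError(QsdoseError):
    """A run/solver configuration is invalid (Courant violation, padding, ...)."""


class FormatError(QsdoseError):
    """A file does not match its declared sidecar metadata."""


class SingularSourceError(QsdoseError):
    """A grid node coincides with (or is too close to) a source filament."""


class ConvergenceError(QsdoseError):
    """The FDTD solve did not reach steady state within max_steps.

    Carries the monitor trace for post-mortem inspection.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
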