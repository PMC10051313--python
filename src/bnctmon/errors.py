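"""Exception hierarchy shared across the monitoring modules.

Everything derives from :class:`BnctMonError` so callers (and the CLI)
can catch domain failures in one place; each subclass also inherits the
closest stdlib exception so untargeted ``except ValueError`` style code
keeps working.
"""


class BnctMonError(Exception):
    """Base class for all package-specific errors."""


class DomainError(BnctMonError, ValueError):
    """An input violates a physical or mathematical precondition."""


class RangeError(DomainError):
    """A rate lies beyond the physical range of the dead-time model."""


class SaturationError(DomainError):
    """A measured rate exceeds the invertible range of the dead-time model."""


class FittingError(BnctMonError, ValueError):
    """A parameter fit cannot be performed (degenerate design, too few points)."""


class ConfigurationError(BnctMonError, ValueError):
    """A calibration or plan parameter makes the requested computation undefined."""


class StreamError(BnctMonError, ValueError):
    """A telemetry stream is malformed (out-of-order timestamps, bad rows)."""


class StateError(BnctMonError, RuntimeError):
    """An operation is not valid in the current session / engine state."""
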