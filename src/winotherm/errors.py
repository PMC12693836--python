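"""Exception hierarchy shared across the package."""


class WinothermError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(WinothermError, ValueError):
    """A geometric quantity (diameter, footprint area, ...) is non-positive."""


class ConfigurationError(WinothermError, ValueError):
    """A configuration value is outside its supported domain."""


class ChannelError(WinothermError, ValueError):
    """A required sensor channel is missing or unrecognized."""


class NonConvergenceError(WinothermError, RuntimeError):
    """An iterative measurement series never satisfied its convergence rule."""

    def __init__(self, message: str, last_delta: float | None = None):
        super().__init__(message)
        self.last_delta = last_delta


class InsufficientCoverageError(WinothermError, ValueError):
    """A statistic requires more valid measurement days than are available."""


class StabilityError(WinothermError, ValueError):
    """The explicit integration step violates the stability bound."""
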