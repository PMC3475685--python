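"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A model or kernel parameter violates its constraints."""


class ConfigError(ValueError):
    """A run configuration, schedule or connection map is invalid."""


class InstabilityError(RuntimeError):
    """The simulated membrane potentials left the physiological range.

    Raised instead of clipping: a clipped trajectory would silently corrupt
    every downstream spectrum, so the run aborts with diagnostics.
    """

    def __init__(self, message: str, time_ms: float | None = None):
        super().__init__(message)
        self.time_ms = time_ms
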