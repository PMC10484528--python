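"""Exception hierarchy for the toolkit."""


class LifmapError(Exception):
    """Base class for all toolkit errors."""


class SimulationError(LifmapError):
    """Integration produced an invalid (non-finite or overflowing) state.

    Carries the offending step index in ``step``.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class InsufficientDataError(LifmapError):
    """A trace is too short for the requested operation."""


class EncodingError(LifmapError):
    """Mantissa/exponent bias encoding failed (range violation)."""


class ScalingError(LifmapError):
    """A physical quantity does not fit the integer domain at the chosen voltage scale."""


class DecayRangeError(LifmapError):
    """Membrane time constant outside the range representable by the decay integer."""


class MaskError(LifmapError):
    """Trace comparison is impossible (misaligned traces or everything masked)."""


class DegenerateTraceError(LifmapError):
    """A constant trace has no variance; correlation is undefined."""


class GridError(LifmapError):
    """Invalid parameter grid or grid-dependent operation."""


class ConfigError(LifmapError):
    """A run configuration failed validation; the message names the offending key."""
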