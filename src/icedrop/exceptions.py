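"""Exception types raised across the icedrop package."""


class IcedropError(Exception):
    """Base class for all icedrop-specific errors."""


class EmptySampleError(IcedropError, ValueError):
    """A statistic was requested for a sample with no droplets."""


class InconsistentCountsError(IcedropError, ValueError):
    """Frozen count exceeds total count, or counts are otherwise impossible."""


class CensoredPointError(IcedropError, ValueError):
    """Active-site density is undefined because the frozen fraction is 1."""


class InseparableClassesError(IcedropError, ValueError):
    """Threshold calibration failed: reference intensity distributions overlap."""


class UndefinedOnsetError(IcedropError, ValueError):
    """The freezing curve never reaches the requested frozen fraction."""


class FitFailureError(IcedropError, RuntimeError):
    """Nonlinear least squares did not converge within the allowed restarts."""


class ConfigError(IcedropError, ValueError):
    """An experiment configuration is invalid."""
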