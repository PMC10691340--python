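"""Exception types shared across the package."""


class InfoLoadError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(InfoLoadError, ValueError):
    """Invalid or inconsistent configuration."""


class StepSizeError(InfoLoadError, ValueError):
    """Integration step too large relative to the network time constant."""


class ToleranceError(InfoLoadError, RuntimeError):
    """A numerical routine failed to reach its requested tolerance."""


class TrainingError(InfoLoadError, RuntimeError):
    """Gradient-based optimization diverged (non-finite loss)."""


class CalibrationError(InfoLoadError, RuntimeError):
    """Noise calibration target unreachable."""


class FormatError(InfoLoadError, ValueError):
    """A file does not conform to the expected on-disk schema."""
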