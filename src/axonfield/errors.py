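"""Exception types shared across the pipeline."""


class AxonFieldError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AxonFieldError, ValueError):
    """A scale, factor or level parameter is outside its valid range."""


class UndersamplingError(InvalidParameterError):
    """The requested filter scale is below the pixel Nyquist limit (sigma < 0.5 px)."""


class CalibrationError(AxonFieldError, ValueError):
    """Pixel pitch of an image and a filter bank (or two rasters) disagree."""


class DegenerateLandmarksError(AxonFieldError, ValueError):
    """Eye landmarks coincide, so no similarity transform exists."""


class InputFormatError(AxonFieldError, ValueError):
    """An input file could not be interpreted (wrong channels, columns, ...)."""
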