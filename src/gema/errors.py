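"""Exception hierarchy for the gema package."""


class GemaError(Exception):
    """Base class for all gema-specific errors."""


class ValidationError(GemaError, ValueError):
    """An input violated a documented precondition or invariant."""


class FormatError(GemaError, ValueError):
    """A file is not in a supported or recognizable format."""


class ImageIOError(GemaError, IOError):
    """An image file could not be read or written."""


class UndefinedCVError(GemaError, ArithmeticError):
    """Coefficient of variation is undefined (zero-mean image)."""


class DegenerateFitError(GemaError, ValueError):
    """Regression requested on points that do not determine a line."""


class OrderingError(GemaError, ValueError):
    """Frame indices were supplied out of order."""


class ConfigError(GemaError, ValueError):
    """A configuration value is invalid or inconsistent."""
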