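"""Exception hierarchy used across the package."""


class MosaicQuantError(Exception):
    """Base class for all package errors."""


class SpecValidationError(MosaicQuantError, ValueError):
    """A parameter object violates one of its invariants; names the field."""


class CapacityError(MosaicQuantError, ValueError):
    """The requested synthetic image cannot hold the requested objects."""


class ImageFormatError(MosaicQuantError, ValueError):
    """Input image is not an 8-bit RGB array of the expected shape."""


class DegenerateImageError(MosaicQuantError, ValueError):
    """Image content cannot support the computation (all black, constant
    intensity, fully excluded).  Cores raising this are 'unevaluable'."""


class UnevaluableCoreError(MosaicQuantError, ValueError):
    """The core produced no usable myocyte area; mirrors the study practice
    of dropping unevaluable images."""


class InsufficientDataError(MosaicQuantError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(MosaicQuantError, ValueError):
    """A correlation was requested on a zero-variance vector."""


class ConfigError(MosaicQuantError, ValueError):
    """Run configuration failed validation before any computation."""
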