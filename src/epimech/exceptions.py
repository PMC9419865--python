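"""Exception hierarchy for epimech.

Every error raised on bad input or degenerate data derives from
:class:`EpimechError` so callers can catch pipeline failures uniformly.
"""


class EpimechError(Exception):
    """Base class for all epimech errors."""


class InvalidParameterError(EpimechError, ValueError):
    """A physical or algorithmic parameter is outside its valid range."""


class ResolutionError(InvalidParameterError):
    """Requested structures are not resolvable at the given pixel size."""


class CapacityError(EpimechError):
    """Object placement failed after bounded retries.

    Carries the name of the limiting parameter so the caller knows what
    to relax (density, minimum spacing, image size ...).
    """

    def __init__(self, message: str, limiting_parameter: str):
        super().__init__(message)
        self.limiting_parameter = limiting_parameter


class NoContactError(EpimechError):
    """No contact regime could be detected in a force curve."""


class DomainError(EpimechError):
    """An indentation falls outside the parametric range of the contact model."""


class EmptySegmentationError(EpimechError):
    """Segmentation produced no foreground objects."""


class DegenerateGeometryError(EpimechError):
    """A mask is too thin or small for skeleton-based measurement."""


class InvalidAnnulusError(EpimechError):
    """The spectral annulus contains no power."""


class InsufficientObjectsError(EpimechError):
    """Fewer objects than the operation requires (e.g. <2 nuclei)."""


class ReferenceUndefinedError(EpimechError):
    """No background/substrate reference pixels available for a height measure."""


class UndefinedRatioError(EpimechError, ZeroDivisionError):
    """A fold change or fraction has a zero denominator."""


class EmptyTableError(EpimechError):
    """An aggregation was asked to summarise an empty collection."""


class InputMissingError(EpimechError, FileNotFoundError):
    """A pipeline stage input path does not exist."""


class ConfigError(EpimechError):
    """Run configuration is malformed (unknown keys, bad types)."""
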