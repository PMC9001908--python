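"""Domain-specific errors raised across the pipeline.

Every error that a caller may want to branch on gets its own class; all of
them derive from :class:`EndosegError` so a CLI can catch the family and turn
it into a diagnostic message plus a nonzero exit status.
"""


class EndosegError(Exception):
    """Base class for all domain errors raised by this package."""


class ValidationError(EndosegError, ValueError):
    """A parameter or input violates a documented precondition."""


class MissingSpacingError(EndosegError):
    """No physical pixel spacing is available for a millimetre-valued output."""


class AnisotropySpacingError(EndosegError):
    """Row/column pixel spacings differ by more than the allowed tolerance."""


class FormatError(EndosegError):
    """A file could not be parsed as the expected image or table format."""


class SchemaError(FormatError):
    """A tabular input is missing required columns."""


class EmptyMaskError(EndosegError):
    """A measurement was requested on a mask with no foreground pixels.

    Signals upstream segmentation failure: there is nothing to measure.
    """


class DegenerateTestError(EndosegError):
    """A statistical test is undefined for the given groups (zero variance)."""
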