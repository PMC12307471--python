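"""Exception hierarchy.

Validation problems (malformed input, inconsistent shapes, degenerate data)
raise :class:`ValidationError`; everything else is an internal error. The CLI
maps ValidationError to exit code 2 and any other failure to exit code 1.
"""


class SerfeError(Exception):
    """Base class for all package errors."""


class ValidationError(SerfeError):
    """Malformed or inconsistent user input."""


class FormatError(ValidationError):
    """A file violates the expected tabular/volume format."""


class GeometryError(ValidationError):
    """Image and mask grids are inconsistent."""


class ROIError(ValidationError):
    """The region of interest is empty or otherwise unusable."""


class AlignmentError(ValidationError):
    """Two pipeline objects refer to different patients or features."""


class DegenerateDataError(ValidationError):
    """Data too degenerate for the requested computation (e.g. all-constant)."""
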