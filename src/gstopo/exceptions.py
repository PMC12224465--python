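"""Exception hierarchy for gstopo.

Every error raised deliberately by the package derives from :class:`GstopoError`
so callers can catch pipeline failures without masking programming errors.
"""


class GstopoError(Exception):
    """Base class for all gstopo errors."""


class CohortError(GstopoError):
    """Invalid cohort request (e.g. too few subjects)."""


class ParameterError(GstopoError):
    """A parameter is outside its admissible range."""


class LayoutError(GstopoError):
    """The requested grid cannot host the atlas region layout."""


class ShapeError(GstopoError):
    """Array shapes are inconsistent with the operation's contract."""


class InsufficientDataError(GstopoError):
    """Too few retained frames (or subjects) for a stable estimate."""


class DegenerateError(GstopoError):
    """Degenerate input (zero variance, empty mask, empty model)."""


class ProvenanceError(GstopoError):
    """A subject or stage output is missing from an upstream record."""


class FormatError(GstopoError):
    """A file on disk does not match the expected text/NIfTI format."""
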