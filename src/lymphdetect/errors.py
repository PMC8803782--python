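"""Exception hierarchy.

Every failure mode raised by the package derives from :class:`LymphDetectError`
so callers can catch the package's errors with a single clause.
"""


class LymphDetectError(Exception):
    """Base class for all package errors."""


class FormatError(LymphDetectError):
    """A file lacks required metadata or cannot be parsed as an image."""


class ShapeError(LymphDetectError):
    """An image has the wrong dimensionality or a degenerate axis."""


class SchemaError(LymphDetectError):
    """A tabular input is missing a required column."""


class ParseError(LymphDetectError):
    """A tabular value cannot be parsed (e.g. non-numeric coordinate)."""


class ConsistencyError(LymphDetectError):
    """Cross-referenced objects disagree (unknown patient, voxel off-grid...)."""


class SegmentationFailureError(LymphDetectError):
    """Lung segmentation produced an empty mask: no thorax can be located."""


class PlacementError(LymphDetectError):
    """Requested phantom lesions cannot be placed at the minimum separation."""


class AnnotationError(LymphDetectError):
    """A node annotation lies outside the grid it is being rasterised on."""


class DegenerateDataError(LymphDetectError):
    """Statistics cannot be fitted (e.g. zero variance training data)."""


class NotFittedError(LymphDetectError):
    """A model or transform was used before being fitted/trained."""


class DataError(LymphDetectError):
    """Training data violate a precondition (no positives, single class...)."""


class AmbiguityError(LymphDetectError):
    """A printed rate cannot be inverted to a unique integer count."""


class DependencyError(LymphDetectError):
    """A pipeline stage was requested before its upstream artefacts exist."""
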