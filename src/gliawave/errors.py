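"""Exception hierarchy.

Exit-code mapping used by the CLI: ParameterError -> 2 (validation),
everything else derived from GliawaveError -> 3 (data quality).
"""


class GliawaveError(Exception):
    """Base class for all package errors."""


class ParameterError(GliawaveError, ValueError):
    """Invalid parameter or configuration value."""


class SegmentationError(GliawaveError):
    """Cell segmentation failed (e.g. all frames empty at a threshold)."""


class InsufficientDataError(GliawaveError):
    """Not enough samples/events for the requested statistic."""


class TraceQualityError(GliawaveError):
    """Edge trace could not be extracted reliably (too many missing columns)."""


class GeometryError(GliawaveError):
    """Requested geometry does not fit the image (ROI/line/band out of bounds)."""


class DegenerateSeriesError(GliawaveError):
    """A series has zero variance or is otherwise unusable for correlation."""
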