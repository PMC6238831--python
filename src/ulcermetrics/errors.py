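"""Exception hierarchy for the analysis pipeline.

Every failure mode a caller may want to branch on gets its own class; the CLI
maps each to a distinct exit code.
"""


class UlcerMetricsError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class GeometryError(UlcerMetricsError):
    """Synthetic-scene geometry violates an invariant (ulcer outside foot,
    sticker overlapping ulcer, shape out of image bounds)."""

    exit_code = 6


class NoStickerFound(UlcerMetricsError):
    """No green component survives the area/circularity filters."""

    exit_code = 3


class AmbiguousSticker(UlcerMetricsError):
    """Two or more surviving green components have comparable areas."""

    exit_code = 3


class NoFootFound(UlcerMetricsError):
    """Largest bright component covers too little of the frame."""

    exit_code = 4


class ScribbleError(UlcerMetricsError):
    """Base for scribble-annotation problems."""

    exit_code = 5


class OverlappingScribbles(ScribbleError):
    """Skin and ulcer strokes touch the same pixel after rasterization."""


class OutOfBounds(ScribbleError):
    """A stroke point lies outside the image."""


class MissingMarker(UlcerMetricsError):
    """Marker grid lacks a skin or an ulcer seed."""

    exit_code = 5


class EmptyMask(UlcerMetricsError):
    """Boundary extraction called on an empty mask."""


class MultipleComponents(UlcerMetricsError):
    """Boundary extraction called on a disconnected mask."""


class ContainmentViolation(UlcerMetricsError):
    """Ulcer pixels fall outside the foot silhouette."""


class NoAssessmentPoint(UlcerMetricsError):
    """No measurement lies in the 4-week assessment window."""


class ZeroBaseline(UlcerMetricsError):
    """Percent-of-baseline curve requested with a zero-area baseline."""
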