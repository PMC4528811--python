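"""Exception hierarchy for the geonarrative pipeline.

Validation errors carry enough context (the offending timestamp, the
unparseable name, ...) for a transcriber or analyst to locate and fix the
problem in the source file, since transcripts are hand-edited inputs.
"""


class GeonarrativeError(Exception):
    """Base class for all errors raised by this package."""


class TranscriptError(GeonarrativeError):
    """Problem in a timestamped transcript; carries the offending stamp."""

    def __init__(self, message: str, stamp: str | None = None):
        super().__init__(message)
        self.stamp = stamp


class MalformedStampError(TranscriptError):
    """A line looks like it starts with a timestamp but does not parse."""


class DuplicateStampError(TranscriptError):
    """Two rows share the same timestamp; processing stops at that time."""


class NonSequentialStampError(TranscriptError):
    """A timestamp is earlier than its predecessor."""


class FormatError(GeonarrativeError):
    """An input file does not match the expected format."""


class EmptyTrackError(FormatError):
    """A GPS source contained no track points."""


class NoFixError(GeonarrativeError):
    """A track contains no valid GPS fix."""


class OutOfRangeError(GeonarrativeError):
    """A query time falls outside the track's valid span."""


class NoOverlapError(GeonarrativeError):
    """No transcript word falls inside the track's valid span.

    Almost always signals a clock-calibration mistake (wrong key-sound
    match) rather than a genuinely disjoint ride.
    """


class NoMappedWordError(GeonarrativeError):
    """Every word of the requested transcript range was dropped."""


class EmptyPatternError(GeonarrativeError):
    """A keyword pattern is empty after stripping its wildcard."""


class NotFoundError(GeonarrativeError):
    """The requested word does not belong to the given narrative/transcript."""


class EmptyInputError(GeonarrativeError):
    """An operation requiring at least one point received none."""


class GeometryError(GeonarrativeError):
    """Grid or extent geometry is incompatible (disjoint, too large, ...)."""
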