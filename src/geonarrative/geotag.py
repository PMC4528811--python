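"""Join interpolated words to GPS coordinates via a clock calibration.

The recorder's media clock and the GPS clock are synchronized with a
single "key sound" heard on both devices: matching that sound's media
timestamp to its GMT gives a scalar offset, ``GMT = media_time +
offset_s``. Rides last well under the span over which consumer-device
clock drift would approach the 1 s GPS sample spacing, so no drift model
is used.

Words whose GMT falls before the first GPS fix, after the last valid
sample, or inside a long mid-ride dropout are *dropped and tallied*, never
clamped to the track endpoints — clamping would pile spurious points at
the ends of the route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoMappedWordError, NoOverlapError
from .gps import GpsTrack, TrackQuality, track_quality
from .transcript import InterpolatedWord, TimedTranscript

__all__ = [
    "ClockCalibration",
    "GeotaggedWord",
    "Geonarrative",
    "CommentAnchor",
    "calibrate",
    "geotag_words",
    "anchor_comment",
]


@dataclass(frozen=True)
class ClockCalibration:
    """Scalar media→GMT offset: ``GMT = media_time + offset_s``."""

    offset_s: float

    def to_gmt(self, media_time: float) -> float:
        return media_time + self.offset_s

    def to_media(self, gmt: float) -> float:
        return gmt - self.offset_s


@dataclass
class GeotaggedWord:
    """A spoken word with its interpolated GMT and coordinate."""

    id: int
    media_time: float
    word: str
    word_norm: str
    speaker: str | None
    row_index: int
    gmt: float
    lat: float
    lon: float
    ride_id: str = ""
    group: str = ""


@dataclass
class Geonarrative:
    """The geotagged word cloud of one ride.

    ``dropped`` tallies unmapped words by reason (``before_fix``,
    ``after_track``, ``gap``); retained words plus the tally always equal
    the interpolated-word total, so nothing vanishes silently.
    """

    ride_id: str
    group: str = ""
    subject_speaker: str | None = None
    words: list[GeotaggedWord] = field(default_factory=list)
    dropped: dict[str, int] = field(default_factory=dict)
    quality: TrackQuality | None = None

    def __len__(self) -> int:
        return len(self.words)

    @property
    def dropped_total(self) -> int:
        return sum(self.dropped.values())


@dataclass
class CommentAnchor:
    """A multi-word excerpt pinned to a single coordinate.

    Used to archive significant commentary (e.g. the history of one
    building) as one pin: the coordinate of the excerpt's first mapped
    word becomes the anchor, unless manually overridden onto the feature
    being described.
    """

    ride_id: str
    row_range: tuple[int, int]
    anchor: tuple[float, float]
    text: str
    overridden: bool = False


def calibrate(media_t_key: float, gmt_key: float) -> ClockCalibration:
    """Build the clock calibration from one matched key sound.

    ``media_t_key`` is the sound's media timestamp, ``gmt_key`` the GMT at
    which the GPS-clocked video heard it. The offset may be negative.
    """
    return ClockCalibration(offset_s=gmt_key - media_t_key)


def geotag_words(
    words: list[InterpolatedWord],
    track: GpsTrack,
    cal: ClockCalibration,
    ride_id: str = "",
    group: str = "",
    subject_speaker: str | None = None,
    max_gap_s: float = 30.0,
) -> Geonarrative:
    """Assign a coordinate to every word that falls on the valid track.

    Each word's GMT is interpolated linearly between its bracketing valid
    GPS samples. Words are dropped (and tallied) when their GMT precedes
    the first fix (``before_fix``), follows the last valid sample
    (``after_track``), or falls in a mid-ride GPS dropout longer than
    ``max_gap_s`` seconds (``gap``). Raises :class:`NoOverlapError` when
    nothing maps — the signature of a calibration mistake.
    """
    gmt_arr, lat_arr, lon_arr = track.valid_arrays()
    if gmt_arr.size == 0:
        raise NoOverlapError("track has no valid samples to geotag against")
    dropped = {"before_fix": 0, "after_track": 0, "gap": 0}
    tagged: list[GeotaggedWord] = []
    for w in words:
        gmt = cal.to_gmt(w.media_time)
        if gmt < gmt_arr[0]:
            dropped["before_fix"] += 1
            continue
        if gmt > gmt_arr[-1]:
            dropped["after_track"] += 1
            continue
        # Bracketing valid samples; exact hits bracket themselves.
        j = int(np.searchsorted(gmt_arr, gmt, side="right"))
        lo, hi = max(j - 1, 0), min(j, gmt_arr.size - 1)
        if gmt_arr[hi] - gmt_arr[lo] > max_gap_s:
            dropped["gap"] += 1
            continue
        lat = float(np.interp(gmt, gmt_arr, lat_arr))
        lon = float(np.interp(gmt, gmt_arr, lon_arr))
        tagged.append(
            GeotaggedWord(
                id=w.id,
                media_time=w.media_time,
                word=w.word,
                word_norm=w.word_norm,
                speaker=w.speaker,
                row_index=w.row_index,
                gmt=gmt,
                lat=lat,
                lon=lon,
                ride_id=ride_id,
                group=group,
            )
        )
    if words and not tagged:
        raise NoOverlapError(
            "no word falls inside the track's valid span — check the clock "
            "calibration (key-sound match)"
        )
    dropped = {k: v for k, v in dropped.items() if v}
    return Geonarrative(
        ride_id=ride_id,
        group=group,
        subject_speaker=subject_speaker,
        words=tagged,
        dropped=dropped,
        quality=track_quality(track),
    )


def anchor_comment(
    n: Geonarrative,
    t: TimedTranscript,
    row_range: tuple[int, int],
    override: tuple[float, float] | None = None,
) -> CommentAnchor:
    """Pin a contiguous transcript excerpt to a single coordinate.

    The anchor is the coordinate of the excerpt's first mapped word;
    ``override`` replaces it (e.g. snapping the pin onto the building the
    comment describes) and sets the ``overridden`` flag.
    """
    start, end = row_range
    if not (0 <= start <= end < len(t.rows)):
        raise IndexError(f"row range {row_range} outside transcript of {len(t.rows)} rows")
    text = " ".join(r.text for r in t.rows[start : end + 1] if r.text).strip()
    first_word = next(
        (w for w in n.words if start <= w.row_index <= end), None
    )
    if first_word is None:
        raise NoMappedWordError(
            f"all words of rows {start}..{end} were dropped; nothing to anchor"
        )
    if override is not None:
        return CommentAnchor(
            ride_id=n.ride_id,
            row_range=(start, end),
            anchor=override,
            text=text,
            overridden=True,
        )
    return CommentAnchor(
        ride_id=n.ride_id,
        row_range=(start, end),
        anchor=(first_word.lat, first_word.lon),
        text=text,
        overridden=False,
    )
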