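"""Keyword, speaker and spatial queries over geotagged word layers.

Queries operate on the normalised word form (lower-cased, edge
punctuation stripped); the display form is kept for labelling. The only
pattern syntax is a trailing ``*`` prefix wildcard (``drug*`` matches
drug, drugs, drugged, ...) — deliberately simpler than regular
expressions so that every query is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyPatternError, NotFoundError
from .geotag import Geonarrative, GeotaggedWord
from .transcript import TimedTranscript, TranscriptRow

__all__ = [
    "KeywordPattern",
    "QueryFilter",
    "FrequencyTable",
    "ContextExcerpt",
    "match_words",
    "word_frequencies",
    "context_at",
    "words_near",
    "haversine_m",
    "EARTH_RADIUS_M",
]

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius


@dataclass(frozen=True)
class KeywordPattern:
    """A keyword query: exact word or prefix wildcard (trailing ``*``)."""

    pattern: str
    case_fold: bool = True

    @property
    def is_prefix(self) -> bool:
        return self.pattern.endswith("*")

    @property
    def stem(self) -> str:
        s = self.pattern[:-1] if self.is_prefix else self.pattern
        s = s.strip()
        if not s:
            raise EmptyPatternError("keyword pattern is empty after stripping '*'")
        return s.lower() if self.case_fold else s

    def matches(self, word_norm: str) -> bool:
        # word_norm is already lower-cased at tokenization; with case_fold
        # the stem is lowered too, otherwise it is compared as given.
        stem = self.stem
        return word_norm.startswith(stem) if self.is_prefix else word_norm == stem


@dataclass(frozen=True)
class QueryFilter:
    """Optional allow-lists restricting a query; empty means unrestricted.

    ``subject_only(narrative)`` builds the common "only the subject's own
    words" preset from a narrative's recorded subject speaker.
    """

    speakers: frozenset[str] | None = None
    groups: frozenset[str] | None = None
    rides: frozenset[str] | None = None

    @staticmethod
    def subject_only(n: Geonarrative) -> "QueryFilter":
        if n.subject_speaker is None:
            return QueryFilter()
        return QueryFilter(speakers=frozenset({n.subject_speaker}))

    def admits(self, w: GeotaggedWord, n: Geonarrative) -> bool:
        if self.speakers is not None and (w.speaker not in self.speakers):
            return False
        if self.groups is not None and n.group not in self.groups:
            return False
        if self.rides is not None and n.ride_id not in self.rides:
            return False
        return True


@dataclass
class FrequencyTable:
    """Word counts, optionally split by narrator group.

    ``rows`` are (word_norm, group, count) tuples sorted by count
    descending then word ascending — the input for a word cloud.
    """

    rows: list[tuple[str, str, int]]
    stopwords_removed: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["word_norm", "group", "count"])

    def counts(self, group: str | None = None) -> dict[str, int]:
        return {
            w: c for w, g, c in self.rows if group is None or g == group
        }


@dataclass
class ContextExcerpt:
    """Transcript rows surrounding one mapped point, for re-reading.

    Every mapped word keeps its media timestamp, so from any point on the
    map one can return to the original transcription and read what was
    being said around that moment.
    """

    ride_id: str
    rows: list[tuple[int, TranscriptRow]]
    focus_time: float

    @property
    def text(self) -> str:
        return " ".join(r.text for _, r in self.rows if r.text)


def _as_list(narratives: Geonarrative | list[Geonarrative]) -> list[Geonarrative]:
    return [narratives] if isinstance(narratives, Geonarrative) else list(narratives)


def match_words(
    narratives: Geonarrative | list[Geonarrative],
    pattern: KeywordPattern | str,
    qfilter: QueryFilter | None = None,
) -> list[GeotaggedWord]:
    """All geotagged words matching a keyword pattern and filters.

    Order is preserved within each ride; rides are concatenated in input
    order.
    """
    if isinstance(pattern, str):
        pattern = KeywordPattern(pattern)
    pattern.stem  # validate eagerly
    qfilter = qfilter or QueryFilter()
    out: list[GeotaggedWord] = []
    for n in _as_list(narratives):
        for w in n.words:
            if pattern.matches(w.word_norm) and qfilter.admits(w, n):
                out.append(w)
    return out


def word_frequencies(
    narratives: Geonarrative | list[Geonarrative],
    stopwords: list[str] | set[str] | None = None,
    by_group: bool = True,
    qfilter: QueryFilter | None = None,
) -> FrequencyTable:
    """Word-frequency table over one or more narratives.

    With ``by_group`` the counts split by each narrative's group label
    (e.g. police vs community), which is how per-group word clouds are
    built. ``stopwords`` (normalised forms) are excluded when given.
    Ordering is deterministic: count descending, then word, then group.
    """
    stop = {s.lower() for s in stopwords} if stopwords else set()
    qfilter = qfilter or QueryFilter()
    counts: dict[tuple[str, str], int] = {}
    for n in _as_list(narratives):
        g = n.group if by_group else ""
        for w in n.words:
            if w.word_norm in stop or not qfilter.admits(w, n):
                continue
            counts[(w.word_norm, g)] = counts.get((w.word_norm, g), 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    return FrequencyTable(
        rows=[(w, g, c) for (w, g), c in rows],
        stopwords_removed=bool(stop),
    )


def context_at(
    narrative: Geonarrative,
    transcript: TimedTranscript,
    word_or_time: GeotaggedWord | float,
    window_rows: int = 1,
) -> ContextExcerpt:
    """Return the transcript rows around a mapped word (or media time).

    The excerpt is the containing row plus ``window_rows`` rows either
    side, clipped at the transcript boundaries.
    """
    if window_rows < 0:
        raise ValueError("window_rows must be >= 0")
    if isinstance(word_or_time, GeotaggedWord):
        w = word_or_time
        if w.ride_id != narrative.ride_id or not any(
            x.id == w.id and x.row_index == w.row_index for x in narrative.words
        ):
            raise NotFoundError(
                f"word id {w.id} does not belong to ride {narrative.ride_id!r}"
            )
        row_idx, focus = w.row_index, w.media_time
    else:
        focus = float(word_or_time)
        stamps = transcript.stamps
        if not stamps or focus < stamps[0]:
            raise NotFoundError(f"media time {focus} precedes the transcript")
        row_idx = int(np.searchsorted(stamps, focus, side="right")) - 1
    if row_idx >= len(transcript.rows):
        raise NotFoundError(f"row {row_idx} outside transcript")
    lo = max(0, row_idx - window_rows)
    hi = min(len(transcript.rows) - 1, row_idx + window_rows)
    return ContextExcerpt(
        ride_id=narrative.ride_id,
        rows=[(i, transcript.rows[i]) for i in range(lo, hi + 1)],
        focus_time=focus,
    )


def haversine_m(
    lat1: float | np.ndarray,
    lon1: float | np.ndarray,
    lat2: float | np.ndarray,
    lon2: float | np.ndarray,
) -> float | np.ndarray:
    """Great-circle distance in metres (haversine, spherical Earth)."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((p2 - p1) / 2.0) ** 2
        + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    )
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(a))


def words_near(
    narratives: Geonarrative | list[Geonarrative],
    center: tuple[float, float],
    radius_m: float,
    qfilter: QueryFilter | None = None,
) -> dict[str, list[GeotaggedWord]]:
    """All words within ``radius_m`` metres of ``center``, grouped by ride.

    This is the "go to a street segment and read what was said there"
    query: the result maps ride_id → that ride's words inside the radius,
    in spoken order.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    qfilter = qfilter or QueryFilter()
    clat, clon = center
    out: dict[str, list[GeotaggedWord]] = {}
    for n in _as_list(narratives):
        if not n.words:
            continue
        lats = np.array([w.lat for w in n.words])
        lons = np.array([w.lon for w in n.words])
        d = haversine_m(lats, lons, clat, clon)
        hits = [
            w
            for w, di in zip(n.words, np.atleast_1d(d))
            if di <= radius_m and qfilter.admits(w, n)
        ]
        if hits:
            out[n.ride_id] = hits
    return out
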