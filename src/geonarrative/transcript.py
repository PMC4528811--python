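"""Parse, validate and word-interpolate timestamped transcripts.

A geonarrative transcript is plain UTF-8 text in which every substantive
comment starts on a new row prefixed by an ``HH:MM:SS`` media timestamp —
seconds elapsed on the recorder clock, written either bare or in
parentheses — optionally followed by a bracketed speaker tag::

    (00:20:18)[HW] Sun

Stamps must be strictly increasing: a duplicated or reversed stamp stops
processing and the error identifies the offending time so the transcriber
can repair the source file (when two people speak in quick succession, a
second must be added or subtracted to give separation).

Words between consecutive stamps are interpolated evenly across the
seconds separating them, so that every spoken word receives its own media
time and can later be joined to a GPS coordinate.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field

from .errors import (
    DuplicateStampError,
    MalformedStampError,
    NonSequentialStampError,
)

__all__ = [
    "TimeStampMedia",
    "TranscriptRow",
    "TimedTranscript",
    "InterpolatedWord",
    "parse_stamp",
    "format_stamp",
    "tokenize",
    "parse_transcript",
    "interpolate_words",
    "words_to_csv",
]

# A stamp is exactly three colon-separated integer fields; minutes and
# seconds are two digits below 60, hours are unbounded (media time is
# recording-relative, so rides longer than 24 h do not wrap).
_STAMP_RE = re.compile(r"(\d{1,4}):([0-5]\d):([0-5]\d)")
_PAREN_LINE_RE = re.compile(r"^\((?P<stamp>[^)]*)\)")
_BARE_LINE_RE = re.compile(r"^(?P<stamp>\d{1,4}:\d{2}:\d{2})(?=[\s\[]|$)")
_SPEAKER_RE = re.compile(r"^\[(?P<tag>[^\]\s]{1,16})\]")

# Curly quote forms normalised so "don’t" and "don't" share one word_norm.
_APOSTROPHES = str.maketrans({"’": "'", "‘": "'"})
# Punctuation stripped from token edges; internal apostrophes and hyphens
# survive so contractions and compounds stay single words.
_EDGE_PUNCT = ".,;:!?\"'()[]{}<>…—–-*/\\`~“”‘’"


@dataclass(frozen=True)
class TimeStampMedia:
    """A media timestamp: seconds since the start of the recording."""

    seconds: float

    def __post_init__(self) -> None:
        if self.seconds < 0:
            raise ValueError("media time must be non-negative")

    def __str__(self) -> str:
        return format_stamp(self.seconds)


@dataclass
class TranscriptRow:
    """One timestamped row: stamp, optional speaker tag, free text."""

    stamp: TimeStampMedia
    speaker: str | None
    text: str


@dataclass
class TimedTranscript:
    """A validated transcript: rows with strictly increasing stamps."""

    rows: list[TranscriptRow] = field(default_factory=list)
    source_name: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def speakers(self) -> set[str]:
        return {r.speaker for r in self.rows if r.speaker is not None}

    @property
    def stamps(self) -> list[float]:
        return [r.stamp.seconds for r in self.rows]


@dataclass
class InterpolatedWord:
    """A single spoken token with its interpolated media time.

    ``id`` is the 1-based position in the ride's word sequence — the first
    column of the classic three-column (ID, time, word) output. ``word``
    keeps the display form as transcribed; ``word_norm`` is the lower-cased,
    edge-punctuation-stripped form used for matching and counting.
    """

    id: int
    media_time: float
    word: str
    word_norm: str
    speaker: str | None
    row_index: int


def parse_stamp(text: str) -> float:
    """Parse ``HH:MM:SS`` (three colon-separated integers) to seconds.

    Raises :class:`MalformedStampError` on anything else.
    """
    m = _STAMP_RE.fullmatch(text.strip())
    if m is None:
        raise MalformedStampError(
            f"timestamp {text!r} does not parse as HH:MM:SS", stamp=text.strip()
        )
    h, mi, s = (int(g) for g in m.groups())
    return float(h * 3600 + mi * 60 + s)


def format_stamp(seconds: float) -> str:
    """Format whole seconds back to ``HH:MM:SS``."""
    t = int(round(seconds))
    return f"{t // 3600:02d}:{t % 3600 // 60:02d}:{t % 60:02d}"


def tokenize(text: str) -> list[tuple[str, str]]:
    """Split row text into (display, normalised) word pairs.

    Splits on whitespace, strips punctuation from token edges, keeps
    internal apostrophes/hyphens, and drops tokens that are punctuation
    only (e.g. a bare ellipsis).
    """
    out: list[tuple[str, str]] = []
    for raw in text.split():
        display = raw.strip(_EDGE_PUNCT)
        if not display:
            continue
        norm = display.translate(_APOSTROPHES).lower()
        out.append((display, norm))
    return out


def _parse_header(line: str) -> tuple[float, str, str, str] | None:
    """Try to read a stamp (and optional speaker) off the start of a line.

    Returns ``(seconds, stamp_text, speaker, rest)`` or ``None`` when the
    line does not begin with a stamp (a continuation line). A line that
    *opens a parenthesis* but whose contents do not parse is an error, per
    the stop-and-identify validation contract.
    """
    if line.startswith("("):
        # An opening parenthesis announces a stamp; failing to parse one is
        # a transcription error, not a continuation line.
        m = _PAREN_LINE_RE.match(line)
        if m is None:
            raise MalformedStampError(
                f"line opens a parenthesis but carries no closed (HH:MM:SS) "
                f"stamp: {line!r}"
            )
        seconds = parse_stamp(m.group("stamp"))  # raises MalformedStampError
        stamp_text = m.group("stamp").strip()
        rest = line[m.end():]
    else:
        m = _BARE_LINE_RE.match(line)
        if m is None:
            return None
        stamp_text = m.group("stamp")
        seconds = parse_stamp(stamp_text)
        rest = line[m.end():]
    rest = rest.lstrip()
    speaker = ""
    sm = _SPEAKER_RE.match(rest)
    if sm is not None:
        speaker = sm.group("tag")
        rest = rest[sm.end():].lstrip()
    return seconds, stamp_text, speaker, rest


def parse_transcript(raw: str, source_name: str = "") -> TimedTranscript:
    """Parse raw transcript text into a validated :class:`TimedTranscript`.

    Lines beginning with a stamp start a new row; other non-empty lines are
    continuations appended to the preceding row's text. Validation stops at
    the first duplicated or non-sequential stamp and reports that time.
    """
    rows: list[TranscriptRow] = []
    for line in raw.splitlines():
        line = line.strip()
        if not line:
            continue
        header = _parse_header(line)
        if header is None:
            if rows:
                rows[-1].text = (rows[-1].text + " " + line).strip()
            else:
                raise MalformedStampError(
                    f"transcript begins with an unstamped line: {line!r}"
                )
            continue
        seconds, stamp_text, speaker, rest = header
        if rows:
            prev = rows[-1].stamp.seconds
            if seconds == prev:
                raise DuplicateStampError(
                    f"duplicate timestamp {format_stamp(seconds)}: duplicates are "
                    "not allowed — a second must be added or subtracted to give "
                    "separation between comments made in quick succession",
                    stamp=format_stamp(seconds),
                )
            if seconds < prev:
                raise NonSequentialStampError(
                    f"timestamp {format_stamp(seconds)} is earlier than the "
                    f"preceding stamp {format_stamp(prev)}: stamps must be "
                    "sequential",
                    stamp=format_stamp(seconds),
                )
        rows.append(
            TranscriptRow(
                stamp=TimeStampMedia(seconds),
                speaker=speaker or None,
                text=rest,
            )
        )
    return TimedTranscript(rows=rows, source_name=source_name)


def interpolate_words(t: TimedTranscript) -> list[InterpolatedWord]:
    """Spread every word of every row evenly across its stamp interval.

    For a closed interval ``[t_i, t_{i+1})`` whose row holds ``n`` tokens,
    token ``k`` (0-based) is placed at ``t_i + k * (t_{i+1} - t_i) / n`` —
    the first word of each comment sits exactly on the stamp that opened
    it. Tokens of the final row (no closing stamp) are spaced by the
    ride-wide mean seconds-per-token of the closed intervals, starting at
    the final stamp; if no closed interval carried a token, they all sit on
    the final stamp.
    """
    words: list[InterpolatedWord] = []
    n_rows = len(t.rows)
    # Ride-wide token rate from token-bearing closed intervals only.
    closed_seconds = 0.0
    closed_tokens = 0
    tokens_per_row = [tokenize(r.text) for r in t.rows]
    for i in range(n_rows - 1):
        n = len(tokens_per_row[i])
        if n:
            closed_seconds += t.rows[i + 1].stamp.seconds - t.rows[i].stamp.seconds
            closed_tokens += n
    mean_spt = closed_seconds / closed_tokens if closed_tokens else 0.0

    next_id = 1
    for i, row in enumerate(t.rows):
        toks = tokens_per_row[i]
        if not toks:
            continue
        start = row.stamp.seconds
        if i < n_rows - 1:
            step = (t.rows[i + 1].stamp.seconds - start) / len(toks)
        else:
            step = mean_spt
        for k, (display, norm) in enumerate(toks):
            words.append(
                InterpolatedWord(
                    id=next_id,
                    media_time=start + k * step,
                    word=display,
                    word_norm=norm,
                    speaker=row.speaker,
                    row_index=i,
                )
            )
            next_id += 1
    return words


def words_to_csv(words: list[InterpolatedWord]) -> str:
    """Serialize interpolated words as CSV.

    The first three columns are the classic (ID, time, word) output; the
    remaining columns carry provenance for downstream filtering.
    """
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["id", "media_time", "word", "word_norm", "speaker", "row_index"])
    for word in words:
        w.writerow(
            [
                word.id,
                repr(word.media_time),
                word.word,
                word.word_norm,
                word.speaker or "",
                word.row_index,
            ]
        )
    return buf.getvalue()
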