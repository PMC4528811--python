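"""GPS track ingestion: GPX and GMT-stamped CSV, quality metrics, filenames.

Camera-mounted GPS units export one track per camera per ride, either as
GPX 1.1 or as a CSV of coordinates with their Greenwich Mean Time. The
first seconds of a ride often precede satellite lock ("first fix"), so
tracks distinguish valid from invalid samples rather than discarding the
warm-up rows — the pre-fix period matters when calibrating the media clock.

All times are stored as epoch seconds UTC; parsing converts immediately.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyTrackError, FormatError, NoFixError, OutOfRangeError

__all__ = [
    "GpsSample",
    "GpsTrack",
    "TrackQuality",
    "VideoFileMeta",
    "parse_gpx",
    "write_gpx",
    "parse_position_csv",
    "write_position_csv",
    "first_fix",
    "last_fix",
    "position_at",
    "track_quality",
    "select_best",
    "parse_video_filename",
]

logger = logging.getLogger(__name__)

_GPX_NS = "http://www.topografix.com/GPX/1/1"


@dataclass(frozen=True)
class GpsSample:
    """One GPS reading: epoch-seconds UTC, WGS84 degrees, fix flag."""

    gmt: float
    lat: float
    lon: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"coordinates out of range: ({self.lat}, {self.lon})")


@dataclass
class GpsTrack:
    """Time-ordered GPS samples from one camera."""

    samples: list[GpsSample]
    camera_label: str = ""

    def __len__(self) -> int:
        return len(self.samples)

    def valid_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(gmt, lat, lon) arrays of the valid samples only."""
        vs = [s for s in self.samples if s.valid]
        return (
            np.array([s.gmt for s in vs], dtype=float),
            np.array([s.lat for s in vs], dtype=float),
            np.array([s.lon for s in vs], dtype=float),
        )


@dataclass
class TrackQuality:
    """Per-camera track performance summary for the ride metadata sheet."""

    duration_s: float
    valid_fraction: float
    max_gap_s: float
    sample_count: int


@dataclass(frozen=True)
class VideoFileMeta:
    """Metadata encoded in a ride video file name.

    Names follow SITE + MMDDYY + SIDE + optional qualifier + "NofM", e.g.
    ``LA031015RA1of4``: Los Angeles, 2015-03-10, right-side camera,
    segment 1 of 4.
    """

    site: str
    date: _dt.date
    side: str
    qualifier: str
    segment: int
    total_segments: int


def _parse_iso_time(text: str) -> float:
    t = text.strip()
    if t.endswith("Z"):
        t = t[:-1] + "+00:00"
    dt = _dt.datetime.fromisoformat(t)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=_dt.timezone.utc)
    return dt.timestamp()


def parse_gpx(source: str | Path) -> GpsTrack:
    """Read a GPX 1.1 document (path or XML string) into a :class:`GpsTrack`.

    Track points must carry ``<time>`` elements; points are re-sorted by
    time (with a warning) if the file is out of order. All GPX points are
    marked valid — the exporter only writes fixed positions.
    """
    text = source
    if isinstance(source, Path) or (
        isinstance(source, str) and "<" not in source
    ):
        text = Path(source).read_text(encoding="utf-8")
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise FormatError(f"not well-formed GPX: {exc}") from exc
    pts = root.findall(f".//{{{_GPX_NS}}}trkpt") or root.findall(".//trkpt")
    if not pts:
        raise EmptyTrackError("GPX document contains no track points")
    samples = []
    for pt in pts:
        time_el = pt.find(f"{{{_GPX_NS}}}time")
        if time_el is None:
            time_el = pt.find("time")
        if time_el is None or not (time_el.text or "").strip():
            raise FormatError("GPX track point is missing its <time> element")
        samples.append(
            GpsSample(
                gmt=_parse_iso_time(time_el.text),
                lat=float(pt.get("lat")),
                lon=float(pt.get("lon")),
                valid=True,
            )
        )
    times = [s.gmt for s in samples]
    if any(b < a for a, b in zip(times, times[1:])):
        logger.warning("GPX track points out of time order; re-sorting")
        samples.sort(key=lambda s: s.gmt)
    return GpsTrack(samples=samples)


def write_gpx(track: GpsTrack, path: str | Path | None = None) -> str:
    """Serialize a track as GPX 1.1; returns the XML text."""
    gpx = ET.Element(
        "gpx",
        {
            "version": "1.1",
            "creator": "geonarrative",
            "xmlns": _GPX_NS,
        },
    )
    seg = ET.SubElement(ET.SubElement(gpx, "trk"), "trkseg")
    for s in track.samples:
        if not s.valid:
            continue
        pt = ET.SubElement(
            seg, "trkpt", {"lat": f"{s.lat:.7f}", "lon": f"{s.lon:.7f}"}
        )
        stamp = _dt.datetime.fromtimestamp(s.gmt, tz=_dt.timezone.utc)
        ET.SubElement(pt, "time").text = stamp.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"
    ET.indent(gpx)
    text = ET.tostring(gpx, encoding="unicode", xml_declaration=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# Default header-name candidates for the camera vendor's CSV export.
_TIME_CANDIDATES = ("gmt", "gmt time", "utc", "utc time", "time", "timestamp")
_LAT_CANDIDATES = ("latitude", "lat")
_LON_CANDIDATES = ("longitude", "lon", "lng", "long")


def _find_column(columns: list[str], candidates: tuple[str, ...]) -> str | None:
    lowered = {c.strip().lower(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def parse_position_csv(
    source: str | Path,
    column_map: dict[str, str] | None = None,
    camera_label: str = "",
) -> GpsTrack:
    """Read a GMT/latitude/longitude CSV export into a :class:`GpsTrack`.

    Columns are identified by header name (case-insensitive, configurable
    via ``column_map`` with keys ``time``/``lat``/``lon``). Rows whose
    coordinates are blank, NaN or the (0, 0) no-fix sentinel are retained
    as invalid samples: they record the pre-fix warm-up period.

    Times may be epoch seconds or ISO-8601 strings (assumed UTC).
    """
    df = pd.read_csv(source, skipinitialspace=True)
    cols = list(df.columns)
    mapping = {
        "time": _find_column(cols, _TIME_CANDIDATES),
        "lat": _find_column(cols, _LAT_CANDIDATES),
        "lon": _find_column(cols, _LON_CANDIDATES),
    }
    if column_map:
        for key, name in column_map.items():
            mapping[key] = name
    missing = [k for k, v in mapping.items() if v is None or v not in df.columns]
    if missing:
        raise FormatError(
            f"cannot identify required column(s) {missing} among {cols}"
        )
    tcol = df[mapping["time"]]
    times = pd.to_numeric(tcol, errors="coerce")
    if times.isna().any():
        times = (
            pd.to_datetime(tcol, utc=True, format="mixed").astype("int64") / 1e9
        )
    lat = pd.to_numeric(df[mapping["lat"]], errors="coerce")
    lon = pd.to_numeric(df[mapping["lon"]], errors="coerce")
    samples = []
    for t, la, lo in zip(times, lat, lon):
        no_fix = (
            pd.isna(la)
            or pd.isna(lo)
            or (la == 0.0 and lo == 0.0)
            or not (-90.0 <= la <= 90.0 and -180.0 <= lo <= 180.0)
        )
        if no_fix:
            samples.append(GpsSample(gmt=float(t), lat=0.0, lon=0.0, valid=False))
        else:
            samples.append(GpsSample(gmt=float(t), lat=float(la), lon=float(lo)))
    samples.sort(key=lambda s: s.gmt)
    return GpsTrack(samples=samples, camera_label=camera_label)


def write_position_csv(track: GpsTrack, path: str | Path | None = None) -> str:
    """Serialize a track as a GMT/Latitude/Longitude CSV; returns the text."""
    rows = []
    for s in track.samples:
        rows.append(
            {
                "GMT": repr(s.gmt),
                "Latitude": "" if not s.valid else repr(s.lat),
                "Longitude": "" if not s.valid else repr(s.lon),
            }
        )
    df = pd.DataFrame(rows, columns=["GMT", "Latitude", "Longitude"])
    text = df.to_csv(index=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def first_fix(track: GpsTrack) -> float:
    """GMT of the earliest valid sample — the moment satellite lock begins.

    May be later than the start of the recording's media time; words spoken
    before it cannot be geotagged.
    """
    for s in track.samples:
        if s.valid:
            return s.gmt
    raise NoFixError("track contains no valid GPS fix")


def last_fix(track: GpsTrack) -> float:
    """GMT of the latest valid sample."""
    for s in reversed(track.samples):
        if s.valid:
            return s.gmt
    raise NoFixError("track contains no valid GPS fix")


def position_at(track: GpsTrack, t: float) -> tuple[float, float]:
    """Linearly interpolated (lat, lon) on the track at GMT ``t``.

    Interpolation is linear in degrees between the bracketing valid
    samples; at ~1 s sample spacing of vehicle motion the difference from
    geodesic interpolation is sub-millimetre. Unsuitable for sparse tracks
    crossing the antimeridian.
    """
    gmt, lat, lon = track.valid_arrays()
    if gmt.size == 0:
        raise NoFixError("track contains no valid GPS fix")
    if t < gmt[0] or t > gmt[-1]:
        raise OutOfRangeError(
            f"time {t} outside valid track span [{gmt[0]}, {gmt[-1]}]"
        )
    return float(np.interp(t, gmt, lat)), float(np.interp(t, gmt, lon))


def track_quality(track: GpsTrack) -> TrackQuality:
    """Quality metrics for one camera's track (for comparison/selection)."""
    n = len(track.samples)
    valid_times = [s.gmt for s in track.samples if s.valid]
    duration = (
        track.samples[-1].gmt - track.samples[0].gmt if n >= 2 else 0.0
    )
    gaps = [b - a for a, b in zip(valid_times, valid_times[1:])]
    return TrackQuality(
        duration_s=duration,
        valid_fraction=(len(valid_times) / n) if n else 0.0,
        max_gap_s=max(gaps) if gaps else 0.0,
        sample_count=n,
    )


def select_best(tracks: list[GpsTrack]) -> GpsTrack:
    """Pick the best of several cameras' tracks for geotagging.

    Ordered lexicographically by (valid_fraction, -max_gap_s, duration_s);
    ties keep the earliest-listed track, so the choice is stable.
    """
    if not tracks:
        raise EmptyTrackError("no tracks to select from")

    def key(track: GpsTrack) -> tuple[float, float, float]:
        q = track_quality(track)
        return (q.valid_fraction, -q.max_gap_s, q.duration_s)

    return max(tracks, key=key)


_FILENAME_RE = re.compile(
    r"^(?P<site>[A-Za-z]+?)"
    r"(?P<mm>\d{2})(?P<dd>\d{2})(?P<yy>\d{2})"
    r"(?P<side>[LRFB])"
    r"(?P<qual>[A-Za-z]?)"
    r"(?P<seg>\d+)of(?P<tot>\d+)$"
)


def parse_video_filename(name: str) -> VideoFileMeta:
    """Decode a ride video file name into its metadata fields.

    ``LA031015RA1of4`` → site LA, date 2015-03-10, right side, segment 1 of
    4 (the single letter after the side code is a camera qualifier). Side
    codes L/R/F/B (left, right, front, back) are accepted.
    """
    stem = name.rsplit(".", 1)[0]
    m = _FILENAME_RE.match(stem)
    if m is None:
        raise FormatError(f"video file name {name!r} does not match the "
                          "SITE+MMDDYY+SIDE+NofM convention")
    try:
        date = _dt.date(
            2000 + int(m.group("yy")), int(m.group("mm")), int(m.group("dd"))
        )
    except ValueError as exc:
        raise FormatError(f"invalid date in file name {name!r}: {exc}") from exc
    segment, total = int(m.group("seg")), int(m.group("tot"))
    if not 1 <= segment <= total:
        raise FormatError(
            f"segment {segment} outside 1..{total} in file name {name!r}"
        )
    return VideoFileMeta(
        site=m.group("site").upper(),
        date=date,
        side=m.group("side").upper(),
        qualifier=m.group("qual").upper(),
        segment=segment,
        total_segments=total,
    )
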