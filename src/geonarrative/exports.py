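"""Serialization to standard geospatial formats, plus confidentiality masks.

Geotagged word layers export as GeoJSON (RFC 7946) point features and flat
CSV; comment anchors export as KML 2.2 placemarks whose descriptions carry
the excerpt text (the emailable "pin map" archive); density surfaces
export as ESRI ASCII grids with a sidecar recording the projection origin.

Because narrative maps can reveal where a subject lives or who they talk
about, every point export accepts a :class:`MaskPolicy` that displaces
coordinates — snapping to a coarse lattice or seeded Gaussian jitter —
applied as the very last step before writing.
"""

from __future__ import annotations

import csv
import io
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .density import LocalProjection, _GridSurface
from .errors import EmptyInputError
from .geotag import CommentAnchor, Geonarrative, GeotaggedWord
from .gps import GpsTrack, TrackQuality
from .query import haversine_m

__all__ = [
    "MaskPolicy",
    "export_points",
    "read_points_geojson",
    "read_points_csv",
    "export_kml",
    "write_metadata_sheet",
    "export_ascii_grid",
]

KML_NS = "http://www.opengis.net/kml/2.2"


@dataclass(frozen=True)
class MaskPolicy:
    """Coordinate-masking policy for confidential exports.

    ``snap_to_grid`` rounds coordinates to a ``grid_m`` lattice in a local
    metric plane; ``jitter`` adds seeded Gaussian noise of ``jitter_sd_m``
    standard deviation. Either way a masked output never reproduces an
    original coordinate.
    """

    mode: str = "none"  # none | snap_to_grid | jitter
    grid_m: float = 100.0
    jitter_sd_m: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "snap_to_grid", "jitter"):
            raise ValueError(f"unknown mask mode {self.mode!r}")


def _apply_mask(
    lats: np.ndarray, lons: np.ndarray, policy: MaskPolicy
) -> tuple[np.ndarray, np.ndarray]:
    if policy.mode == "none" or lats.size == 0:
        return lats, lons
    proj = LocalProjection(float(lats.mean()), float(lons.mean()))
    x, y = proj.forward(lats, lons)
    if policy.mode == "snap_to_grid":
        g = policy.grid_m
        sx, sy = np.round(x / g) * g, np.round(y / g) * g
        # A point already on the lattice must still move.
        on_lattice = (sx == x) & (sy == y)
        sx = np.where(on_lattice, sx + g / 2.0, sx)
        x, y = sx, sy
    else:  # jitter
        rng = np.random.default_rng(policy.seed)
        dx = rng.normal(0.0, policy.jitter_sd_m, size=x.shape)
        dy = rng.normal(0.0, policy.jitter_sd_m, size=y.shape)
        zero = (dx == 0.0) & (dy == 0.0)
        dx = np.where(zero, policy.jitter_sd_m, dx)
        x, y = x + dx, y + dy
    return proj.inverse(x, y)


def _as_words(source) -> list[GeotaggedWord]:
    if isinstance(source, Geonarrative):
        return list(source.words)
    return list(source)


_PROPS = ("id", "word", "word_norm", "speaker", "gmt", "media_time",
          "ride_id", "group", "row_index")


def export_points(
    source: Geonarrative | list[GeotaggedWord],
    path: str | Path | None = None,
    fmt: str = "geojson",
    mask: MaskPolicy | None = None,
) -> str:
    """Write a word layer as GeoJSON point features or flat CSV.

    One feature/row per word with the word as its label property; an
    unmasked export re-imports to identical coordinates (full float
    precision is preserved).
    """
    words = _as_words(source)
    if not words:
        raise EmptyInputError("nothing to export")
    lats = np.array([w.lat for w in words])
    lons = np.array([w.lon for w in words])
    if mask is not None:
        lats, lons = _apply_mask(lats, lons, mask)
    if fmt == "geojson":
        features = []
        for w, la, lo in zip(words, lats, lons):
            props = {p: getattr(w, p) for p in _PROPS}
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(lo), float(la)]},
                    "properties": props,
                }
            )
        text = json.dumps(
            {"type": "FeatureCollection", "features": features}, indent=1
        )
    elif fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(list(_PROPS) + ["lat", "lon"])
        for w, la, lo in zip(words, lats, lons):
            writer.writerow(
                [getattr(w, p) if getattr(w, p) is not None else "" for p in _PROPS]
                + [repr(float(la)), repr(float(lo))]
            )
        text = buf.getvalue()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def _word_from_record(rec: dict, lat: float, lon: float) -> GeotaggedWord:
    return GeotaggedWord(
        id=int(rec["id"]),
        media_time=float(rec["media_time"]),
        word=str(rec["word"]),
        word_norm=str(rec["word_norm"]),
        speaker=(str(rec["speaker"]) or None) if rec.get("speaker") not in (None, "") else None,
        row_index=int(rec["row_index"]),
        gmt=float(rec["gmt"]),
        lat=lat,
        lon=lon,
        ride_id=str(rec.get("ride_id", "")),
        group=str(rec.get("group", "")),
    )


def read_points_geojson(source: str | Path) -> list[GeotaggedWord]:
    """Re-import a GeoJSON word layer written by :func:`export_points`."""
    text = source
    if isinstance(source, Path) or (isinstance(source, str) and "{" not in source):
        text = Path(source).read_text(encoding="utf-8")
    doc = json.loads(text)
    out = []
    for feat in doc["features"]:
        lon, lat = feat["geometry"]["coordinates"][:2]
        out.append(_word_from_record(feat["properties"], float(lat), float(lon)))
    return out


def read_points_csv(source: str | Path) -> list[GeotaggedWord]:
    """Re-import a CSV word layer written by :func:`export_points`."""
    text = source
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text(encoding="utf-8")
    reader = csv.DictReader(io.StringIO(text))
    return [
        _word_from_record(rec, float(rec["lat"]), float(rec["lon"]))
        for rec in reader
    ]


def export_kml(
    anchors: list[CommentAnchor],
    path: str | Path | None = None,
    mask: MaskPolicy | None = None,
    document_name: str = "geonarrative anchors",
) -> str:
    """Write comment anchors as a KML 2.2 document of placemarks.

    One placemark per anchor, in order; the description holds the excerpt
    text, so opening the file in a virtual globe shows a pin that reveals
    the relevant commentary for that location.
    """
    if not anchors:
        raise EmptyInputError("no anchors to export")
    lats = np.array([a.anchor[0] for a in anchors])
    lons = np.array([a.anchor[1] for a in anchors])
    if mask is not None:
        lats, lons = _apply_mask(lats, lons, mask)
    ET.register_namespace("", KML_NS)
    kml = ET.Element(f"{{{KML_NS}}}kml")
    doc = ET.SubElement(kml, f"{{{KML_NS}}}Document")
    ET.SubElement(doc, f"{{{KML_NS}}}name").text = document_name
    for a, la, lo in zip(anchors, lats, lons):
        pm = ET.SubElement(doc, f"{{{KML_NS}}}Placemark")
        ET.SubElement(pm, f"{{{KML_NS}}}name").text = (
            f"{a.ride_id} rows {a.row_range[0]}-{a.row_range[1]}"
        )
        ET.SubElement(pm, f"{{{KML_NS}}}description").text = a.text
        point = ET.SubElement(pm, f"{{{KML_NS}}}Point")
        ET.SubElement(point, f"{{{KML_NS}}}coordinates").text = (
            f"{float(lo):.7f},{float(la):.7f},0"
        )
    ET.indent(kml)
    text = ET.tostring(kml, encoding="unicode", xml_declaration=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def _bbox_and_length(track: GpsTrack) -> tuple[tuple[float, float, float, float], float]:
    gmt, lat, lon = track.valid_arrays()
    bbox = (float(lat.min()), float(lon.min()), float(lat.max()), float(lon.max()))
    if lat.size < 2:
        return bbox, 0.0
    seg = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return bbox, float(np.sum(seg)) / 1000.0


def write_metadata_sheet(
    ride_id: str,
    date: str,
    tracks: list[GpsTrack],
    qualities: list[TrackQuality],
    chosen_label: str,
    narrative_summary: str = "",
    processing_log: list[str] | None = None,
    path: str | Path | None = None,
) -> str:
    """Deterministic markdown metadata sheet for one ride.

    Lists every camera's track quality exactly once, the chosen track, a
    route summary (bbox, length, duration) and the processing log. The
    date is injected by the caller, never read from the wall clock, so
    re-running on the same inputs is byte-identical.
    """
    if len(tracks) != len(qualities):
        raise ValueError("tracks and qualities must align")
    chosen = next((t for t in tracks if t.camera_label == chosen_label), tracks[0])
    bbox, length_km = _bbox_and_length(chosen)
    lines = [
        f"# Ride metadata sheet — {ride_id}",
        "",
        f"- date: {date}",
        f"- cameras: {len(tracks)}",
        f"- chosen track: {chosen_label}",
        "",
        "## Route summary",
        "",
        f"- bounding box (S, W, N, E): {bbox[0]:.6f}, {bbox[1]:.6f}, "
        f"{bbox[2]:.6f}, {bbox[3]:.6f}",
        f"- length: {length_km:.2f} km",
        f"- duration: {qualities[tracks.index(chosen)].duration_s:.0f} s",
        "",
        "## Narrative summary",
        "",
        narrative_summary or "(none)",
        "",
        "## Per-camera GPS quality",
        "",
    ]
    for t, q in zip(tracks, qualities):
        lines += [
            f"### camera {t.camera_label or '(unlabelled)'}",
            "",
            f"- samples: {q.sample_count}",
            f"- duration: {q.duration_s:.0f} s",
            f"- valid fraction: {q.valid_fraction:.3f}",
            f"- max gap between fixes: {q.max_gap_s:.1f} s",
            "",
        ]
    lines += ["## Processing log", ""]
    for entry in processing_log or ["(empty)"]:
        lines.append(f"- {entry}")
    lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def export_ascii_grid(
    surface: _GridSurface,
    path: str | Path,
    nodata: float = -9999.0,
) -> None:
    """Write a surface as an ESRI ASCII grid plus a projection sidecar.

    The ``.asc`` carries cell values (masked cells as NODATA, row order
    north→south per the format); the sidecar ``.asc.aux.json`` records the
    projection origin so the grid can be placed back in degrees.
    """
    path = Path(path)
    half = surface.cell_size_m / 2.0
    header = [
        f"ncols {surface.n_cols}",
        f"nrows {surface.n_rows}",
        f"xllcorner {surface.x0 - half:.3f}",
        f"yllcorner {surface.y0 - half:.3f}",
        f"cellsize {surface.cell_size_m:.3f}",
        f"NODATA_value {nodata}",
    ]
    vals = np.where(surface.mask, surface.values, nodata)
    body = "\n".join(
        " ".join(f"{v:.9g}" for v in row) for row in vals[::-1]
    )
    path.write_text("\n".join(header) + "\n" + body + "\n", encoding="utf-8")
    sidecar = {
        "projection": "azimuthal_equidistant",
        "origin_lat": surface.projection.origin_lat,
        "origin_lon": surface.projection.origin_lon,
        "units": "meters",
    }
    Path(str(path) + ".aux.json").write_text(
        json.dumps(sidecar, indent=1), encoding="utf-8"
    )
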