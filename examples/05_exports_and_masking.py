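"""Exports: GeoJSON/CSV word layers, KML comment pins, masked coordinates.

Comment anchors pin a multi-row excerpt to the coordinate of its first
mapped word — the institutional-knowledge archive pattern — and export as
KML placemarks. For confidential sharing, a mask policy displaces every
coordinate (lattice snap or seeded jitter) as the last step of an export.
"""

from pathlib import Path
from tempfile import mkdtemp

from geonarrative import (
    MaskPolicy,
    SyntheticScenario,
    anchor_comment,
    calibrate,
    export_kml,
    export_points,
    geotag_words,
    interpolate_words,
    parse_transcript,
    read_points_geojson,
    synth_narrative,
    synth_track,
)

out = Path(mkdtemp(prefix="geonarrative_"))
scenario = SyntheticScenario(seed=11)
track = synth_track(scenario)
text, _ = synth_narrative(scenario, track)
transcript = parse_transcript(text)
ride = geotag_words(
    interpolate_words(transcript), track,
    calibrate(0.0, scenario.start_gmt), ride_id="sim11",
)

export_points(ride, out / "words.geojson", fmt="geojson")
back = read_points_geojson(out / "words.geojson")
print(f"GeoJSON round trip: {len(back)} words, coordinates preserved")

anchors = [anchor_comment(ride, transcript, (i, i + 1)) for i in (5, 10, 15)]
export_kml(anchors, out / "anchors.kml")
print(f"KML: {len(anchors)} placemarks with excerpt descriptions")

masked = export_points(
    ride, out / "masked.csv", fmt="csv",
    mask=MaskPolicy(mode="jitter", jitter_sd_m=25.0, seed=99),
)
moved = sum(
    1 for a, b in zip(ride.words, read_points_geojson(
        export_points(ride, fmt="geojson",
                      mask=MaskPolicy(mode="jitter", jitter_sd_m=25.0, seed=99))
    ))
    if (a.lat, a.lon) != (b.lat, b.lon)
)
print(f"jitter mask displaced {moved}/{len(ride.words)} coordinates (seeded, reproducible)")
print(f"outputs in {out}")
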