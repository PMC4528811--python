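"""Relative-frequency surface and hotspot recovery on a planted cluster.

The keyword's kernel density alone mostly shows where talk is dense; the
dual-KDE ratio (keyword as numerator, all words as denominator) shows
where the topic is over-represented. On a synthetic ride with a planted
50 m keyword cluster, the ratio peak lands within metres of the truth.
"""

from geonarrative import (
    SyntheticScenario,
    calibrate,
    geotag_words,
    haversine_m,
    hotspot_peaks,
    interpolate_words,
    kde,
    match_words,
    parse_transcript,
    ratio_surface,
    synth_narrative,
    synth_track,
)

scenario = SyntheticScenario(seed=3)
track = synth_track(scenario)
text, truth = synth_narrative(scenario, track)
ride = geotag_words(
    interpolate_words(parse_transcript(text)), track,
    calibrate(0.0, scenario.start_gmt),
)

kw = match_words(ride, scenario.keyword)
density = kde(kw, bandwidth_m=50.0)
print(f"KDE of {len(kw)} keyword points integrates to {density.integral():.3f}")

surface = ratio_surface(kw, ride.words, bandwidth_m=50.0)
(lat, lon, value), = hotspot_peaks(surface, k=1)
clat, clon, radius, mult = scenario.clusters[0]
err = float(haversine_m(lat, lon, clat, clon))
print(f"ratio peak {value:.3f} at ({lat:.6f}, {lon:.6f})")
print(f"planted cluster centre ({clat:.6f}, {clon:.6f}); error {err:.1f} m")

# The peak value approximates the keyword share of talk inside the
# cluster; the localization error is well inside one 50 m bandwidth.
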