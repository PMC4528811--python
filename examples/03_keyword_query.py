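"""Query the word map: keyword patterns, context, and radius search.

A 'drug*' style prefix query returns the mapped locations of every
matching word; from any hit one can return to the transcript rows around
that moment, or ask what else was said within a radius of a place.
"""

from geonarrative import (
    SyntheticScenario,
    calibrate,
    context_at,
    geotag_words,
    interpolate_words,
    match_words,
    parse_transcript,
    synth_narrative,
    synth_track,
    word_frequencies,
    words_near,
    STOPWORDS,
)

scenario = SyntheticScenario(seed=7)
track = synth_track(scenario)
text, truth = synth_narrative(scenario, track)
transcript = parse_transcript(text)
ride = geotag_words(
    interpolate_words(transcript), track,
    calibrate(0.0, scenario.start_gmt), ride_id="sim7", group="community",
)

hits = match_words(ride, scenario.keyword + "*")
print(f"'{scenario.keyword}*' matches: {len(hits)}")
first = hits[0]
print(f"first mention at ({first.lat:.6f}, {first.lon:.6f}), media {first.media_time:.1f} s")

excerpt = context_at(ride, transcript, first, window_rows=1)
print(f"context rows {excerpt.rows[0][0]}–{excerpt.rows[-1][0]}: {excerpt.text[:70]}...")

nearby = words_near(ride, (first.lat, first.lon), radius_m=100.0)
print(f"words within 100 m of that mention: {sum(len(v) for v in nearby.values())}")

table = word_frequencies(ride, stopwords=STOPWORDS)
print("top words after stopword removal:", [r[0] for r in table.rows[:5]])

# The keyword clusters around the planted hotspot, so its mentions share a
# small stretch of the route; the frequency table is the word-cloud input.
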