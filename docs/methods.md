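# Methods

This note records the model behind each pipeline stage, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
test bed does and does not establish about real rides.

## Transcript model and word-time interpolation

A transcript is plain UTF-8 text. A row begins with a media timestamp —
exactly three colon-separated integer fields, minutes and seconds below
60, hours unbounded (media time is recording-relative, so rides are not
wrapped at 24 h) — written bare or parenthesized, optionally followed by
a bracketed speaker tag (`[HW]`). Unstamped non-empty lines continue the
previous row: stamps precede comments, usually per sentence, not per
printed line. Stamps must be strictly increasing. Validation is
fail-fast and names the offending time, because transcripts are
hand-edited inputs and the fix (add or subtract a second between
quick-succession comments) belongs to the transcriber.

Tokenization splits on whitespace, strips punctuation from token edges,
keeps internal apostrophes and hyphens, and normalises curly apostrophes;
matching and counting use the lower-cased form while exports keep the
display form. Every word is mapped, including function words — the
all-words layer is itself the denominator of the ratio analysis.

Interpolation convention: intervals are half-open `[tᵢ, tᵢ₊₁)` and the
first token of each row sits exactly on its opening stamp. The
alternative (centring tokens inside the interval) is defensible; keying
the first word to the moment the comment began best preserves
stamp-near-statement locality, and the convention is uniform so
downstream analyses are unaffected by the choice up to sub-interval
offsets. Tokens of the final, unclosed row advance by the ride-wide mean
seconds-per-token of the token-bearing closed intervals (falling back to
the final stamp when no such interval exists); uniform trailing spacing
avoids piling many words onto one coordinate.

## GPS tracks

Tracks come from GPX 1.1 or from GMT/latitude/longitude CSV exports
(header names configurable; rows with blank, NaN, out-of-range or (0, 0)
coordinates are retained as *invalid* samples recording the pre-fix
warm-up). Times are converted to epoch seconds UTC at parse time.
`position_at` interpolates linearly in degrees between bracketing valid
fixes: at ~1 s sample spacing of vehicle motion the difference from
geodesic interpolation is far below GPS noise. This is documented as
unsuitable for sparse tracks or tracks crossing the antimeridian.

Multi-camera rides are compared by `(valid_fraction, −max_gap_s,
duration_s)` lexicographically; ties keep input order. This encodes the
manual practice of choosing the best GPS stream per ride as one explicit,
reproducible rule.

## Clock calibration and geotagging

A single scalar offset (`GMT = media + offset`) from one matched key
sound; no drift model, since consumer-device drift over a ride of an
hour or three is below the 1 s GPS sampling. Words are dropped, with a
per-reason tally (`before_fix`, `after_track`, `gap`), rather than
clamped: clamping would fabricate hotspots at the route ends. Mid-ride
GPS dropouts are bridged by interpolation when shorter than a
configurable threshold (default 30 s, about 300 m of urban driving) and
dropped beyond it, where straight-line bridging would place words far
from the street actually driven.

## Density analysis

Metric bandwidths need a metric plane: points are projected through a
spherical azimuthal equidistant projection centred on the data centroid
(round-trip error < 0.5 m within 50 km, verified by test; an extent over
100 km raises — the method is single-city). Kernel density uses a
Gaussian kernel, bandwidth defaulting to 50 m (the contour scale used
for street-level work) and cell size bandwidth/5. The estimator bins
points to cells and convolves with a discrete Gaussian: linear in the
point set (duplication doubles the surface exactly) and mass-conserving
to well under 1% for interior data with the 3-bandwidth grid padding; the
binning places points to within half a cell (5 m at defaults), far below
bandwidth. No boundary correction is applied.

The relative-frequency surface is the unnormalised density ratio
`N_k f̂_k / (N_a f̂_a)` — the share of talk that is the keyword — masked
where the all-words density falls below the equivalent of 5 words within
two bandwidths (default), since a ratio over an un-narrated street is
noise. Group comparison is the difference of two ratio surfaces on the
intersection of their masks (resampled bilinearly when grids differ),
antisymmetric by construction.

Peak extraction takes 3×3-neighbourhood local maxima, greedily separated
by at least one bandwidth. One genuine subtlety: over words narrated
along a road, keyword and all-words kernels share the same perpendicular
decay, so the ratio surface is a *ridge* of near-constant value
perpendicular to the road and the raw argmax is arbitrary along the
ridge. Candidates whose values tie within 1e-6 relative are therefore
ranked by denominator density ("support"): the ratio is equally high off
the road, but the evidence sits on it. Without this rule peak locations
wander tens of metres off-route.

## Exports and masking

GeoJSON and CSV word layers round-trip at full float precision; KML 2.2
placemarks carry anchored excerpt text in their descriptions; surfaces
write as ESRI ASCII grids with a JSON sidecar recording the projection
origin. Metadata sheets are deterministic (dates injected, never read
from the wall clock). Masking — lattice snap (default 100 m) or seeded
Gaussian jitter (default sd 25 m) — is applied as the last step of an
export and guarantees every output coordinate differs from its original
(an exactly-on-lattice point is shifted by half a grid step). No
quantitative masking standard exists for this kind of data; the defaults
are explicit configuration, and the mask never alters in-memory objects.

## Synthetic test bed

The generator emulates the study conditions of a typical ride: a vehicle
at 10 m/s on a ~3.6 km path, 1 Hz GPS with a 30 s pre-fix warm-up,
narration at 2 words/s in rows stamped every 5–15 s, a fixed 29-word
filler vocabulary (stopwords included, so stopword tests have exact
expected counts), subject/interviewer turn-taking at 0.8/0.2, a 1%
per-word keyword probability multiplied 50× inside a single planted 50 m
cluster at the path midpoint, and ground truth recording every keyword
emission's exact time and coordinate. Problem sizes in the test suite
and acceptance script (100 two-minute rides for conservation checks, 50
full rides for hotspot recovery) were chosen as the smallest sets that
exercise the statistical claims with comfortable margins.

What the synthetic bed does *not* model: street-network routing and
turns, speed variation and stops, GPS noise and multipath, narration lag
("spatial fuzziness" — subjects describing a place before or after
passing it), abbreviations and disfluencies in transcription. Passing
tests therefore establish the correctness of the *processing* — times,
joins, conservation, densities — not the ecological accuracy of word
placement on real rides, which is bounded below by vehicle speed times
stamp spacing regardless of implementation.

## Numerical choices and edge cases

- Whole-second stamps; interpolated times are exact float expressions
  `start + k·step`, and an independent naive recomputation agrees to
  1e-9 s.
- Calibration invariance (shifting the media clock by Δ with offset −Δ)
  is exact at the bit level when Δ and the involved times make float
  addition exact — integer-second Δ, as produced by stamp matching; the
  test asserts equality, not a tolerance.
- Empty transcript → empty result; rows with no tokens contribute
  nothing but remain addressable for context queries; punctuation-only
  tokens are dropped.
- `ratio_surface` requires both sets nonempty; a keyword set containing
  the only word at a location yields exactly 1/N against N coincident
  words.
- Peak lists may be shorter than requested `k`; separation is enforced
  greedily in value order.

## Known limitations

- Single scalar clock offset; no drift correction.
- Linear (not geodesic) coordinate interpolation between fixes.
- Prefix-only keyword wildcard by design (auditable queries); no phrase
  dictionaries or semantic expansion.
- No statistical significance testing of hotspots; surfaces are
  descriptive.
- Network-constrained (street-segment) denominators are not
  implemented; the all-words denominator is the one operationalized.
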