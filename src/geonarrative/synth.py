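"""Seeded synthetic drives and narratives with known ground truth.

Every stage of the pipeline is testable without any real ride data: a
scenario describes a vehicle drive (a polyline driven at constant speed,
sampled at the GPS rate, with an optional no-fix warm-up emulating the
wait for the first satellite fix) and a narrative spoken during it
(timestamped rows every 5–15 s, filler vocabulary at a fixed word rate,
plus keyword mentions whose per-word probability is multiplied inside
planted spatial clusters). The ground truth records each keyword
emission's exact time and coordinate, so hotspot-recovery tests know
where the answer is.

The filler vocabulary is a fixed small list that includes common
stopwords, giving frequency-table and stopword tests known expected
counts; rows alternate stochastically between a subject and an
interviewer speaker to exercise subject-only filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .density import LocalProjection
from .gps import GpsSample, GpsTrack
from .query import haversine_m
from .transcript import format_stamp

__all__ = ["SyntheticScenario", "synth_track", "synth_narrative", "FILLER_VOCAB"]

# Small fixed vocabulary, stopwords first.
FILLER_VOCAB = (
    "the", "it", "and", "a", "to", "of", "you", "that",
    "street", "house", "corner", "park", "block", "school", "lot",
    "water", "basement", "traps", "camp", "alley", "people", "safe",
    "community", "work", "here", "over", "there", "problem", "place",
)
STOPWORDS = FILLER_VOCAB[:8]

# Default drive: ~3.6 km west-to-east through a mid-latitude city.
_DEFAULT_PATH = ((41.1000, -81.3700), (41.1000, -81.3270))


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic ride.

    Defaults describe a typical city drive: 10 m/s along a ~3.6 km
    street, 1 Hz GPS with a 30 s pre-fix warm-up, two words per second of
    narration, a 1% per-word chance of the keyword outside clusters and a
    50× multiplier inside the single planted 50 m cluster at the path
    midpoint.
    """

    seed: int = 0
    path: tuple[tuple[float, float], ...] = _DEFAULT_PATH
    speed_mps: float = 10.0
    gps_rate_hz: float = 1.0
    prefix_gap_s: float = 30.0
    word_rate_wps: float = 2.0
    keyword: str = "meth"
    keyword_base_rate: float = 0.01
    clusters: list[tuple[float, float, float, float]] = field(
        default_factory=lambda: [(41.1000, -81.34850, 50.0, 50.0)]
    )  # (lat, lon, radius_m, rate multiplier)
    speakers: dict[str, float] = field(
        default_factory=lambda: {"HW": 0.8, "DR": 0.2}
    )
    start_gmt: float = 1_438_992_000.0

    def __post_init__(self) -> None:
        if self.speed_mps <= 0 or self.gps_rate_hz <= 0 or self.word_rate_wps <= 0:
            raise ValueError("rates and speed must be positive")


def _path_geometry(s: SyntheticScenario):
    """Cumulative along-path distance (m) of the polyline vertices."""
    pts = np.asarray(s.path, dtype=float)
    seg = haversine_m(pts[:-1, 0], pts[:-1, 1], pts[1:, 0], pts[1:, 1])
    cum = np.concatenate([[0.0], np.cumsum(np.atleast_1d(seg))])
    return pts, cum


def _position_along(s: SyntheticScenario, dist_m):
    """(lat, lon) at a given along-path distance, straight-line in a
    local metric plane (adequate at city scale)."""
    pts, cum = _path_geometry(s)
    proj = LocalProjection(float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    x, y = proj.forward(pts[:, 0], pts[:, 1])
    d = np.clip(np.asarray(dist_m, dtype=float), 0.0, cum[-1])
    xi = np.interp(d, cum, x)
    yi = np.interp(d, cum, y)
    return proj.inverse(xi, yi)


def ride_duration_s(s: SyntheticScenario) -> float:
    """Seconds needed to drive the whole path at the scenario speed."""
    _, cum = _path_geometry(s)
    return float(cum[-1] / s.speed_mps)


def synth_track(s: SyntheticScenario) -> GpsTrack:
    """GPS track of the scenario drive.

    Media time 0 corresponds to ``start_gmt``. Samples before
    ``prefix_gap_s`` are invalid (the warm-up before first fix); from then
    on the vehicle moves along the path at constant speed, sampled at
    ``gps_rate_hz``.
    """
    duration = ride_duration_s(s)
    dt = 1.0 / s.gps_rate_hz
    times = np.arange(0.0, duration + dt / 2, dt)
    lats, lons = _position_along(s, times * s.speed_mps)
    samples = []
    for t, la, lo in zip(times, np.atleast_1d(lats), np.atleast_1d(lons)):
        if t < s.prefix_gap_s:
            samples.append(GpsSample(gmt=s.start_gmt + t, lat=0.0, lon=0.0, valid=False))
        else:
            samples.append(GpsSample(gmt=s.start_gmt + t, lat=float(la), lon=float(lo)))
    return GpsTrack(samples=samples, camera_label="synthetic")


def _keyword_prob(s: SyntheticScenario, lat: float, lon: float) -> float:
    p = s.keyword_base_rate
    for clat, clon, radius_m, mult in s.clusters:
        if haversine_m(lat, lon, clat, clon) <= radius_m:
            p = s.keyword_base_rate * mult
            break
    return min(p, 0.9)


def synth_narrative(
    s: SyntheticScenario, track: GpsTrack
) -> tuple[str, dict]:
    """Timestamped transcript text plus ground truth for the drive.

    Stamps start at media 0 and advance by 5–15 s; each row holds words
    whose true emission times are uniform within the row's interval, in
    speaking order. Each word is the scenario keyword with probability
    ``keyword_base_rate`` (multiplied inside clusters, evaluated at the
    vehicle's true position at emission time), otherwise a filler word.

    Ground truth records the clock calibration (media 0 ↔ ``start_gmt``),
    every keyword emission's true media time and coordinate, the stamp
    times and total token count.
    """
    rng = np.random.default_rng(s.seed)
    duration = ride_duration_s(s)
    stamps = [0.0]
    while True:
        nxt = stamps[-1] + rng.uniform(5.0, 15.0)
        if nxt >= duration:
            break
        stamps.append(np.floor(nxt))  # whole-second stamps, as transcribed
    # Whole-second flooring could collide; enforce strict increase.
    for i in range(1, len(stamps)):
        if stamps[i] <= stamps[i - 1]:
            stamps[i] = stamps[i - 1] + 1.0
    speaker_labels = list(s.speakers)
    speaker_probs = np.array(list(s.speakers.values()), dtype=float)
    speaker_probs = speaker_probs / speaker_probs.sum()

    lines: list[str] = []
    truth_mentions: list[dict] = []
    total_tokens = 0
    for i, t0 in enumerate(stamps):
        t1 = stamps[i + 1] if i + 1 < len(stamps) else duration
        n_words = int(rng.poisson(s.word_rate_wps * (t1 - t0)))
        emit_times = np.sort(rng.uniform(t0, t1, size=n_words))
        speaker = str(rng.choice(speaker_labels, p=speaker_probs))
        tokens: list[str] = []
        for et in emit_times:
            lat, lon = _position_along(s, float(et) * s.speed_mps)
            lat, lon = float(lat), float(lon)
            if rng.uniform() < _keyword_prob(s, lat, lon):
                tokens.append(s.keyword)
                truth_mentions.append(
                    {
                        "media_time": float(et),
                        "gmt": s.start_gmt + float(et),
                        "lat": lat,
                        "lon": lon,
                    }
                )
            else:
                tokens.append(str(rng.choice(FILLER_VOCAB)))
        total_tokens += len(tokens)
        lines.append(f"({format_stamp(t0)})[{speaker}] " + " ".join(tokens))
    text = "\n".join(lines) + "\n"
    truth = {
        "seed": s.seed,
        "keyword": s.keyword,
        "calibration": {"media_time": 0.0, "gmt": s.start_gmt},
        "duration_s": duration,
        "stamps": [float(t) for t in stamps],
        "total_tokens": total_tokens,
        "mentions": truth_mentions,
        "clusters": [list(c) for c in s.clusters],
        "max_stamp_gap_s": float(
            max(
                (b - a for a, b in zip(stamps, stamps[1:])),
                default=0.0,
            )
        ),
    }
    return text, truth


def write_fixture_files(s: SyntheticScenario, out_dir) -> dict:
    """Write transcript.txt, track.gpx and truth.json for a scenario."""
    from pathlib import Path

    from .gps import write_gpx

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    track = synth_track(s)
    text, truth = synth_narrative(s, track)
    (out / "transcript.txt").write_text(text, encoding="utf-8")
    write_gpx(track, out / "track.gpx")
    (out / "truth.json").write_text(json.dumps(truth, indent=1), encoding="utf-8")
    return truth
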