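"""Shared fixtures: printed transcript excerpts and random-ride builders."""

from __future__ import annotations

import numpy as np
import pytest

from geonarrative import (
    GpsSample,
    GpsTrack,
    InterpolatedWord,
    TimedTranscript,
    tokenize,
)

# Opening excerpt of a mosquito-control ride transcript (vehicle tour of
# trap locations); five rows, no speaker tags.
MOSQUITO_EXCERPT = """\
(00:14:00) Prior to closing this up, I could stick my dipper in there, you know a foot to a foot and a half.
(00:14:10) I used to set my traps up here but I haven’t caught anything when I set it up here.
(00:14:17) But if you go over here.
(00:14:33) And if I set it up over here, it’s pretty moist and there’s probably water inside.
(00:14:41) And in this basement area right here I put a trap in here and I catch Aedes and Culex in this area right here.
"""

# Skid Row outreach ride excerpt: health worker (HW) and driver (DR)
# speaker tags, stamps 00:07:34 through 00:24:19.
SKIDROW_EXCERPT = """\
(00:07:34) So, you’ve got different types of homeless, which I know it sounds really crazy, but the guys that are on this side of the freeway,
(00:07:40) are definitely a little bit, um, rougher around the edges, than the people,
(00:07:47) on the other side of the 101. And the reason why is because you’ve got MacArthur Park,
(00:07:51) you’ve got like, more of the suburbs, you’ve got more areas where, um the hills.
(00:07:57) Um here, it’s concrete jungle, and they’re completely trapped.
(00:08:03) So you’ll see them, their like, their sixth senses grow a little bit harder. Their vibe is a little bit more intimidating.
(00:08:09) It’s just because they’re in the middle of the jungle. That’s my impression.
(00:08:17) When I first started coming down here, you would never see families with kids.
(00:08:22) When you go to the jewelry mart, you’d never see families with kids. You would see crack deals.
(00:20:16)[DR] How come there is no one on the other side?
(00:20:18)[HW] Sun
(00:20:19)[DR] Oh the sun
(00:20:21)[HW] So they basically fort, I mean it’s a lot of work to be homeless. You have to find the right spot,
(00:20:26)[HW] you have to make sure there’s no sun, you have to make sure that people aren’t going to kick you out,
(00:20:30)[HW] you have to make sure you’re not coming on someone else’s block. You have to make sure like.
(00:20:36)[HW] It’s a lot of work.
(00:20:39)[DR] And are they, are, you said people are loners, are some people actually group, gregarious and connected to each other or do they look out for each other?
(00:20:50)[HW] yea there’s a sense of community.
(00:20:53)[HW] There’s a sense of community for sure. But you also have to keep in mind, what drugs are they using?
(00:21:00)[HW] because and what time of the month, what time of the month is it. Are they going to be sharing their drugs in order to have friends,
(00:21:09)[HW] Are they going to be just doing all the dope themselves, …. the time of the month, matters a lot.
(00:21:17)[HW] See there are too many gates here
(00:21:20)[DR] What do you mean too many gates?
(00:21:21)[HW] Too many gates, it’s not a safe place to hang out.
(00:21:26)[DR] Because too much traffic?
(00:21:29)[HW] Too much traffic, too much activity.
(00:21:33)[HW] She’s probably looking for a rock.
(00:21:45)[HW] So I want to go, so you see how that’s safe there?
(00:21:52)[HW] That’s a safe spot.
(00:21:53)[HW] uh huh, that’s a safe spot.
(00:21:57)[HW] So as I said, when we first started, we were on Fifth and Main and we came here in two thousand five.
(00:22:41)[HW] And this is kind of where it starts.
(00:22:46)[DR] Do all those people camp together? Do they know each other?
(00:22:49)[HW] Mhmm
(00:22:58)[HW] See they respect Skid Row Housing Trust, they’re not on that corner.
(00:23:04)[HW] But now they’re over here.
(00:23:33)[HW] I mean that alleyway there’s a lot of stuff that goes on. A lot of stuff that goes on because you’ve got these guys on the corner, they’re slinging, they’re hustling.
(00:23:46)[HW] They know what’s up. You’ve got the watchdog, you’ve got the old man, you’ve got the one who’s carrying it and you can tell by their shoes.
(00:23:54)[DR] Who the dealers are, who’s dealing?
(00:23:55)[HW] Yea. You can tell by how clean their shoes are.
(00:24:03)[HW] How white their shirts are
(00:24:08)[HW] Do you see what I mean, do you get the vibe?
(00:24:13)[DR] So is this where the alleys are to the left?
(00:24:17)[HW] The alley is right here to the left.
(00:24:19)[HW] And this is always where they comingle.
"""

_VOCAB = [
    "the", "a", "street", "house", "corner", "drugs", "water", "safe",
    "people", "here", "over", "camp", "recovery", "alley", "it's",
]


@pytest.fixture
def mosquito_excerpt() -> str:
    return MOSQUITO_EXCERPT


@pytest.fixture
def skidrow_excerpt() -> str:
    return SKIDROW_EXCERPT


def random_transcript_text(rng: np.random.Generator, n_rows: int = 10) -> str:
    """A random valid transcript: increasing whole-second stamps, 0–8
    words per row, occasional speaker tags."""
    t = int(rng.integers(0, 120))
    lines = []
    for _ in range(n_rows):
        h, m, s = t // 3600, t % 3600 // 60, t % 60
        speaker = f"[{rng.choice(['HW', 'DR'])}] " if rng.uniform() < 0.3 else " "
        words = " ".join(rng.choice(_VOCAB, size=int(rng.integers(0, 9))))
        lines.append(f"({h:02d}:{m:02d}:{s:02d}){speaker}{words}")
        t += int(rng.integers(1, 30))
    return "\n".join(lines) + "\n"


def naive_word_times(t: TimedTranscript) -> list[float]:
    """Independent per-interval recomputation of interpolated word times.

    Plain per-row arithmetic, written separately from the pipeline: for a
    row closed by the next stamp, the k-th of its n tokens sits at
    ``start + k * span / n``; the final row's tokens advance by the mean
    seconds-per-token of the token-bearing closed rows.
    """
    times: list[float] = []
    spans, counts = [], []
    for i in range(len(t.rows) - 1):
        n = len(tokenize(t.rows[i].text))
        if n > 0:
            spans.append(t.rows[i + 1].stamp.seconds - t.rows[i].stamp.seconds)
            counts.append(n)
    rate = sum(spans) / sum(counts) if counts else 0.0
    for i, row in enumerate(t.rows):
        n = len(tokenize(row.text))
        start = row.stamp.seconds
        if i < len(t.rows) - 1:
            span = t.rows[i + 1].stamp.seconds - start
            for k in range(n):
                times.append(start + k * span / n)
        else:
            for k in range(n):
                times.append(start + k * rate)
    return times


def straight_track(
    n: int = 200,
    t0: float = 1_000_000.0,
    lat0: float = 41.0,
    lon0: float = -81.5,
    dlat: float = 0.0,
    dlon: float = 1e-4,
    invalid_prefix: int = 0,
) -> GpsTrack:
    """A 1 Hz straight-line track; optional invalid warm-up samples."""
    samples = []
    for i in range(n):
        if i < invalid_prefix:
            samples.append(GpsSample(gmt=t0 + i, lat=0.0, lon=0.0, valid=False))
        else:
            samples.append(
                GpsSample(gmt=t0 + i, lat=lat0 + i * dlat, lon=lon0 + i * dlon)
            )
    return GpsTrack(samples=samples, camera_label="test")


def make_words(times_and_norms: list[tuple[float, str]]) -> list[InterpolatedWord]:
    """Interpolated words at explicit media times (word == norm)."""
    return [
        InterpolatedWord(
            id=i + 1,
            media_time=t,
            word=w,
            word_norm=w,
            speaker=None,
            row_index=i,
        )
        for i, (t, w) in enumerate(times_and_norms)
    ]
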