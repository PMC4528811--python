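"""Parse a timestamped transcript and give every word its own time.

A ride transcript stamps each comment with the recorder clock (HH:MM:SS).
Words between consecutive stamps are spread evenly across the seconds
separating them, so each spoken word gets a media time of its own — the
prerequisite for joining words to GPS coordinates.
"""

from geonarrative import interpolate_words, parse_transcript

TEXT = """\
(00:14:00) Prior to closing this up, I could stick my dipper in there, you know a foot to a foot and a half.
(00:14:10) I used to set my traps up here but I haven't caught anything when I set it up here.
(00:14:17) But if you go over here.
"""

t = parse_transcript(TEXT)
print(f"{len(t)} rows, stamps {t.rows[0].stamp} .. {t.rows[-1].stamp}")

words = interpolate_words(t)
print(f"{len(words)} words interpolated; first five:")
for w in words[:5]:
    print(f"  id={w.id:<3d} t={w.media_time:8.3f} s  {w.word}")

# The first word of each comment sits exactly on the stamp that opened it;
# the 22 words of the first row advance by 10/22 s each, so the row's talk
# fills the ten seconds until the next stamp.
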