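"""GPS track ingestion, interpolation, quality and filename metadata."""

import datetime

import numpy as np
import pytest

from geonarrative import (
    EmptyTrackError,
    FormatError,
    GpsSample,
    GpsTrack,
    NoFixError,
    OutOfRangeError,
    first_fix,
    parse_gpx,
    parse_position_csv,
    parse_video_filename,
    position_at,
    select_best,
    track_quality,
    write_gpx,
    write_position_csv,
)

from conftest import straight_track


def gpx_doc(points) -> str:
    body = "".join(
        f'<trkpt lat="{lat}" lon="{lon}"><time>{time}</time></trkpt>'
        for lat, lon, time in points
    )
    return (
        '<?xml version="1.0"?>'
        '<gpx xmlns="http://www.topografix.com/GPX/1/1" version="1.1" '
        f'creator="t"><trk><trkseg>{body}</trkseg></trk></gpx>'
    )


class TestParseGpx:
    def test_reads_points_in_order(self):
        doc = gpx_doc(
            [
                (41.0, -81.0, "2015-03-10T15:00:00Z"),
                (41.1, -81.1, "2015-03-10T15:00:01Z"),
                (41.2, -81.2, "2015-03-10T15:00:02Z"),
            ]
        )
        track = parse_gpx(doc)
        assert len(track) == 3
        assert all(s.valid for s in track.samples)
        assert track.samples[1].lat == 41.1
        assert track.samples[1].gmt - track.samples[0].gmt == 1.0

    def test_unordered_points_resorted(self, caplog):
        doc = gpx_doc(
            [
                (41.1, -81.1, "2015-03-10T15:00:05Z"),
                (41.0, -81.0, "2015-03-10T15:00:00Z"),
            ]
        )
        with caplog.at_level("WARNING"):
            track = parse_gpx(doc)
        assert [s.lat for s in track.samples] == [41.0, 41.1]
        assert any("re-sorting" in r.message for r in caplog.records)

    def test_no_trkpt_raises(self):
        with pytest.raises(EmptyTrackError):
            parse_gpx(gpx_doc([]))

    def test_missing_time_raises(self):
        doc = gpx_doc([(41.0, -81.0, "2015-03-10T15:00:00Z")]).replace(
            "<time>2015-03-10T15:00:00Z</time>", ""
        )
        with pytest.raises(FormatError):
            parse_gpx(doc)

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        track = straight_track(n=50, lat0=41.123456, lon0=-81.654321)
        path = tmp_path / "out.gpx"
        write_gpx(track, path)
        back = parse_gpx(path)
        assert len(back) == len(track)
        for a, b in zip(track.samples, back.samples):
            assert abs(a.lat - b.lat) < 1e-7
            assert abs(a.lon - b.lon) < 1e-7
            assert abs(a.gmt - b.gmt) < 1e-2


class TestParsePositionCsv:
    def test_blank_rows_kept_as_invalid(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("GMT,Latitude,Longitude\n0,,\n1,41.1,-81.3\n")
        track = parse_position_csv(p)
        assert len(track) == 2
        assert not track.samples[0].valid
        assert track.samples[1].valid
        assert track.samples[1].lat == 41.1

    def test_zero_zero_is_no_fix_sentinel(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text("GMT,Latitude,Longitude\n0,0,0\n1,41.1,-81.3\n")
        track = parse_position_csv(p)
        assert not track.samples[0].valid

    def test_column_order_irrelevant_with_names(self, tmp_path):
        p1 = tmp_path / "c1.csv"
        p2 = tmp_path / "c2.csv"
        p1.write_text("GMT,Latitude,Longitude\n5,41.0,-81.0\n")
        p2.write_text("Longitude,GMT,Latitude\n-81.0,5,41.0\n")
        t1, t2 = parse_position_csv(p1), parse_position_csv(p2)
        assert t1.samples == t2.samples

    def test_custom_column_map(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("when,y,x\n5,41.0,-81.0\n")
        track = parse_position_csv(
            p, column_map={"time": "when", "lat": "y", "lon": "x"}
        )
        assert track.samples[0].lat == 41.0

    def test_unidentifiable_columns_raise(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(FormatError):
            parse_position_csv(p)

    def test_iso_times_parsed_as_utc(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text(
            "GMT,Latitude,Longitude\n2015-03-10T15:00:00Z,41.0,-81.0\n"
        )
        track = parse_position_csv(p)
        expect = datetime.datetime(
            2015, 3, 10, 15, tzinfo=datetime.timezone.utc
        ).timestamp()
        assert track.samples[0].gmt == expect

    def test_roundtrip_through_csv(self, tmp_path):
        track = straight_track(n=20, invalid_prefix=3)
        p = tmp_path / "g.csv"
        write_position_csv(track, p)
        back = parse_position_csv(p)
        assert [s.valid for s in back.samples] == [s.valid for s in track.samples]
        for a, b in zip(track.samples, back.samples):
            if a.valid:
                assert abs(a.lat - b.lat) < 1e-12


class TestFirstFixAndPosition:
    def test_first_fix_after_warmup(self):
        track = straight_track(n=100, t0=0.0, invalid_prefix=30)
        assert first_fix(track) == 30.0

    def test_first_fix_all_valid(self):
        track = straight_track(n=10, t0=5.0)
        assert first_fix(track) == 5.0

    def test_no_fix_raises(self):
        track = GpsTrack(
            samples=[GpsSample(gmt=0.0, lat=0, lon=0, valid=False)]
        )
        with pytest.raises(NoFixError):
            first_fix(track)

    def test_position_exact_at_sample(self):
        track = straight_track(n=10, t0=0.0, lat0=41.0, lon0=-81.0, dlon=0.001)
        lat, lon = position_at(track, 3.0)
        assert (lat, lon) == (41.0, -81.0 + 3 * 0.001)

    def test_position_midway_linear(self):
        track = GpsTrack(
            samples=[
                GpsSample(gmt=100.0, lat=41.0, lon=-81.0),
                GpsSample(gmt=200.0, lat=41.2, lon=-81.4),
            ]
        )
        lat, lon = position_at(track, 150.0)
        assert lat == pytest.approx(41.1)
        assert lon == pytest.approx(-81.2)

    def test_before_first_fix_out_of_range(self):
        track = straight_track(n=100, t0=0.0, invalid_prefix=30)
        with pytest.raises(OutOfRangeError):
            position_at(track, 10.0)

    def test_continuity_against_naive_oracle(self):
        rng = np.random.default_rng(11)
        times = np.sort(rng.uniform(0, 100, size=20))
        lats = 41.0 + np.cumsum(rng.normal(0, 1e-4, size=20))
        lons = -81.0 + np.cumsum(rng.normal(0, 1e-4, size=20))
        track = GpsTrack(
            samples=[
                GpsSample(gmt=float(t), lat=float(la), lon=float(lo))
                for t, la, lo in zip(times, lats, lons)
            ]
        )
        # exact at samples
        for t, la, lo in zip(times, lats, lons):
            plat, plon = position_at(track, float(t))
            assert plat == pytest.approx(la, abs=1e-12)
            assert plon == pytest.approx(lo, abs=1e-12)
        # hand linear interpolation at midpoints
        for i in range(19):
            tm = (times[i] + times[i + 1]) / 2
            f = (tm - times[i]) / (times[i + 1] - times[i])
            plat, plon = position_at(track, float(tm))
            assert plat == pytest.approx(lats[i] + f * (lats[i + 1] - lats[i]), abs=1e-12)


class TestQualityAndSelection:
    def test_metrics(self):
        track = straight_track(n=100, t0=0.0, invalid_prefix=25)
        q = track_quality(track)
        assert q.sample_count == 100
        assert q.duration_s == 99.0
        assert q.valid_fraction == 0.75
        assert q.max_gap_s == 1.0

    def test_select_prefers_higher_valid_fraction(self):
        a = straight_track(n=100, invalid_prefix=10)
        b = straight_track(n=100, invalid_prefix=1)
        assert select_best([a, b]) is b

    def test_tie_keeps_first(self):
        a = straight_track(n=100)
        b = straight_track(n=100)
        assert select_best([a, b]) is a

    def test_single_track_returned(self):
        a = straight_track(n=10)
        assert select_best([a]) is a


class TestVideoFilename:
    def test_canonical_example(self):
        meta = parse_video_filename("LA031015RA1of4")
        assert meta.site == "LA"
        assert meta.date == datetime.date(2015, 3, 10)
        assert meta.side == "R"
        assert meta.segment == 1
        assert meta.total_segments == 4

    def test_left_side_variant(self):
        meta = parse_video_filename("JO052211LB2of3")
        assert meta.site == "JO"
        assert meta.date == datetime.date(2011, 5, 22)
        assert meta.side == "L"
        assert (meta.segment, meta.total_segments) == (2, 3)

    @pytest.mark.parametrize("bad", ["notaname.mov", "LA131015RA1of4", "LA031015RA5of4"])
    def test_rejects_bad_names(self, bad):
        with pytest.raises(FormatError):
            parse_video_filename(bad)
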