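"""Projection, KDE, ratio/difference surfaces and hotspot peaks."""

import numpy as np
import pytest

from geonarrative import (
    EmptyInputError,
    GeometryError,
    LocalProjection,
    difference_surface,
    haversine_m,
    hotspot_peaks,
    kde,
    ratio_surface,
)


class TestLocalProjection:
    def test_roundtrip_under_half_meter_within_50km(self):
        rng = np.random.default_rng(8)
        proj = LocalProjection(41.0, -81.5)
        # random points within ~50 km of the origin
        lat = 41.0 + rng.uniform(-0.45, 0.45, size=500)
        lon = -81.5 + rng.uniform(-0.6, 0.6, size=500)
        x, y = proj.forward(lat, lon)
        lat2, lon2 = proj.inverse(x, y)
        err = haversine_m(lat, lon, lat2, lon2)
        assert float(np.max(err)) < 0.5

    def test_origin_maps_to_zero_and_back(self):
        proj = LocalProjection(34.04, -118.24)
        x, y = proj.forward(34.04, -118.24)
        assert abs(float(x)) < 1e-9 and abs(float(y)) < 1e-9
        lat, lon = proj.inverse(0.0, 0.0)
        assert (float(lat), float(lon)) == (34.04, -118.24)

    def test_distance_from_origin_preserved(self):
        # azimuthal equidistant: range from the center is exact
        proj = LocalProjection(41.0, -81.0)
        lat, lon = 41.02, -81.03
        x, y = proj.forward(lat, lon)
        assert float(np.hypot(x, y)) == pytest.approx(
            float(haversine_m(41.0, -81.0, lat, lon)), rel=1e-9
        )


class TestKde:
    def test_single_point_integral_and_argmax(self):
        surf = kde(np.array([[41.0, -81.0]]), bandwidth_m=50.0)
        assert surf.integral() == pytest.approx(1.0, rel=0.01)
        i, j = np.unravel_index(np.argmax(surf.values), surf.values.shape)
        xs, ys = surf.cell_centers()
        px, py = surf.projection.forward(41.0, -81.0)
        assert abs(xs[j] - float(px)) <= surf.cell_size_m
        assert abs(ys[i] - float(py)) <= surf.cell_size_m

    def test_coincident_points_double_surface_exactly(self):
        one = kde(np.array([[41.0, -81.0]]), bandwidth_m=50.0)
        two = kde(np.array([[41.0, -81.0], [41.0, -81.0]]), bandwidth_m=50.0)
        assert np.array_equal(two.values, 2.0 * one.values)

    def test_seeded_gaussian_sample_mass_and_mode(self):
        rng = np.random.default_rng(123)
        proj = LocalProjection(41.0, -81.0)
        xy = rng.normal(0.0, 120.0, size=(200, 2))
        lat, lon = proj.inverse(xy[:, 0], xy[:, 1])
        surf = kde(np.column_stack([lat, lon]), bandwidth_m=50.0)
        assert surf.integral() == pytest.approx(200.0, rel=0.01)
        i, j = np.unravel_index(np.argmax(surf.values), surf.values.shape)
        xs, ys = surf.cell_centers()
        plat, plon = surf.projection.inverse(xs[j], ys[i])
        assert float(haversine_m(plat, plon, 41.0, -81.0)) < 50.0

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            kde(np.empty((0, 2)))

    def test_mass_conservation_random_seeds(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            proj = LocalProjection(41.0, -81.0)
            xy = rng.uniform(-300, 300, size=(50, 2))
            lat, lon = proj.inverse(xy[:, 0], xy[:, 1])
            surf = kde(np.column_stack([lat, lon]), bandwidth_m=40.0)
            assert surf.integral() == pytest.approx(50.0, rel=0.01)


def _line_points(n, lon_span=0.02, lat=41.0, lon0=-81.0, rng=None):
    lons = np.linspace(lon0, lon0 + lon_span, n)
    return np.column_stack([np.full(n, lat), lons])


class TestRatioSurface:
    def test_identical_sets_give_unit_ratio(self):
        pts = _line_points(100)
        surf = ratio_surface(pts, pts, bandwidth_m=50.0)
        assert surf.mask.any()
        assert np.max(np.abs(surf.values[surf.mask] - 1.0)) < 1e-9

    def test_single_keyword_among_coincident_words(self):
        # N words at one location, one of them the keyword: the unmasked
        # ratio at the shared point is exactly 1/N.
        N = 8
        all_pts = np.tile([[41.0, -81.0]], (N, 1))
        kw = all_pts[:1]
        surf = ratio_surface(kw, all_pts, bandwidth_m=50.0)
        assert surf.values[surf.mask] == pytest.approx(1.0 / N)

    def test_corpus_duplication_invariance(self):
        rng = np.random.default_rng(4)
        all_pts = _line_points(200)
        kw = all_pts[rng.uniform(size=200) < 0.2]
        a = ratio_surface(kw, all_pts, bandwidth_m=50.0)
        b = ratio_surface(
            np.vstack([kw, kw]), np.vstack([all_pts, all_pts]), bandwidth_m=50.0
        )
        assert b.numerator_count == 2 * a.numerator_count
        # cells supported before stay supported and keep their ratio
        assert (a.mask <= b.mask).all()
        assert np.allclose(a.values[a.mask], b.values[a.mask], atol=1e-12)

    def test_planted_disc_recovers_argmax(self):
        # keyword mentions only inside a 100 m disc on the corpus line
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            proj = LocalProjection(41.0, -81.0)
            x = rng.uniform(-1000, 1000, size=400)
            y = np.zeros_like(x)
            lat, lon = proj.inverse(x, y)
            all_pts = np.column_stack([lat, lon])
            inside = np.abs(x) <= 100.0
            kw = all_pts[inside & (rng.uniform(size=400) < 0.5)]
            if kw.shape[0] == 0:
                continue
            surf = ratio_surface(kw, all_pts, bandwidth_m=50.0)
            (plat, plon, _), = hotspot_peaks(surf, k=1)
            px, _ = proj.forward(plat, plon)
            hits += abs(float(px)) <= 100.0
        assert hits >= 48  # >=95% of 50 seeded runs

    def test_empty_sets_raise(self):
        pts = _line_points(10)
        with pytest.raises(EmptyInputError):
            ratio_surface(np.empty((0, 2)), pts)
        with pytest.raises(EmptyInputError):
            ratio_surface(pts, np.empty((0, 2)))


class TestDifferenceSurface:
    def test_identical_surfaces_give_zero(self):
        pts = _line_points(100)
        kw = pts[::5]
        a = ratio_surface(kw, pts, bandwidth_m=50.0)
        d = difference_surface(a, a)
        assert np.all(d.values == 0.0)

    def test_antisymmetry(self):
        pts = _line_points(150)
        a = ratio_surface(pts[::3], pts, bandwidth_m=50.0)
        b = ratio_surface(pts[::7], pts, bandwidth_m=50.0)
        d1 = difference_surface(a, b)
        d2 = difference_surface(b, a)
        assert np.array_equal(d1.values, -d2.values)
        assert np.array_equal(d1.mask, d2.mask)

    def test_offset_clusters_show_opposite_lobes(self):
        proj = LocalProjection(41.0, -81.0)
        x = np.linspace(-800, 800, 400)
        lat, lon = proj.inverse(x, np.zeros_like(x))
        pts = np.column_stack([lat, lon])
        kw_a = pts[np.abs(x + 400) <= 80]  # group A cluster near -400 m
        kw_b = pts[np.abs(x - 400) <= 80]  # group B cluster near +400 m
        a = ratio_surface(kw_a, pts, bandwidth_m=50.0)
        b = ratio_surface(kw_b, pts, bandwidth_m=50.0)
        d = difference_surface(a, b)
        xs, ys = d.cell_centers()
        xv = np.broadcast_to(xs, d.values.shape)
        vals = np.where(d.mask, d.values, 0.0)
        near_a = np.abs(xv + 400) <= 80
        near_b = np.abs(xv - 400) <= 80
        assert vals[near_a].max() > 0.2
        assert vals[near_b].min() < -0.2

    def test_disjoint_extents_raise(self):
        a = ratio_surface(_line_points(50), _line_points(50), bandwidth_m=50.0)
        far = _line_points(50, lat=45.0, lon0=-70.0)
        b = ratio_surface(far, far, bandwidth_m=50.0)
        with pytest.raises(GeometryError):
            difference_surface(a, b)


class TestHotspotPeaks:
    def test_unimodal_surface_single_peak(self):
        surf = kde(np.array([[41.0, -81.0]]), bandwidth_m=50.0)
        peaks = hotspot_peaks(surf, k=1)
        assert len(peaks) == 1
        lat, lon, v = peaks[0]
        assert float(haversine_m(lat, lon, 41.0, -81.0)) < surf.cell_size_m * 2
        assert v == surf.values.max()

    def test_two_equal_peaks_1km_apart(self):
        proj = LocalProjection(41.0, -81.0)
        lat, lon = proj.inverse(np.array([-500.0, 500.0]), np.array([0.0, 0.0]))
        surf = kde(np.column_stack([lat, lon]), bandwidth_m=50.0)
        peaks = hotspot_peaks(surf, k=2, min_separation_m=100.0)
        assert len(peaks) == 2
        px = [float(proj.forward(la, lo)[0]) for la, lo, _ in peaks]
        assert sorted(round(abs(p)) for p in px) == [500, 500]

    def test_short_list_when_fewer_peaks_exist(self):
        surf = kde(np.array([[41.0, -81.0]]), bandwidth_m=50.0)
        assert len(hotspot_peaks(surf, k=5, min_separation_m=200.0)) == 1
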