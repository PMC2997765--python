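import json
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lenscount import geometry as G
from lenscount.errors import FitError, GeometryError, ParameterError, VisibilityError
from lenscount.geometry import PlanarPoint, SphericalPoint


class TestProjections:
    @pytest.mark.parametrize(
        "colat, az, radius, expected",
        [
            (0.0, 1.23, 1250.0, (0.0, 0.0)),  # pole -> projection centre
            (math.pi / 2, 0.0, 1250.0, (1250.0, 0.0)),  # equator -> rim
            (math.pi / 6, math.pi / 2, 1000.0, (0.0, 500.0)),  # sin 30 deg = 1/2
        ],
    )
    def test_polar_examples(self, colat, az, radius, expected):
        q = G.polar_project(SphericalPoint(colat, az, radius))
        assert q.x == pytest.approx(expected[0], abs=1e-9)
        assert q.y == pytest.approx(expected[1], abs=1e-9)

    def test_polar_rejects_posterior_hemisphere(self):
        with pytest.raises(VisibilityError):
            G.polar_project(SphericalPoint(math.pi / 2 + 0.01, 0.0, 1000.0))

    @pytest.mark.parametrize(
        "colat, az, view, expected",
        [
            (math.pi / 2, 0.7, 0.7, (0.0, 0.0)),  # subsolar equator point
            (0.0, 2.2, 0.4, (0.0, 1000.0)),  # pole -> top of projection
            (math.pi / 3, math.pi / 6, 0.0,
             (1000.0 * math.sin(math.pi / 3) * 0.5, 500.0)),
        ],
    )
    def test_equatorial_examples(self, colat, az, view, expected):
        q = G.equatorial_project(SphericalPoint(colat, az, 1000.0), view)
        assert q.x == pytest.approx(expected[0], abs=1e-9)
        assert q.y == pytest.approx(expected[1], abs=1e-9)

    def test_equatorial_rejects_back_hemisphere(self):
        with pytest.raises(VisibilityError):
            G.equatorial_project(SphericalPoint(math.pi / 2, math.pi, 1000.0), 0.0)

    @given(
        colat=st.floats(0.0, math.pi / 2),
        az=st.floats(0.0, 2 * math.pi - 1e-9),
        radius=st.floats(10.0, 5000.0),
    )
    def test_polar_preserves_azimuth_and_is_monotonic(self, colat, az, radius):
        q = G.polar_project(SphericalPoint(colat, az, radius))
        rho = math.hypot(q.x, q.y)
        assert rho == pytest.approx(radius * math.sin(colat), rel=1e-12, abs=1e-9)
        if rho > 1e-6:
            assert math.atan2(q.y, q.x) % (2 * math.pi) == pytest.approx(
                az % (2 * math.pi), abs=1e-9
            )

    @given(
        colat=st.floats(1e-3, math.pi - 1e-3),
        az=st.floats(0.0, 2 * math.pi),
        view=st.floats(0.0, 2 * math.pi),
    )
    def test_equatorial_height_depends_only_on_latitude(self, colat, az, view):
        """Latitude lines are parallel: y is invariant to azimuth and viewpoint."""
        p = SphericalPoint(colat, az, 1000.0)
        if math.sin(colat) * math.cos(az - view) < 0:
            return
        q = G.equatorial_project(p, view)
        assert q.y == pytest.approx(1000.0 * math.cos(colat), abs=1e-9)

    @given(colat=st.floats(0.0, math.pi / 2 - 1e-6))
    def test_polar_round_trip_recovers_colatitude(self, colat):
        p = SphericalPoint(colat, 1.0, 1250.0)
        q = G.polar_project(p)
        back = G.colatitude_from_polar_radius(math.hypot(q.x, q.y), 1250.0)
        assert back == pytest.approx(colat, abs=1e-9)


class TestCircleFit:
    def test_exact_circle_recovered(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([1250 * np.cos(t), 1250 * np.sin(t)])
        fit = G.fit_circle(pts)
        assert fit.diameter == pytest.approx(2500.0, abs=1e-6)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-6)

    def test_exact_arc_subsample_has_zero_residual(self):
        t = np.linspace(0.2, 1.1, 7)
        pts = np.column_stack([40 + 300 * np.cos(t), -25 + 300 * np.sin(t)])
        fit = G.fit_circle(pts)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-8)
        assert fit.diameter == pytest.approx(600.0, rel=1e-9)

    def test_three_points_match_circumcircle_construction(self):
        # Independent oracle: perpendicular-bisector circumcentre.
        a, b, c = np.array([0.0, 0.0]), np.array([4.0, 0.0]), np.array([1.0, 3.0])
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        ux = (
            (a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])
        ) / d
        uy = (
            (a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])
        ) / d
        r = math.hypot(a[0] - ux, a[1] - uy)
        fit = G.fit_circle(np.array([a, b, c]))
        assert fit.center.x == pytest.approx(ux, abs=1e-9)
        assert fit.center.y == pytest.approx(uy, abs=1e-9)
        assert fit.diameter == pytest.approx(2 * r, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_circle_diameter_within_statistical_bound(self, seed):
        rng = np.random.default_rng(seed)
        n, sigma, radius = 200, 5.0, 1250.0
        t = rng.uniform(0, 2 * np.pi, n)
        rr = radius + rng.normal(0, sigma, n)
        fit = G.fit_circle(np.column_stack([rr * np.cos(t), rr * np.sin(t)]))
        assert abs(fit.radius - radius) <= 3 * sigma / math.sqrt(n)

    def test_agrees_with_independent_library_fit(self):
        """Taubin fit matches skimage's CircleModel on noisy arc data."""
        from skimage.measure import CircleModel

        rng = np.random.default_rng(17)
        t = rng.uniform(0.3, 2.4, 150)
        rr = 900.0 + rng.normal(0, 4.0, 150)
        pts = np.column_stack([55 + rr * np.cos(t), -80 + rr * np.sin(t)])
        fit = G.fit_circle(pts)
        model = CircleModel.from_estimate(pts)
        (xc, yc), r = model.center, model.radius
        assert fit.center.x == pytest.approx(xc, abs=1.5)
        assert fit.center.y == pytest.approx(yc, abs=1.5)
        assert fit.radius == pytest.approx(r, abs=1.5)

    def test_too_few_or_collinear_points_raise(self):
        with pytest.raises(FitError):
            G.fit_circle(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(FitError):
            G.fit_circle(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))


def _fit(center=(0.0, 0.0), diameter=2500.0):
    return G.CircleFit(PlanarPoint(*center), diameter, 0.0)


class TestAnteriorSector:
    def test_radius_is_distance_to_fiduciary(self):
        s = G.define_anterior_sector(_fit(), PlanarPoint(1000.0, 0.0))
        assert s.sector_radius == pytest.approx(1000.0)
        s2 = G.define_anterior_sector(_fit(), PlanarPoint(600.0, 800.0))
        assert s2.sector_radius == pytest.approx(1000.0)  # 3-4-5 triangle

    def test_full_circle_sector_is_the_disk(self):
        s = G.define_anterior_sector(_fit(), PlanarPoint(800.0, 0.0), 2 * math.pi)
        rng = np.random.default_rng(0)
        for _ in range(100):
            t, r = rng.uniform(0, 2 * np.pi), rng.uniform(0, 800)
            assert G.point_in_sector(PlanarPoint(r * np.cos(t), r * np.sin(t)), s)
        assert not G.point_in_sector(PlanarPoint(801.0, 0.0), s)

    def test_coincident_fiduciary_is_degenerate(self):
        with pytest.raises(GeometryError):
            G.define_anterior_sector(_fit(), PlanarPoint(0.0, 0.0))

    def test_closed_boundary_membership(self):
        s = G.AnteriorSector(PlanarPoint(0, 0), 1000.0, 0.0, math.pi / 3)
        assert G.point_in_sector(PlanarPoint(0.0, 0.0), s)  # apex
        assert G.point_in_sector(PlanarPoint(1000.0, 0.0), s)  # arc on bisector
        assert not G.point_in_sector(PlanarPoint(1000.5, 0.0), s)

    def test_fiduciary_lies_on_sector_for_both_placements(self):
        fid = PlanarPoint(600.0, 800.0)
        for placement in ("edge", "center"):
            s = G.define_anterior_sector(_fit(), fid, placement=placement)
            assert G.point_in_sector(fid, s)

    def test_membership_matches_polar_coordinate_oracle(self):
        s = G.AnteriorSector(PlanarPoint(30.0, -40.0), 900.0, 0.7, math.pi / 3)
        rng = np.random.default_rng(42)
        pts = rng.uniform(-1300, 1300, size=(1000, 2))
        for x, y in pts:
            dx, dy = x - 30.0, y + 40.0
            r = math.hypot(dx, dy)
            ang = (math.atan2(dy, dx) - 0.7 + math.pi) % (2 * math.pi) - math.pi
            oracle = r <= 900.0 and abs(ang) <= math.pi / 6
            assert G.point_in_sector(PlanarPoint(x, y), s) == oracle

    def test_area_fraction_of_sixty_degree_sector(self):
        """A 60° sector holds ~1/6 of uniform disk points (binomial bound)."""
        s = G.AnteriorSector(PlanarPoint(0, 0), 1000.0, 1.0, math.pi / 3)
        rng = np.random.default_rng(7)
        n = 20000
        r = 1000.0 * np.sqrt(rng.uniform(0, 1, n))
        t = rng.uniform(0, 2 * np.pi, n)
        inside = sum(
            G.point_in_sector(PlanarPoint(float(x), float(y)), s)
            for x, y in zip(r * np.cos(t), r * np.sin(t))
        )
        p = 1.0 / 6.0
        assert abs(inside - n * p) <= 3 * math.sqrt(n * p * (1 - p))


class TestEquatorialTrapezoid:
    def test_base_chord_at_equator(self):
        t = G.define_equatorial_trapezoid(500.0, 0.0, 1000.0)
        assert t.side_b == pytest.approx(2 * 1000.0 * math.sin(math.radians(5)), rel=1e-9)

    def test_degenerate_and_invalid_latitudes_raise(self):
        with pytest.raises(GeometryError):
            G.define_equatorial_trapezoid(300.0, 300.0, 1000.0)
        with pytest.raises(GeometryError):
            G.define_equatorial_trapezoid(1500.0, 0.0, 1000.0)
        with pytest.raises(GeometryError):
            G.define_equatorial_trapezoid(-100.0, 200.0, 1000.0)  # top below base

    def test_thirty_six_tiles_approximate_the_full_ring(self):
        """36 adjacent 10° chords sum to the circumference within 0.2%."""
        radius, y = 1250.0, 300.0
        t = G.define_equatorial_trapezoid(y, 0.0, radius)
        ring = 2 * math.pi * radius * math.sin(G.colatitude_from_height(y, radius))
        assert 36 * t.side_a == pytest.approx(ring, rel=2e-3)

    def test_closed_boundary_and_centroid(self):
        t = G.define_equatorial_trapezoid(300.0, -100.0, 1250.0)
        cy = (t.top_y + t.base_y) / 2
        assert G.point_in_trapezoid(PlanarPoint(0.0, cy), t)
        assert G.point_in_trapezoid(PlanarPoint(0.0, t.top_y), t)  # on side a
        assert G.point_in_trapezoid(PlanarPoint(t.side_a / 2, t.top_y), t)  # corner
        assert not G.point_in_trapezoid(PlanarPoint(0.0, t.top_y + 0.5), t)

    def test_membership_matches_half_plane_oracle(self):
        t = G.define_equatorial_trapezoid(290.0, -105.0, 1250.0)
        ha, hb = t.side_a / 2, t.side_b / 2
        # Convex-polygon oracle: non-negative cross products around the hull.
        verts = [(-hb, t.base_y), (hb, t.base_y), (ha, t.top_y), (-ha, t.top_y)]

        def oracle(x, y):
            signs = []
            for (x1, y1), (x2, y2) in zip(verts, verts[1:] + verts[:1]):
                signs.append((x2 - x1) * (y - y1) - (y2 - y1) * (x - x1))
            return all(s >= -1e-9 for s in signs)

        rng = np.random.default_rng(3)
        pts = np.column_stack(
            [rng.uniform(-250, 250, 1000), rng.uniform(-200, 400, 1000)]
        )
        for x, y in pts:
            assert G.point_in_trapezoid(PlanarPoint(x, y), t) == oracle(x, y)


class TestRegionSerialisation:
    @pytest.mark.parametrize(
        "region",
        [
            G.AnteriorSector(PlanarPoint(3.0, -2.0), 980.0, 0.45, math.pi / 3),
            G.EquatorialTrapezoid(math.radians(10), 280.0, -100.0, 1250.0),
        ],
        ids=["sector", "trapezoid"],
    )
    def test_json_round_trip(self, tmp_path, region):
        path = tmp_path / "region.json"
        G.save_region(region, path)
        loaded = G.load_region(path)
        assert type(loaded) is type(region)
        for field in region.__dataclass_fields__:
            a, b = getattr(region, field), getattr(loaded, field)
            if isinstance(a, PlanarPoint):
                assert (a.x, a.y) == pytest.approx((b.x, b.y))
            else:
                assert a == pytest.approx(b)
        d = G.region_to_dict(region)
        assert json.dumps(d)  # serialisable with plain types
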