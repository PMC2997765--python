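"""Spherical geometry of the lens surface and its two orthographic views.

The lens is modelled as a sphere of radius ``R`` (µm) centred on the optical
axis.  Positions on the epithelial surface are spherical points with

* ``colatitude`` — angle from the anterior pole along the optical axis,
  radians in [0, π];
* ``azimuth`` — angle around the optical axis, radians in [0, 2π);
* ``radius`` — distance from the lens centre, µm.

Two orthographic azimuthal projections are used, exactly as a cartographer
would draw them:

* **polar aspect** (view along the optical axis): a point maps to planar
  radius ``R·sin(colatitude)`` at its own azimuth.  Lines of longitude are
  straight, lines of latitude are concentric circles.  Only the anterior
  hemisphere (colatitude ≤ π/2) is visible.
* **equatorial aspect** (view along an equatorial axis at ``view_azimuth``):
  horizontal = ``R·sin(colatitude)·sin(azimuth − view_azimuth)``,
  vertical = ``R·cos(colatitude)``.  Lines of latitude are straight and
  parallel; the vertical coordinate depends only on latitude.  Only the
  viewer-facing hemisphere is visible.

Counting regions are a circular sector in the polar view (the anterior
sector) and an isosceles trapezoid in the equatorial view (the equatorial
sector).  Both are closed sets: a centroid on the boundary is inside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import FitError, GeometryError, ParameterError, VisibilityError

TWO_PI = 2.0 * math.pi

# Relative slack used for closed-boundary membership tests.  Purely a guard
# against floating-point round-off; regions remain closed sets.
_REL_EPS = 1e-9


def _wrap_pm_pi(angle: float) -> float:
    """Wrap an angle into (-π, π]."""
    a = math.fmod(angle, TWO_PI)
    if a <= -math.pi:
        a += TWO_PI
    elif a > math.pi:
        a -= TWO_PI
    return a


@dataclass(frozen=True)
class SphericalPoint:
    """A point near the lens surface in lens-centred spherical coordinates."""

    colatitude: float
    azimuth: float
    radius: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.colatitude <= math.pi):
            raise ParameterError(
                f"colatitude must lie in [0, pi], got {self.colatitude!r}"
            )
        if not (self.radius > 0.0 and math.isfinite(self.radius)):
            raise ParameterError(f"radius must be positive, got {self.radius!r}")
        object.__setattr__(self, "azimuth", self.azimuth % TWO_PI)


@dataclass(frozen=True)
class PlanarPoint:
    """A point in a projection plane, µm, origin at the projection centre."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ParameterError(f"planar coordinates must be finite: ({self.x}, {self.y})")

    def distance_to(self, other: "PlanarPoint") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------

def polar_project(p: SphericalPoint, atol: float = 1e-12) -> PlanarPoint:
    """Project a point onto the anterior (polar-aspect) plane.

    Raises :class:`VisibilityError` for points on the posterior hemisphere
    (colatitude > π/2), which are hidden in the polar aspect.
    """
    if p.colatitude > math.pi / 2.0 + atol:
        raise VisibilityError(
            f"colatitude {p.colatitude:.6f} rad is beyond the visible anterior hemisphere"
        )
    rho = p.radius * math.sin(p.colatitude)
    return PlanarPoint(rho * math.cos(p.azimuth), rho * math.sin(p.azimuth))


def equatorial_project(
    p: SphericalPoint, view_azimuth: float = 0.0, atol: float = 1e-12
) -> PlanarPoint:
    """Project a point onto the equatorial-aspect plane seen from ``view_azimuth``.

    The vertical coordinate is ``radius·cos(colatitude)`` (it depends only on
    latitude, so latitude lines are parallel).  Points on the far hemisphere
    raise :class:`VisibilityError`.
    """
    d = p.azimuth - view_azimuth
    if math.sin(p.colatitude) * math.cos(d) < -atol:
        raise VisibilityError("point lies on the back hemisphere for this view azimuth")
    return PlanarPoint(
        p.radius * math.sin(p.colatitude) * math.sin(d),
        p.radius * math.cos(p.colatitude),
    )


def colatitude_from_polar_radius(rho: float, lens_radius: float) -> float:
    """Invert the polar projection: planar radius -> colatitude (anterior branch)."""
    if rho < 0 or lens_radius <= 0:
        raise ParameterError("rho must be >= 0 and lens_radius > 0")
    return math.asin(min(1.0, rho / lens_radius))


def colatitude_from_height(y: float, lens_radius: float) -> float:
    """Invert the equatorial projection's vertical coordinate -> colatitude."""
    if lens_radius <= 0:
        raise ParameterError("lens_radius must be > 0")
    return math.acos(min(1.0, max(-1.0, y / lens_radius)))


# Vectorised helpers used by the simulator and the registration search.  They
# perform no visibility checks; callers mask with the *_visible helpers.

def polar_project_xy(colat, az, radius):
    rho = np.asarray(radius) * np.sin(colat)
    return rho * np.cos(az), rho * np.sin(az)


def polar_visible(colat, atol: float = 1e-12):
    return np.asarray(colat) <= math.pi / 2.0 + atol


def equatorial_project_xy(colat, az, radius, view_azimuth: float = 0.0, mirror: bool = False):
    sign = -1.0 if mirror else 1.0
    r = np.asarray(radius)
    x = sign * r * np.sin(colat) * np.sin(np.asarray(az) - view_azimuth)
    y = r * np.cos(colat)
    return x, y


def equatorial_visible(colat, az, view_azimuth: float = 0.0, atol: float = 1e-12):
    return np.sin(colat) * np.cos(np.asarray(az) - view_azimuth) >= -atol


def equatorial_depth(colat, az, radius, view_azimuth: float = 0.0):
    """Signed distance toward the viewer (positive = viewer-facing)."""
    return np.asarray(radius) * np.sin(colat) * np.cos(np.asarray(az) - view_azimuth)


# ---------------------------------------------------------------------------
# Circle fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle fitted to the projected lens outline."""

    center: PlanarPoint
    diameter: float
    rms_residual: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ParameterError("diameter must be positive")
        if self.rms_residual < 0:
            raise ParameterError("rms_residual must be >= 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def _as_xy(points) -> np.ndarray:
    if isinstance(points, np.ndarray):
        xy = np.asarray(points, dtype=float)
    else:
        pts = list(points)
        if pts and isinstance(pts[0], PlanarPoint):
            xy = np.array([(p.x, p.y) for p in pts], dtype=float)
        else:
            xy = np.asarray(pts, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ParameterError("expected an (n, 2) array of planar coordinates")
    return xy


def fit_circle(boundary_points) -> CircleFit:
    """Fit a circle by Taubin's algebraic least squares.

    Replaces the by-eye circle-and-square construction with a reproducible
    numerical fit.  Requires at least 3 non-collinear points.
    """
    xy = _as_xy(boundary_points)
    n = xy.shape[0]
    if n < 3:
        raise FitError(f"circle fit needs >= 3 points, got {n}")
    mean = xy.mean(axis=0)
    u = xy[:, 0] - mean[0]
    v = xy[:, 1] - mean[1]
    # Collinearity check via the singular values of the centred coordinates.
    s = np.linalg.svd(np.column_stack([u, v]), compute_uv=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise FitError("boundary points are collinear; no circle is defined")
    z = u * u + v * v
    zmean = z.mean()
    # Taubin constraint: smallest-singular-vector solution of [Z~, u, v].
    zcol = (z - zmean) / (2.0 * math.sqrt(zmean))
    m = np.column_stack([zcol, u, v])
    _, _, vt = np.linalg.svd(m, full_matrices=False)
    c0, c1, c2 = vt[-1]
    b = c0 / (2.0 * math.sqrt(zmean))
    if abs(b) < 1e-15:
        raise FitError("degenerate (line-like) configuration in circle fit")
    cu = -c1 / (2.0 * b)
    cv = -c2 / (2.0 * b)
    r2 = cu * cu + cv * cv + zmean
    radius = math.sqrt(max(r2, 0.0))
    center = PlanarPoint(cu + mean[0], cv + mean[1])
    rho = np.hypot(xy[:, 0] - center.x, xy[:, 1] - center.y)
    rms = float(np.sqrt(np.mean((rho - radius) ** 2)))
    return CircleFit(center=center, diameter=2.0 * radius, rms_residual=rms)


# ---------------------------------------------------------------------------
# Counting regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnteriorSector:
    """Circular sector in the polar projection used to sample the anterior cap.

    ``sector_radius`` is the distance from the projection centre to the
    fiduciary nucleus; ``orientation`` is the azimuth of the sector bisector;
    ``central_angle`` defaults to 60° so the cap count is the sector count × 6.
    """

    center: PlanarPoint
    sector_radius: float
    orientation: float
    central_angle: float

    def __post_init__(self) -> None:
        if not (0.0 < self.central_angle <= TWO_PI + 1e-12):
            raise ParameterError("central_angle must lie in (0, 2*pi]")
        if self.sector_radius <= 0:
            raise ParameterError("sector_radius must be positive")


@dataclass(frozen=True)
class EquatorialTrapezoid:
    """Isosceles trapezoid sampling the equatorial band in the equatorial view.

    The top side (*a*) sits at the fiduciary latitude (``top_y``), the base
    (*b*) at the epithelial margin (``base_y``); both are horizontal, i.e.
    parallel to the lens equator.  The side lengths are the chords subtended
    by ``longitude_width`` at the respective latitudes; the legs are straight
    segments, so the region is the trapezoid that closely approximates the
    10°-of-longitude lune between the two latitudes.
    """

    longitude_width: float
    top_y: float
    base_y: float
    lens_radius: float

    def __post_init__(self) -> None:
        if self.longitude_width <= 0:
            raise ParameterError("longitude_width must be positive")
        if self.lens_radius <= 0:
            raise ParameterError("lens_radius must be positive")
        if self.top_y == self.base_y:
            raise ParameterError("top_y and base_y must differ")

    def half_width_at_latitude(self, y: float) -> float:
        """Half-chord of the longitude lune where it crosses projection height y."""
        colat = colatitude_from_height(y, self.lens_radius)
        return self.lens_radius * math.sin(colat) * math.sin(self.longitude_width / 2.0)

    @property
    def side_a(self) -> float:
        """Top side length (at the fiduciary latitude), µm."""
        return 2.0 * self.half_width_at_latitude(self.top_y)

    @property
    def side_b(self) -> float:
        """Base side length (at the epithelial margin), µm."""
        return 2.0 * self.half_width_at_latitude(self.base_y)

    def contains(self, x: float, y: float) -> bool:
        lo, hi = sorted((self.base_y, self.top_y))
        span = hi - lo
        eps = _REL_EPS * max(1.0, abs(hi), abs(lo), span)
        if y < lo - eps or y > hi + eps:
            return False
        t = (y - self.base_y) / (self.top_y - self.base_y)
        t = min(1.0, max(0.0, t))
        hw = (1.0 - t) * self.half_width_at_latitude(self.base_y) + t * self.half_width_at_latitude(self.top_y)
        return abs(x) <= hw + _REL_EPS * max(1.0, hw)


RegionSpec = Union[AnteriorSector, EquatorialTrapezoid]


def define_anterior_sector(
    fit: CircleFit,
    fiduciary: PlanarPoint,
    central_angle: float = math.pi / 3.0,
    placement: str = "edge",
) -> AnteriorSector:
    """Construct the anterior sector from the circle fit and fiduciary nucleus.

    The sector radius is the fiduciary's distance from the fitted centre.
    With ``placement="edge"`` (default) the fiduciary lies on the sector arc
    at one angular edge, as in the construction where the sector is drawn
    adjacent to the fiduciary; ``placement="center"`` centres the bisector on
    the fiduciary azimuth.  Under the lens's azimuthal symmetry the choice
    does not bias the count.
    """
    if not (0.0 < central_angle <= TWO_PI + 1e-12):
        raise ParameterError("central_angle must lie in (0, 2*pi]")
    dx = fiduciary.x - fit.center.x
    dy = fiduciary.y - fit.center.y
    r = math.hypot(dx, dy)
    if r <= 1e-9:
        raise GeometryError("fiduciary coincides with the circle centre")
    fid_az = math.atan2(dy, dx)
    if placement == "edge":
        orientation = fid_az + central_angle / 2.0
    elif placement == "center":
        orientation = fid_az
    else:
        raise ParameterError(f"unknown sector placement {placement!r}")
    return AnteriorSector(
        center=fit.center,
        sector_radius=r,
        orientation=_wrap_pm_pi(orientation),
        central_angle=central_angle,
    )


def point_in_sector(q: PlanarPoint, s: AnteriorSector) -> bool:
    """Closed-region membership: on-boundary centroids count as inside."""
    dx = q.x - s.center.x
    dy = q.y - s.center.y
    dist = math.hypot(dx, dy)
    if dist > s.sector_radius * (1.0 + _REL_EPS) + _REL_EPS:
        return False
    if s.central_angle >= TWO_PI - 1e-12:
        return True
    if dist <= _REL_EPS * s.sector_radius:
        return True  # the apex belongs to the closed sector
    off = _wrap_pm_pi(math.atan2(dy, dx) - s.orientation)
    return abs(off) <= s.central_angle / 2.0 + _REL_EPS


def define_equatorial_trapezoid(
    fiduciary_y: float,
    margin_y: float,
    lens_radius: float,
    longitude_width: float = math.radians(10.0),
) -> EquatorialTrapezoid:
    """Construct the equatorial trapezoid between fiduciary and margin latitudes."""
    if lens_radius <= 0:
        raise ParameterError("lens_radius must be positive")
    for name, y in (("fiduciary_y", fiduciary_y), ("margin_y", margin_y)):
        if abs(y) > lens_radius * (1.0 + 1e-9):
            raise GeometryError(f"{name}={y} lies outside the lens disk (radius {lens_radius})")
    if fiduciary_y == margin_y:
        raise GeometryError("fiduciary and margin latitudes coincide; trapezoid is degenerate")
    if fiduciary_y < margin_y:
        raise GeometryError("fiduciary latitude (top) must lie above the margin (base)")
    return EquatorialTrapezoid(
        longitude_width=longitude_width,
        top_y=fiduciary_y,
        base_y=margin_y,
        lens_radius=lens_radius,
    )


def point_in_trapezoid(q: PlanarPoint, t: EquatorialTrapezoid) -> bool:
    """Closed-region membership test for the equatorial trapezoid."""
    return t.contains(q.x, q.y)


def point_in_region(q: PlanarPoint, region: RegionSpec) -> bool:
    if isinstance(region, AnteriorSector):
        return point_in_sector(q, region)
    if isinstance(region, EquatorialTrapezoid):
        return point_in_trapezoid(q, region)
    raise ParameterError(f"unknown region type {type(region).__name__}")


# ---------------------------------------------------------------------------
# Region (de)serialisation — JSON sidecars so counts are auditable
# ---------------------------------------------------------------------------

def region_to_dict(region: RegionSpec) -> dict:
    if isinstance(region, AnteriorSector):
        return {
            "type": "anterior_sector",
            "center_x_um": float(region.center.x),
            "center_y_um": float(region.center.y),
            "sector_radius_um": float(region.sector_radius),
            "orientation_deg": math.degrees(region.orientation),
            "central_angle_deg": math.degrees(region.central_angle),
        }
    if isinstance(region, EquatorialTrapezoid):
        return {
            "type": "equatorial_trapezoid",
            "longitude_width_deg": math.degrees(region.longitude_width),
            "top_y_um": float(region.top_y),
            "base_y_um": float(region.base_y),
            "lens_radius_um": float(region.lens_radius),
            "lens_diameter_um": 2.0 * float(region.lens_radius),
        }
    raise ParameterError(f"unknown region type {type(region).__name__}")


def region_from_dict(d: dict) -> RegionSpec:
    kind = d.get("type")
    if kind == "anterior_sector":
        return AnteriorSector(
            center=PlanarPoint(d["center_x_um"], d["center_y_um"]),
            sector_radius=d["sector_radius_um"],
            orientation=math.radians(d["orientation_deg"]),
            central_angle=math.radians(d["central_angle_deg"]),
        )
    if kind == "equatorial_trapezoid":
        return EquatorialTrapezoid(
            longitude_width=math.radians(d["longitude_width_deg"]),
            top_y=d["top_y_um"],
            base_y=d["base_y_um"],
            lens_radius=d["lens_radius_um"],
        )
    raise ParameterError(f"unknown region type {kind!r}")


def save_region(region: RegionSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(region_to_dict(region), fh, indent=2)


def load_region(path) -> RegionSpec:
    with open(path) as fh:
        return region_from_dict(json.load(fh))
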