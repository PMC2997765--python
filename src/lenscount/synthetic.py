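"""Ground-truthed synthetic lens epithelia and their rendered voxel stacks.

The simulator emulates the statistical structure the counting method relies
on, for a mouse lens of ≈2.5 mm equatorial diameter:

* epithelial nuclei on a spherical surface, with surface density rising from
  the anterior pole toward the epithelial margin (the pre-equatorial band is
  by far the densest part of the epithelium);
* an EdU-positive subset concentrated in the germinative zone, whose chance
  groupings form the "constellations" used to register the two views;
* meridional-row nuclei in regular columns just beyond the margin (young
  fiber cells, excluded from epithelial counts);
* fiber-cell nuclei of the lens bow lying tens of µm beneath the surface,
  which degrade the equatorial projection until they are masked away.

Nuclei are solid bodies in a monolayer, so sampling uses a hard-core point
process (dart throwing with a minimum centre separation); set
``exclusion_radius=0`` for a pure inhomogeneous random sample.

Rendering places a blob of lateral FWHM = nucleus diameter and axial FWHM =
the optical-section thickness at each visible nucleus and adds Gaussian
noise.  The default lateral profile is a solid disc blurred by the lateral
point-spread function (a confocal image of a stained nucleus is a
sharp-edged object, since the lateral PSF of a 10× objective is much smaller
than a nucleus); a pure Gaussian profile is available via
``blob_profile="gaussian"``.  Everything is reproducible bit-for-bit from
``seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import erf

from . import geometry
from .errors import ParameterError
from .geometry import PlanarPoint, RegionSpec, SphericalPoint
from .stack_ops import (
    ASPECT_ANTERIOR,
    ASPECT_EQUATORIAL,
    CHANNEL_DNA,
    CHANNEL_EDU,
    VoxelStack,
)

log = logging.getLogger(__name__)

CLS_EPITHELIAL = "epithelial"
CLS_MERIDIONAL = "meridional"
CLS_FIBER = "fiber"

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def lateral_blob_profile(rho, diameter: float, edge_sigma: float, profile: str = "disc"):
    """Normalised lateral intensity of a rendered nucleus at radius ``rho`` µm.

    ``disc``: a solid nucleus blurred by the lateral PSF,
    ``0.5·(1 − erf((ρ − d/2)/(√2·σ_e)))`` — half-maximum at ρ = d/2, so the
    FWHM equals the nucleus diameter for any edge softness.
    ``gaussian``: ``exp(−ρ²/2σ²)`` with σ = d/(2√(2 ln 2)), same FWHM.
    """
    rho = np.asarray(rho, dtype=float)
    if profile == "disc":
        return 0.5 * (1.0 - erf((rho - diameter / 2.0) / (math.sqrt(2.0) * edge_sigma)))
    if profile == "gaussian":
        sig = diameter * _FWHM_TO_SIGMA
        return np.exp(-(rho**2) / (2.0 * sig**2))
    raise ParameterError(f"unknown blob profile {profile!r}")


@dataclass
class LensSimParams:
    """Study conditions for a simulated 8-week mouse lens.

    Angles are radians internally (config files use degrees).  Defaults model
    a 2.5 mm lens bearing ~44,000 epithelial cells whose density rises ~9-fold
    from the central epithelium to the margin across the germinative zone,
    which reproduces the observed partition of cells between the anterior cap
    and the equatorial band (~15,000 : ~25,200 at a fiduciary near 80°).
    """

    lens_radius: float = 1250.0
    n_epithelial: int = 44_000
    margin_colatitude: float = math.radians(95.0)
    density_gradient: float = 9.0
    density_ramp_start: float = math.radians(75.0)
    germinative_zone: Tuple[float, float] = (math.radians(75.0), math.radians(95.0))
    edu_fraction_gz: float = 0.08
    edu_fraction_central: float = 0.002
    n_meridional: int = 9_000
    meridional_extent: float = math.radians(5.0)
    n_fiber: int = 4_000
    fiber_zone: Tuple[float, float] = (math.radians(88.0), math.radians(108.0))
    fiber_depth: float = 40.0
    fiber_depth_spread: float = 30.0
    exclusion_radius: float = 6.0
    nucleus_diameter: float = 8.0
    blob_profile: str = "disc"  # "disc" (PSF-blurred solid nucleus) or "gaussian"
    edge_sigma: float = 1.2  # lateral PSF sigma blurring the nucleus edge, µm
    axial_fwhm: float = 30.0
    amplitude: float = 200.0
    amplitude_jitter: float = 0.0  # fractional sd of per-nucleus brightness
    noise_sd: float = 5.0
    voxel_size: float = 2.25  # lateral, µm/px (1.15 mm field over 512 px)
    z_step: float = 25.0  # optical-section spacing, µm
    pad: float = 30.0
    eq_fov_y: Tuple[float, float] = (-500.0, 700.0)
    seed: int = 0

    def validate(self) -> None:
        if self.lens_radius <= 0:
            raise ParameterError("lens_radius must be positive")
        for name in ("n_epithelial", "n_meridional", "n_fiber"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("edu_fraction_gz", "edu_fraction_central"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.margin_colatitude <= math.pi):
            raise ParameterError("margin_colatitude must lie in (0, pi]")
        lo, hi = self.germinative_zone
        if not (0.0 <= lo < hi <= self.margin_colatitude + 1e-12):
            raise ParameterError("germinative_zone must be within [0, margin_colatitude]")
        if not (0.0 <= self.density_ramp_start < self.margin_colatitude):
            raise ParameterError("density_ramp_start must lie in [0, margin_colatitude)")
        if self.density_gradient <= 0:
            raise ParameterError("density_gradient must be positive")
        if self.exclusion_radius < 0:
            raise ParameterError("exclusion_radius must be >= 0")
        for name in ("nucleus_diameter", "axial_fwhm", "voxel_size", "z_step", "amplitude", "edge_sigma"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.blob_profile not in ("disc", "gaussian"):
            raise ParameterError("blob_profile must be 'disc' or 'gaussian'")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    def relative_density(self, colat) -> np.ndarray:
        """Relative surface density (cells per unit area), 1 at the pole.

        Flat at 1 up to ``density_ramp_start``, then linear in colatitude up
        to ``density_gradient`` at the margin.  ``density_ramp_start=0``
        gives the plain linear-in-colatitude profile.
        """
        colat = np.asarray(colat, dtype=float)
        span = self.margin_colatitude - self.density_ramp_start
        ramp = 1.0 + (self.density_gradient - 1.0) * np.clip(
            (colat - self.density_ramp_start) / span, 0.0, 1.0
        )
        return np.where(colat < self.density_ramp_start, 1.0, ramp)


@dataclass(frozen=True)
class SphericalNucleus:
    """Ground-truth nucleus on (or below) the lens surface."""

    position: SphericalPoint
    depth: float
    cls: str
    edu_positive: bool
    id: int


@dataclass
class GroundTruth:
    """All simulated nuclei plus the parameters that generated them.

    Arrays are parallel over nuclei; ``nuclei`` materialises the record view.
    """

    params: LensSimParams
    colatitude: np.ndarray
    azimuth: np.ndarray
    depth: np.ndarray
    cls: np.ndarray  # array of strings
    edu: np.ndarray  # bool
    ids: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def nuclei(self) -> List[SphericalNucleus]:
        r = self.params.lens_radius
        return [
            SphericalNucleus(
                position=SphericalPoint(
                    float(self.colatitude[i]), float(self.azimuth[i]), r - float(self.depth[i])
                ),
                depth=float(self.depth[i]),
                cls=str(self.cls[i]),
                edu_positive=bool(self.edu[i]),
                id=int(self.ids[i]),
            )
            for i in range(self.n)
        ]

    def mask(self, cls: Optional[str] = None, edu_only: bool = False) -> np.ndarray:
        m = np.ones(self.n, dtype=bool)
        if cls is not None:
            m &= self.cls == cls
        if edu_only:
            m &= self.edu
        return m

    def class_counts(self) -> dict:
        return {
            c: int((self.cls == c).sum())
            for c in (CLS_EPITHELIAL, CLS_MERIDIONAL, CLS_FIBER)
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "class": self.cls,
                "colatitude_deg": np.degrees(self.colatitude),
                "azimuth_deg": np.degrees(self.azimuth),
                "depth_um": self.depth,
                "edu": self.edu.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, params: LensSimParams) -> "GroundTruth":
        df = pd.read_csv(path)
        return cls(
            params=params,
            colatitude=np.radians(df["colatitude_deg"].to_numpy(float)),
            azimuth=np.radians(df["azimuth_deg"].to_numpy(float)),
            depth=df["depth_um"].to_numpy(float),
            cls=df["class"].to_numpy(str),
            edu=df["edu"].to_numpy(bool),
            ids=df["id"].to_numpy(int),
        )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_colatitudes(
    rng: np.random.Generator, n: int, params: LensSimParams
) -> np.ndarray:
    """Rejection-sample colatitudes from relative_density(θ)·sin(θ) on [0, margin]."""
    theta_m = params.margin_colatitude
    out = np.empty(0)
    # Envelope: density is monotone non-decreasing, sin θ ≤ 1.
    bound = max(params.density_gradient, 1.0)
    while len(out) < n:
        m = max(4 * (n - len(out)), 1024)
        theta = rng.uniform(0.0, theta_m, m)
        u = rng.uniform(0.0, bound, m)
        acc = u < params.relative_density(theta) * np.sin(theta)
        out = np.concatenate([out, theta[acc]])
    return out[:n]


def _unit_xyz(colat, az):
    s = np.sin(colat)
    return np.column_stack([s * np.cos(az), s * np.sin(az), np.cos(colat)])


def _hardcore_sample(
    rng: np.random.Generator, params: LensSimParams, n: int, max_rounds: int = 250
) -> Tuple[np.ndarray, np.ndarray]:
    """Hard-core sample of n surface positions with the exact colatitude law.

    Colatitudes are drawn first from the configured density profile (so the
    latitude marginal is exact by construction); overlaps are then resolved
    by re-proposing the azimuth — and, if a clash persists, slightly
    jittering the colatitude — of the later member of each clashing pair.
    A handful of unresolvable overlaps near the jamming-density margin may
    remain; they are kept (real epithelia contain the odd doublet) and
    logged.
    """
    excl = params.exclusion_radius
    r = params.lens_radius
    colat = np.sort(_sample_colatitudes(rng, n, params))
    az = rng.uniform(0.0, geometry.TWO_PI, n)
    tolerated = max(2, int(5e-4 * n))  # a residual doublet or two is biological
    pairs = np.empty((0, 2), dtype=np.intp)
    for rnd in range(max_rounds):
        xyz = _unit_xyz(colat, az) * r
        tree = cKDTree(xyz, balanced_tree=False, compact_nodes=False)
        pairs = tree.query_pairs(excl, output_type="ndarray")
        if len(pairs) <= tolerated:
            break
        redo = np.unique(pairs[:, 1])
        az[redo] = rng.uniform(0.0, geometry.TWO_PI, len(redo))
        if rnd >= 8:
            # Unjam stubborn near-margin clusters with a small latitude jitter
            # (σ ≈ exclusion radius of arc; negligible against band widths).
            colat[redo] = np.clip(
                colat[redo] + rng.normal(0.0, 1.2 * excl / r, len(redo)),
                0.0,
                params.margin_colatitude,
            )
    if len(pairs):
        log.info(
            "hard-core sampling: %d overlapping pairs remain (n=%d)", len(pairs), n
        )
    return colat, az


def _meridional_rows(
    rng: np.random.Generator, params: LensSimParams
) -> Tuple[np.ndarray, np.ndarray]:
    """Regular columns of nuclei just beyond the margin, with slight jitter."""
    n = params.n_meridional
    if n == 0:
        return np.empty(0), np.empty(0)
    r = params.lens_radius
    column_spacing = 1.25 * params.nucleus_diameter
    circumference = geometry.TWO_PI * r * math.sin(params.margin_colatitude)
    n_cols = max(1, int(round(circumference / column_spacing)))
    per_col = int(math.ceil(n / n_cols))
    col_az = np.arange(n_cols) * geometry.TWO_PI / n_cols
    row_step = params.meridional_extent / max(per_col, 1)
    colat = np.empty(n)
    az = np.empty(n)
    idx = 0
    for k in range(per_col):
        take = min(n_cols, n - idx)
        if take <= 0:
            break
        colat[idx : idx + take] = (
            params.margin_colatitude
            + (k + 0.5) * row_step
            + rng.normal(0.0, 0.15 * row_step, take)
        )
        az[idx : idx + take] = col_az[:take] + rng.normal(
            0.0, 0.05 * geometry.TWO_PI / n_cols, take
        )
        idx += take
    return colat, az % geometry.TWO_PI


def sample_epithelium(params: LensSimParams) -> GroundTruth:
    """Draw a full ground-truth nucleus population for one lens.

    Epithelial colatitudes follow the configured density profile weighted by
    the sin(colatitude) area element; azimuths are uniform; EdU status is
    Bernoulli with the germinative-zone or central probability.  Meridional
    and fiber nuclei are placed beyond the margin and below the surface.
    Deterministic given ``params.seed``.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    rng_pos, rng_edu, rng_mer, rng_fib = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    if params.exclusion_radius > 0 and params.n_epithelial > 0:
        colat_e, az_e = _hardcore_sample(rng_pos, params, params.n_epithelial)
    else:
        colat_e = _sample_colatitudes(rng_pos, params.n_epithelial, params)
        az_e = rng_pos.uniform(0.0, geometry.TWO_PI, params.n_epithelial)
    gz_lo, gz_hi = params.germinative_zone
    in_gz = (colat_e >= gz_lo) & (colat_e <= gz_hi)
    p = np.where(in_gz, params.edu_fraction_gz, params.edu_fraction_central)
    edu_e = rng_edu.uniform(size=params.n_epithelial) < p

    colat_m, az_m = _meridional_rows(rng_mer, params)

    colat_f = rng_fib.uniform(params.fiber_zone[0], params.fiber_zone[1], params.n_fiber)
    az_f = rng_fib.uniform(0.0, geometry.TWO_PI, params.n_fiber)
    depth_f = rng_fib.uniform(
        params.fiber_depth, params.fiber_depth + params.fiber_depth_spread, params.n_fiber
    )

    colat = np.concatenate([colat_e, colat_m, colat_f])
    az = np.concatenate([az_e, az_m, az_f]) % geometry.TWO_PI
    depth = np.concatenate(
        [np.zeros(len(colat_e)), np.zeros(len(colat_m)), depth_f]
    )
    cls = np.concatenate(
        [
            np.full(len(colat_e), CLS_EPITHELIAL),
            np.full(len(colat_m), CLS_MERIDIONAL),
            np.full(len(colat_f), CLS_FIBER),
        ]
    )
    edu = np.concatenate(
        [edu_e, np.zeros(len(colat_m), bool), np.zeros(len(colat_f), bool)]
    )
    ids = np.arange(len(colat))
    np.clip(colat, 0.0, math.pi, out=colat)
    return GroundTruth(
        params=params, colatitude=colat, azimuth=az, depth=depth, cls=cls, edu=edu, ids=ids
    )


# ---------------------------------------------------------------------------
# Brute-force region oracle
# ---------------------------------------------------------------------------

def true_count_in_region(
    gt: GroundTruth, region: RegionSpec, view_azimuth: float = 0.0
) -> int:
    """Count epithelial nuclei whose exact projected position falls in the region.

    This is the accuracy oracle for the imaging pipeline: it bypasses
    rendering and detection entirely, projecting each ground-truth nucleus
    with the geometry module and applying the same membership test.
    """
    count = 0
    is_sector = isinstance(region, geometry.AnteriorSector)
    r = gt.params.lens_radius
    for i in np.nonzero(gt.mask(cls=CLS_EPITHELIAL))[0]:
        colat = float(gt.colatitude[i])
        az = float(gt.azimuth[i])
        p = SphericalPoint(colat, az, r)
        if is_sector:
            if colat > math.pi / 2.0:
                continue
            q = geometry.polar_project(p)
            if geometry.point_in_sector(q, region):
                count += 1
        else:
            if math.sin(colat) * math.cos(az - view_azimuth) < 0:
                continue
            q = geometry.equatorial_project(p, view_azimuth)
            if geometry.point_in_trapezoid(q, region):
                count += 1
    return count


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _view_coordinates(gt: GroundTruth, aspect: str, view_azimuth: float):
    """(x, y, z_view) µm for every nucleus, plus visibility mask."""
    r_eff = gt.params.lens_radius - gt.depth
    if aspect == ASPECT_ANTERIOR:
        x, y = geometry.polar_project_xy(gt.colatitude, gt.azimuth, r_eff)
        z = r_eff * np.cos(gt.colatitude)
        vis = geometry.polar_visible(gt.colatitude)
    elif aspect == ASPECT_EQUATORIAL:
        x, y = geometry.equatorial_project_xy(gt.colatitude, gt.azimuth, r_eff, view_azimuth)
        z = geometry.equatorial_depth(gt.colatitude, gt.azimuth, r_eff, view_azimuth)
        vis = geometry.equatorial_visible(gt.colatitude, gt.azimuth, view_azimuth)
    else:
        raise ParameterError(f"unknown aspect {aspect!r}")
    return x, y, z, vis


def _stack_frame(params: LensSimParams, aspect: str):
    """Grid extents for a rendered stack: (x0, y0, z0, nx, ny, nz)."""
    r, pad = params.lens_radius, params.pad
    vxy, vz = params.voxel_size, params.z_step
    x_lo, x_hi = -r - pad, r + pad
    if aspect == ASPECT_ANTERIOR:
        y_lo, y_hi = -r - pad, r + pad
    else:
        y_lo, y_hi = params.eq_fov_y
    z_lo, z_hi = -pad, r + pad
    nx = int(math.ceil((x_hi - x_lo) / vxy)) + 1
    ny = int(math.ceil((y_hi - y_lo) / vxy)) + 1
    nz = int(math.ceil((z_hi - z_lo) / vz)) + 1
    return x_lo, y_hi, z_hi, nx, ny, nz


def render_stack(
    gt: GroundTruth,
    aspect: str,
    view_azimuth: float = 0.0,
    channel: str = CHANNEL_DNA,
    params: Optional[LensSimParams] = None,
) -> VoxelStack:
    """Render the visible nuclei of one channel as a noisy voxel stack.

    EdU channel renders EdU-positive nuclei only; the DNA channel renders all
    classes.  Each nucleus is an anisotropic Gaussian blob (lateral FWHM =
    nucleus diameter, axial FWHM = optical-section thickness) at its
    Cartesian position in the view frame; additive Gaussian noise is applied
    and clipped at zero.  Nuclei falling outside the grid are clipped
    silently and logged.
    """
    params = params or gt.params
    if channel not in (CHANNEL_DNA, CHANNEL_EDU):
        raise ParameterError(f"unknown channel {channel!r}")
    if aspect not in (ASPECT_ANTERIOR, ASPECT_EQUATORIAL):
        raise ParameterError(f"unknown aspect {aspect!r}")
    x0, y0, z0, nx, ny, nz = _stack_frame(params, aspect)
    vxy, vz = params.voxel_size, params.z_step
    data = np.zeros((nz, ny, nx), dtype=np.float32)

    sel = gt.edu.copy() if channel == CHANNEL_EDU else np.ones(gt.n, dtype=bool)
    x, y, z, vis = _view_coordinates(gt, aspect, view_azimuth)
    sel &= vis
    idx = np.nonzero(sel)[0]

    sig_z = params.axial_fwhm * _FWHM_TO_SIGMA
    if params.blob_profile == "disc":
        lat_extent = params.nucleus_diameter / 2.0 + 4.0 * params.edge_sigma
    else:
        lat_extent = 4.0 * params.nucleus_diameter * _FWHM_TO_SIGMA
    hx = max(1, int(math.ceil(lat_extent / vxy)))
    hz = max(1, int(math.ceil(4.0 * sig_z / vz)))

    aspect_code = {ASPECT_ANTERIOR: 0, ASPECT_EQUATORIAL: 1}[aspect]
    channel_code = {CHANNEL_EDU: 0, CHANNEL_DNA: 1}[channel]
    ss = np.random.SeedSequence(
        entropy=params.seed, spawn_key=(2 + aspect_code * 2 + channel_code,)
    )
    rng = np.random.default_rng(ss)
    if params.amplitude_jitter > 0:
        amps = params.amplitude * np.clip(
            1.0 + rng.normal(0.0, params.amplitude_jitter, len(idx)), 0.1, None
        )
    else:
        amps = np.full(len(idx), params.amplitude)

    n_clipped = 0
    inv2sz = 1.0 / (2.0 * sig_z**2)
    for amp, i in zip(amps, idx):
        # Continuous voxel-index position of the nucleus centre.
        cc = (x[i] - x0) / vxy
        rr = (y0 - y[i]) / vxy
        kk = (z0 - z[i]) / vz
        c0i, r0i, k0i = int(round(cc)), int(round(rr)), int(round(kk))
        if not (0 <= c0i < nx and 0 <= r0i < ny and 0 <= k0i < nz):
            n_clipped += 1
            continue
        clo, chi = max(0, c0i - hx), min(nx, c0i + hx + 1)
        rlo, rhi = max(0, r0i - hx), min(ny, r0i + hx + 1)
        klo, khi = max(0, k0i - hz), min(nz, k0i + hz + 1)
        dx = (np.arange(clo, chi) - cc) * vxy
        dy = (np.arange(rlo, rhi) - rr) * vxy
        rho = np.hypot(dy[:, None], dx[None, :])
        lat = lateral_blob_profile(
            rho, params.nucleus_diameter, params.edge_sigma, params.blob_profile
        )
        gz_ = amp * np.exp(-((np.arange(klo, khi) - kk) * vz) ** 2 * inv2sz)
        data[klo:khi, rlo:rhi, clo:chi] += (
            gz_[:, None, None] * lat[None, :, :]
        ).astype(np.float32)
    if n_clipped:
        log.info("render_stack: %d nuclei outside the %s grid were clipped", n_clipped, aspect)

    if params.noise_sd > 0:
        noise = rng.standard_normal(size=data.shape, dtype=np.float32)
        noise *= params.noise_sd
        data += noise
        del noise
        np.clip(data, 0.0, None, out=data)
    return VoxelStack(
        data=data,
        voxel_size=(vz, vxy, vxy),
        channel=channel,
        aspect=aspect,
        x0=x0,
        y0=y0,
        z0=z0,
        view_azimuth=view_azimuth,
    )


def render_planar_field(
    centers_um: np.ndarray,
    field_um: float,
    pixel_size: float = 2.25,
    fwhm: float = 8.0,
    amplitude: float = 200.0,
    noise_sd: float = 0.0,
    diameters: Optional[np.ndarray] = None,
    seed: int = 0,
    channel: str = CHANNEL_DNA,
    blob_profile: str = "disc",
    edge_sigma: float = 1.2,
):
    """Render a flat 2-D field of nucleus blobs (a deterministic fixture).

    ``centers_um`` is (n, 2) planar positions with the origin at the field
    centre.  Used to exercise detection in isolation from lens geometry.
    Returns a :class:`Projection`.
    """
    from .stack_ops import Projection

    centers = np.atleast_2d(np.asarray(centers_um, dtype=float))
    npx = int(round(field_um / pixel_size)) + 1
    x0 = -field_um / 2.0
    y0 = field_um / 2.0
    img = np.zeros((npx, npx), dtype=np.float32)
    xs = x0 + np.arange(npx) * pixel_size
    ys = y0 - np.arange(npx) * pixel_size
    if diameters is None:
        diameters = np.full(len(centers), fwhm)
    for (cx, cy), d in zip(centers, np.asarray(diameters, dtype=float)):
        rho = np.hypot(ys[:, None] - cy, xs[None, :] - cx)
        img += (
            amplitude * lateral_blob_profile(rho, d, edge_sigma, blob_profile)
        ).astype(np.float32)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, img.shape).astype(np.float32)
        np.clip(img, 0.0, None, out=img)
    return Projection(
        data=img,
        pixel_size=(pixel_size, pixel_size),
        channel=channel,
        aspect=ASPECT_ANTERIOR,
        x0=x0,
        y0=y0,
    )


def edu_records_from_ground_truth(
    gt: GroundTruth,
    aspect: str,
    view_azimuth: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
):
    """Idealised detection records of the EdU-positive nuclei in one view.

    Projects the ground-truth EdU nuclei exactly (optionally adding Gaussian
    centroid jitter emulating localisation error) and wraps them as
    :class:`~lenscount.detect.NucleusRecord`.  This isolates registration
    from the imaging and detection stages.
    """
    from .detect import NucleusRecord

    sel = gt.mask(edu_only=True)
    x, y, _, vis = _view_coordinates(gt, aspect, view_azimuth)
    sel &= vis
    idx = np.nonzero(sel)[0]
    rng = np.random.default_rng(seed)
    if jitter_sd > 0:
        x = x + rng.normal(0.0, jitter_sd, gt.n)
        y = y + rng.normal(0.0, jitter_sd, gt.n)
    d = gt.params.nucleus_diameter
    return [
        NucleusRecord(
            centroid=PlanarPoint(float(x[i]), float(y[i])),
            area=math.pi * (d / 2.0) ** 2,
            mean_intensity=1.0,
            equivalent_diameter=d,
            channel=CHANNEL_EDU,
            id=int(gt.ids[i]),
        )
        for i in idx
    ]


def separated_positions(
    rng: np.random.Generator, n: int, field_um: float, min_separation: float
) -> np.ndarray:
    """n random planar positions with a minimum pairwise separation."""
    pts: list = []
    guard = 0
    while len(pts) < n:
        guard += 1
        if guard > 20000 * n:
            raise ParameterError("cannot place that many separated points in the field")
        p = rng.uniform(-field_um / 2 + min_separation, field_um / 2 - min_separation, 2)
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_separation**2 for q in pts):
            pts.append(p)
    return np.asarray(pts)
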