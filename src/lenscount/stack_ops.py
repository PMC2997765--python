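"""Voxel-stack containers, maximum-intensity projection and shell masking.

Conventions
-----------
A :class:`VoxelStack` is a ``(nz, ny, nx)`` grid of non-negative intensities.
Axis 0 is the viewing axis: slice 0 is the slice nearest the viewer (the top
of the stack).  Physical coordinates are µm in the projection frame of the
stack's aspect:

* column ``c`` sits at planar ``x = x0 + c·vx``;
* row ``r`` sits at planar ``y = y0 − r·vy`` (image convention: y decreases
  down the frame);
* slice ``k`` sits at viewing-axis coordinate ``z = z0 − k·vz`` (distance
  from the lens centre plane toward the viewer).

For the anterior aspect the viewing axis is the optical axis and ``z`` is the
height above the equatorial plane; for the equatorial aspect it is the
viewer-facing depth axis.  In both cases the lens centre is at
``(x, y, z) = (0, 0, 0)``, so a sphere fitted to the bright epithelial shell
should recover the lens centre and radius.

Sub-epithelial cleanup replaces the manual slice-by-slice deletion of fiber
nuclei: a sphere is fitted to the bright shell and every voxel deeper than
``shell_thickness`` below the fitted surface is zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .errors import FitError, ParameterError

log = logging.getLogger(__name__)

ASPECT_ANTERIOR = "anterior"
ASPECT_EQUATORIAL = "equatorial"
CHANNEL_EDU = "edu"
CHANNEL_DNA = "dna"


@dataclass
class VoxelStack:
    """A 3-D intensity grid with physical metadata."""

    data: np.ndarray  # (nz, ny, nx), float32
    voxel_size: Tuple[float, float, float]  # (vz, vy, vx) µm
    channel: str
    aspect: str
    x0: float = 0.0  # planar x of column 0 (pixel centre), µm
    y0: float = 0.0  # planar y of row 0, µm
    z0: float = 0.0  # viewing-axis coordinate of slice 0, µm
    view_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ParameterError("stack data must be 3-D (z, y, x)")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel sizes must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def x_coords(self) -> np.ndarray:
        return self.x0 + np.arange(self.data.shape[2]) * self.voxel_size[2]

    def y_coords(self) -> np.ndarray:
        return self.y0 - np.arange(self.data.shape[1]) * self.voxel_size[1]

    def z_coords(self) -> np.ndarray:
        return self.z0 - np.arange(self.data.shape[0]) * self.voxel_size[0]

    def metadata(self) -> dict:
        return {
            "voxel_size_um": list(self.voxel_size),
            "channel": self.channel,
            "aspect": self.aspect,
            "x0_um": self.x0,
            "y0_um": self.y0,
            "z0_um": self.z0,
            "view_azimuth_rad": self.view_azimuth,
        }


@dataclass
class Projection:
    """A 2-D maximum-intensity projection with pixel-size metadata."""

    data: np.ndarray  # (ny, nx)
    pixel_size: Tuple[float, float]  # (vy, vx) µm
    channel: str
    aspect: str
    x0: float = 0.0
    y0: float = 0.0
    view_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ParameterError("projection data must be 2-D")
        if any(v <= 0 for v in self.pixel_size):
            raise ParameterError("pixel sizes must be positive")

    def x_coords(self) -> np.ndarray:
        return self.x0 + np.arange(self.data.shape[1]) * self.pixel_size[1]

    def y_coords(self) -> np.ndarray:
        return self.y0 - np.arange(self.data.shape[0]) * self.pixel_size[0]

    def physical_from_rc(self, row, col):
        """Map (row, col) image coordinates (possibly fractional) to planar µm."""
        return (
            self.x0 + np.asarray(col) * self.pixel_size[1],
            self.y0 - np.asarray(row) * self.pixel_size[0],
        )

    def rc_from_physical(self, x, y):
        return (
            (self.y0 - np.asarray(y)) / self.pixel_size[0],
            (np.asarray(x) - self.x0) / self.pixel_size[1],
        )

    def metadata(self) -> dict:
        return {
            "pixel_size_um": list(self.pixel_size),
            "channel": self.channel,
            "aspect": self.aspect,
            "x0_um": self.x0,
            "y0_um": self.y0,
            "view_azimuth_rad": self.view_azimuth,
        }


@dataclass(frozen=True)
class LensSurfaceFit:
    """Sphere fitted to the bright epithelial shell of a stack."""

    center: Tuple[float, float, float]  # (x, y, z) µm in the stack frame
    radius: float
    rms_residual: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("fitted radius must be positive")


def max_project(stack: VoxelStack) -> Projection:
    """Collapse a stack to its maximum-intensity projection along the viewing axis."""
    if stack.data.size == 0:
        raise ParameterError("cannot project an empty stack")
    return Projection(
        data=stack.data.max(axis=0),
        pixel_size=(stack.voxel_size[1], stack.voxel_size[2]),
        channel=stack.channel,
        aspect=stack.aspect,
        x0=stack.x0,
        y0=stack.y0,
        view_azimuth=stack.view_azimuth,
    )


def _sphere_lstsq(coords: np.ndarray):
    """Algebraic sphere fit: |p - c|² = R² linearised in (c, R²−|c|²)."""
    a = np.column_stack([2.0 * coords, np.ones(len(coords))])
    b = (coords ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise FitError("sphere fit collapsed to non-positive radius")
    return center, float(np.sqrt(r2))


def fit_lens_surface(
    stack: VoxelStack,
    intensity_quantile: float = 0.995,
    max_points: int = 200_000,
    n_robust_iter: int = 3,
    min_points: int = 50,
) -> LensSurfaceFit:
    """Fit a sphere to the bright epithelial shell of a stack.

    Voxels above the given intensity quantile are taken as shell samples and a
    sphere is fitted by linear least squares; a few trimming iterations drop
    samples whose radial residual exceeds 3 robust standard deviations, so
    that sub-epithelial fiber nuclei do not drag the fit inward.
    """
    if not (0.0 < intensity_quantile < 1.0):
        raise ParameterError("intensity_quantile must lie in (0, 1)")
    data = stack.data
    if data.size == 0 or float(data.max()) <= 0:
        raise FitError("stack contains no signal to fit a surface to")
    # Quantile on a strided subsample keeps this cheap on large stacks.
    sample = data.ravel()[:: max(1, data.size // 2_000_000)]
    thr = float(np.quantile(sample, intensity_quantile))
    if thr <= 0:
        thr = float(data.max()) * 0.25
    kz, ky, kx = np.nonzero(data > thr)
    if len(kz) < min_points:
        raise FitError(f"only {len(kz)} voxels above the intensity quantile; need {min_points}")
    if len(kz) > max_points:
        step = len(kz) // max_points + 1
        kz, ky, kx = kz[::step], ky[::step], kx[::step]
    vz, vy, vx = stack.voxel_size
    coords = np.column_stack(
        [stack.x0 + kx * vx, stack.y0 - ky * vy, stack.z0 - kz * vz]
    )
    center, radius = _sphere_lstsq(coords)
    keep = np.ones(len(coords), dtype=bool)
    for _ in range(n_robust_iter):
        resid = np.linalg.norm(coords - center, axis=1) - radius
        med = np.median(resid[keep])
        mad = np.median(np.abs(resid[keep] - med))
        sigma = max(1.4826 * mad, 1e-6)
        new_keep = np.abs(resid - med) <= 3.0 * sigma
        if new_keep.sum() < min_points or np.array_equal(new_keep, keep):
            break
        keep = new_keep
        center, radius = _sphere_lstsq(coords[keep])
    resid = np.linalg.norm(coords[keep] - center, axis=1) - radius
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return LensSurfaceFit(
        center=tuple(float(c) for c in center),
        radius=float(radius),
        rms_residual=rms,
        n_points=int(keep.sum()),
    )


def shell_mask(
    stack: VoxelStack, surface: LensSurfaceFit, shell_thickness: float = 15.0
) -> VoxelStack:
    """Zero every voxel deeper than ``shell_thickness`` below the fitted surface.

    Voxels within the shell (and outside the sphere) are left unchanged, so
    the masked stack's projection contains only epithelial / meridional-row
    signal; this is the automated surrogate for manually deleting fiber-cell
    nuclei in sub-epithelial optical sections.
    """
    if shell_thickness < 0:
        raise ParameterError("shell_thickness must be >= 0")
    cx, cy, cz = surface.center
    cutoff = surface.radius - shell_thickness
    out = stack.data.copy()
    x = stack.x_coords() - cx
    y = stack.y_coords() - cy
    zs = stack.z_coords() - cz
    xy2 = (y ** 2)[:, None] + (x ** 2)[None, :]
    for k in range(out.shape[0]):  # slice-wise to bound memory
        r2 = xy2 + zs[k] ** 2
        out[k][r2 < cutoff * cutoff] = 0
    return replace(stack, data=out)


def apply_binary_mask(stack: VoxelStack, mask: np.ndarray) -> VoxelStack:
    """Honor a user-supplied binary mask verbatim (manual-editing parity)."""
    if mask.shape != stack.data.shape:
        raise ParameterError(
            f"mask shape {mask.shape} does not match stack shape {stack.data.shape}"
        )
    return replace(stack, data=np.where(mask.astype(bool), stack.data, 0).astype(stack.data.dtype))
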