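"""End-to-end counting pipeline: stacks in, extrapolated cell total out.

Stages (mirroring the measurement procedure):

1. equatorial stacks: fit the spherical shell, zero sub-epithelial voxels,
   maximum-project;
2. anterior stacks: maximum-project;
3. fit a circle to the anterior DNA projection outline (lens diameter D and
   projection centre);
4. detect EdU nuclei in both views and register the views by their EdU
   constellations; select the fiduciary nucleus;
5. build the 60° anterior sector and the 10° equatorial trapezoid, count
   DNA-channel nuclei whose centroids fall inside each;
6. extrapolate (×6 and ×36) and sum.

A :class:`LensScene` holds the per-lens intermediates so that replicate
measurements (a different fiduciary choice and sector orientation) can be
recounted without re-rendering or re-registering.

One deliberate consistency choice: the sector radius is computed from the
fiduciary's *equatorial* vertical coordinate (ρ = R·sin(colatitude)) rather
than from its anterior centroid distance.  Near the equator the anterior
radial coordinate is foreshortened by cos(colatitude), so a small centroid
error there would shift the cap/band partition by several degrees of
latitude; the equatorial vertical coordinate carries no such amplification,
and using it for both regions makes cap and band complementary by
construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours, label as sk_label
from scipy import ndimage as ndi

from . import geometry
from .counting import CountResult
from .detect import DetectParams, NucleusRecord, count_in_region, detect_nuclei
from .errors import DetectionError, FitError, ParameterError
from .geometry import CircleFit, PlanarPoint
from .register import ConstellationMatch, Fiduciary, match_constellations, select_fiduciary
from .stack_ops import (
    ASPECT_ANTERIOR,
    ASPECT_EQUATORIAL,
    CHANNEL_DNA,
    CHANNEL_EDU,
    LensSurfaceFit,
    Projection,
    VoxelStack,
    fit_lens_surface,
    max_project,
    shell_mask,
)
from .synthetic import GroundTruth, LensSimParams, render_stack, sample_epithelium

log = logging.getLogger(__name__)

StackSet = Dict[Tuple[str, str], VoxelStack]  # keyed by (aspect, channel)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the counting pipeline (angles in degrees)."""

    anterior_angle_deg: float = 60.0
    equatorial_width_deg: float = 10.0
    margin_colatitude_deg: float = 95.0
    margin_y_um: Optional[float] = None  # overrides margin_colatitude_deg if set
    shell_thickness_um: float = 15.0
    registration_tolerance_um: float = 12.0
    surface_quantile: float = 0.995
    sector_placement: str = "edge"
    sector_orientation_offset_deg: float = 0.0
    fiduciary_rank: int = 0
    # The fiduciary (cap/band border) is restricted to the lower germinative
    # zone: beyond ~80° the polar projection compresses radial spacing by
    # cos(colatitude) < 0.17 and individual nuclei can no longer be resolved
    # there, while the equatorial view images those latitudes face-on.
    fiduciary_max_colatitude_deg: float = 80.0
    roi_pad_um: float = 25.0
    dna_detect: DetectParams = field(default_factory=DetectParams)
    edu_detect: DetectParams = field(
        default_factory=lambda: DetectParams(deconvolve_iterations=8)
    )

    def validate(self) -> None:
        for name in ("anterior_angle_deg", "equatorial_width_deg"):
            v = getattr(self, name)
            if not (0.0 < v <= 360.0):
                raise ParameterError(f"{name} must lie in (0, 360]")
        if not (0.0 < self.margin_colatitude_deg <= 180.0):
            raise ParameterError("margin_colatitude_deg must lie in (0, 180]")
        if self.shell_thickness_um < 0:
            raise ParameterError("shell_thickness_um must be >= 0")


@dataclass
class LensScene:
    """Per-lens intermediates shared by replicate counts."""

    projections: Dict[Tuple[str, str], Projection]
    circle_fit: CircleFit
    surface_fit: LensSurfaceFit
    anterior_edu: List[NucleusRecord]
    equatorial_edu: List[NucleusRecord]
    match: ConstellationMatch


@dataclass
class LensAnalysis:
    """A counted lens: the scene, the regions used, and the result."""

    scene: LensScene
    fiduciary: Fiduciary
    sector: geometry.AnteriorSector
    trapezoid: geometry.EquatorialTrapezoid
    anterior_records: List[NucleusRecord]
    equatorial_records: List[NucleusRecord]
    result: CountResult


# ---------------------------------------------------------------------------
# Circle fit on the anterior projection outline
# ---------------------------------------------------------------------------

def fit_projection_circle(projection: Projection, smooth_um: float = 5.0) -> CircleFit:
    """Fit a circle to the outline of the projected lens disk.

    The projection is smoothed, thresholded (Otsu), the largest connected
    component filled, and the fitted circle is the Taubin least-squares fit
    to its longest contour — the automated counterpart of fitting a circle
    "by eye" to the arc of the lens.
    """
    px = projection.pixel_size[1]
    img = gaussian(
        projection.data.astype(float), sigma=max(1.0, smooth_um / px), preserve_range=True
    )
    if float(img.max()) <= 0:
        raise FitError("projection contains no signal to outline")
    thr = threshold_otsu(img)
    mask = img > thr
    lab = sk_label(mask)
    if lab.max() == 0:
        raise FitError("no foreground component found for the circle fit")
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    filled = ndi.binary_fill_holes(lab == largest)
    contours = find_contours(filled.astype(float), 0.5)
    if not contours:
        raise FitError("no contour found for the circle fit")
    contour = max(contours, key=len)
    x, y = projection.physical_from_rc(contour[:, 0], contour[:, 1])
    return geometry.fit_circle(np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# ROI masks confining dense-field segmentation to the counting regions
# ---------------------------------------------------------------------------

def _sector_roi_mask(proj: Projection, sector: geometry.AnteriorSector, pad: float):
    xs = proj.x_coords() - sector.center.x
    ys = proj.y_coords() - sector.center.y
    xx, yy = np.meshgrid(xs, ys)
    dist = np.hypot(xx, yy)
    inside = dist <= sector.sector_radius + pad
    if sector.central_angle < 2.0 * math.pi - 1e-9:
        ang = np.arctan2(yy, xx) - sector.orientation
        ang = (ang + math.pi) % (2.0 * math.pi) - math.pi
        # Angular pad equivalent to `pad` µm at the point's own radius.
        ang_pad = pad / np.maximum(dist, pad)
        inside &= np.abs(ang) <= sector.central_angle / 2.0 + ang_pad
    return inside


def _trapezoid_roi_mask(proj: Projection, trap: geometry.EquatorialTrapezoid, pad: float):
    xs = proj.x_coords()
    ys = proj.y_coords()
    lo, hi = sorted((trap.base_y, trap.top_y))
    hw = max(trap.side_a, trap.side_b) / 2.0 + pad
    ym = (ys >= lo - pad) & (ys <= hi + pad)
    xm = np.abs(xs) <= hw
    return ym[:, None] & xm[None, :]


# ---------------------------------------------------------------------------
# Scene construction and counting
# ---------------------------------------------------------------------------

def build_scene(stacks: StackSet, config: Optional[AnalysisConfig] = None) -> LensScene:
    """Project, mask, detect EdU, and register the two views of one lens."""
    config = config or AnalysisConfig()
    config.validate()
    for key in [
        (ASPECT_ANTERIOR, CHANNEL_DNA),
        (ASPECT_ANTERIOR, CHANNEL_EDU),
        (ASPECT_EQUATORIAL, CHANNEL_DNA),
        (ASPECT_EQUATORIAL, CHANNEL_EDU),
    ]:
        if key not in stacks:
            raise ParameterError(f"missing stack for (aspect, channel) = {key}")

    surface = fit_lens_surface(
        stacks[(ASPECT_EQUATORIAL, CHANNEL_DNA)], config.surface_quantile
    )
    projections: Dict[Tuple[str, str], Projection] = {}
    for channel in (CHANNEL_DNA, CHANNEL_EDU):
        masked = shell_mask(
            stacks[(ASPECT_EQUATORIAL, channel)], surface, config.shell_thickness_um
        )
        projections[(ASPECT_EQUATORIAL, channel)] = max_project(masked)
        projections[(ASPECT_ANTERIOR, channel)] = max_project(
            stacks[(ASPECT_ANTERIOR, channel)]
        )

    circle = fit_projection_circle(projections[(ASPECT_ANTERIOR, CHANNEL_DNA)])

    anterior_edu = detect_nuclei(
        projections[(ASPECT_ANTERIOR, CHANNEL_EDU)], config.edu_detect
    )
    equatorial_edu = detect_nuclei(
        projections[(ASPECT_EQUATORIAL, CHANNEL_EDU)], config.edu_detect
    )
    for name, recs in (("anterior", anterior_edu), ("equatorial", equatorial_edu)):
        if len(recs) == 0:
            raise DetectionError(
                f"no EdU nuclei detected in the {name} view; check the EdU channel, "
                "its detection thresholds, and that the stacks cover the germinative zone"
            )

    # Quantitative radius from the 3-D surface fit: the projection-outline
    # circle is biased outward by roughly one blob half-width (the contour
    # follows the intensity edge, not the outermost nucleus centres), which
    # matters for the ρ -> colatitude inversion; the sphere fitted to the
    # equatorial shell voxels has no such bias.  The circle fit still
    # supplies the projection centre and the reported lens diameter D.
    match = match_constellations(
        anterior_edu,
        equatorial_edu,
        lens_radius=surface.radius,
        tolerance=config.registration_tolerance_um,
        anterior_center=circle.center,
    )
    return LensScene(
        projections=projections,
        circle_fit=circle,
        surface_fit=surface,
        anterior_edu=anterior_edu,
        equatorial_edu=equatorial_edu,
        match=match,
    )


def count_scene(
    scene: LensScene,
    config: Optional[AnalysisConfig] = None,
    fiduciary_rank: Optional[int] = None,
    sector_orientation_offset_deg: Optional[float] = None,
) -> LensAnalysis:
    """Build the counting regions for a scene and produce the CountResult.

    ``fiduciary_rank`` and ``sector_orientation_offset_deg`` override the
    config; varying them yields replicate measurements of the same lens.
    """
    config = config or AnalysisConfig()
    rank = config.fiduciary_rank if fiduciary_rank is None else fiduciary_rank
    offset = (
        config.sector_orientation_offset_deg
        if sector_orientation_offset_deg is None
        else sector_orientation_offset_deg
    )
    circle = scene.circle_fit
    r_lens = scene.surface_fit.radius  # unbiased radius (see build_scene)

    fid = select_fiduciary(
        scene.match,
        scene.anterior_edu,
        scene.equatorial_edu,
        rank=rank,
        max_colatitude=math.radians(config.fiduciary_max_colatitude_deg),
    )
    # Consistent fiduciary radius from the equatorial latitude (see module
    # docstring); the anterior centroid supplies only the sector azimuth.
    rho = r_lens * math.sin(fid.colatitude)
    fid_az = math.atan2(
        fid.anterior_position.y - circle.center.y,
        fid.anterior_position.x - circle.center.x,
    )
    anchor = PlanarPoint(
        circle.center.x + rho * math.cos(fid_az),
        circle.center.y + rho * math.sin(fid_az),
    )
    sector = geometry.define_anterior_sector(
        circle,
        anchor,
        central_angle=math.radians(config.anterior_angle_deg),
        placement=config.sector_placement,
    )
    if offset:
        sector = geometry.AnteriorSector(
            center=sector.center,
            sector_radius=sector.sector_radius,
            orientation=(sector.orientation + math.radians(offset) + math.pi)
            % (2 * math.pi)
            - math.pi,
            central_angle=sector.central_angle,
        )

    if config.margin_y_um is not None:
        margin_y = config.margin_y_um
    else:
        margin_y = r_lens * math.cos(math.radians(config.margin_colatitude_deg))
    trapezoid = geometry.define_equatorial_trapezoid(
        fiduciary_y=fid.equatorial_position.y,
        margin_y=margin_y,
        lens_radius=r_lens,
        longitude_width=math.radians(config.equatorial_width_deg),
    )

    ant_proj = scene.projections[(ASPECT_ANTERIOR, CHANNEL_DNA)]
    eq_proj = scene.projections[(ASPECT_EQUATORIAL, CHANNEL_DNA)]
    ant_records = detect_nuclei(
        ant_proj,
        config.dna_detect,
        roi_mask=_sector_roi_mask(ant_proj, sector, config.roi_pad_um),
    )
    eq_records = detect_nuclei(
        eq_proj,
        config.dna_detect,
        roi_mask=_trapezoid_roi_mask(eq_proj, trapezoid, config.roi_pad_um),
    )
    n_as = count_in_region(ant_records, sector)
    n_es = count_in_region(eq_records, trapezoid)

    provenance = {
        "lens_diameter_um": round(circle.diameter, 2),
        "circle_rms_um": round(circle.rms_residual, 3),
        "surface_radius_um": round(scene.surface_fit.radius, 2),
        "view_azimuth_deg": round(math.degrees(scene.match.view_azimuth), 3),
        "mirrored": scene.match.mirrored,
        "n_registration_inliers": scene.match.n_inliers,
        "registration_residual_um": round(scene.match.mean_pair_residual, 3),
        "fiduciary_id_pair": list(fid.id_pair),
        "fiduciary_rank": rank,
        "sector_orientation_offset_deg": offset,
        "sector": geometry.region_to_dict(sector),
        "trapezoid": geometry.region_to_dict(trapezoid),
    }
    result = CountResult.from_sector_counts(
        n_anterior_sector=n_as,
        n_equatorial_sector=n_es,
        anterior_angle=config.anterior_angle_deg,
        equatorial_width=config.equatorial_width_deg,
        fiduciary_colatitude=math.degrees(fid.colatitude),
        provenance=provenance,
    )
    return LensAnalysis(
        scene=scene,
        fiduciary=fid,
        sector=sector,
        trapezoid=trapezoid,
        anterior_records=ant_records,
        equatorial_records=eq_records,
        result=result,
    )


def analyze_lens(stacks: StackSet, config: Optional[AnalysisConfig] = None) -> LensAnalysis:
    """Full pipeline on a set of four stacks (2 aspects × 2 channels)."""
    config = config or AnalysisConfig()
    scene = build_scene(stacks, config)
    return count_scene(scene, config)


# ---------------------------------------------------------------------------
# Simulation convenience wrappers
# ---------------------------------------------------------------------------

def simulate_lens_stacks(
    params: LensSimParams, view_azimuth: float = 0.0
) -> Tuple[GroundTruth, StackSet]:
    """Sample a ground-truth lens and render its four stacks."""
    gt = sample_epithelium(params)
    stacks: StackSet = {}
    for aspect in (ASPECT_ANTERIOR, ASPECT_EQUATORIAL):
        for channel in (CHANNEL_DNA, CHANNEL_EDU):
            stacks[(aspect, channel)] = render_stack(
                gt, aspect, view_azimuth=view_azimuth, channel=channel, params=params
            )
    return gt, stacks


def estimate_total(
    params: LensSimParams,
    config: Optional[AnalysisConfig] = None,
    view_azimuth: float = 0.0,
) -> Tuple[LensAnalysis, GroundTruth]:
    """Simulate one lens and run the full counting pipeline on it."""
    gt, stacks = simulate_lens_stacks(params, view_azimuth)
    return analyze_lens(stacks, config), gt
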