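"""EdU-constellation registration between the polar and equatorial views.

The two views are calibrated orthographic projections of the same sphere, so
the only unknowns relating them are the azimuthal offset of the equatorial
viewpoint and an in-plane mirror (the equatorial aspect can be seen from
either side).  Each anterior EdU centroid is inverted to (colatitude,
azimuth) on the fitted sphere; for each candidate view azimuth the anterior
points are forward-projected into the equatorial frame and greedily paired
with equatorial EdU centroids within a distance tolerance.  The rotation
maximising the inlier count (ties broken by lowest mean residual) wins and
is polished by a local least-squares refinement on the inlier pairs.

The fiduciary nucleus — the matched pair marking the cap/band boundary — is
the inlier whose equatorial position is closest to the horizontal centre of
the equatorial projection, so the trapezoid sits in the centre of the view
where longitude lines are nearly straight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from . import geometry
from .detect import NucleusRecord
from .errors import ParameterError, RegistrationError
from .geometry import PlanarPoint

TWO_PI = 2.0 * math.pi


@dataclass
class ConstellationMatch:
    """Accepted pairing between anterior and equatorial EdU records."""

    pairs: List[Tuple[int, int]]  # (anterior record id, equatorial record id)
    view_azimuth: float  # recovered rotation, radians in [0, 2π)
    mirrored: bool
    mean_pair_residual: float  # µm
    lens_radius: float

    @property
    def n_inliers(self) -> int:
        return len(self.pairs)

    def to_dict(self) -> dict:
        return {
            "view_azimuth_deg": math.degrees(self.view_azimuth),
            "mirrored": self.mirrored,
            "n_inliers": self.n_inliers,
            "residual_um": self.mean_pair_residual,
            "pairs": [list(p) for p in self.pairs],
            "lens_radius_um": self.lens_radius,
        }


@dataclass(frozen=True)
class Fiduciary:
    """The matched EdU nucleus marking the cap/band boundary."""

    anterior_position: PlanarPoint
    equatorial_position: PlanarPoint
    colatitude: float
    id_pair: Tuple[int, int]


def _invert_anterior(records: Sequence[NucleusRecord], lens_radius: float,
                     center: Optional[PlanarPoint] = None):
    cx = center.x if center else 0.0
    cy = center.y if center else 0.0
    x = np.array([r.centroid.x - cx for r in records])
    y = np.array([r.centroid.y - cy for r in records])
    rho = np.hypot(x, y)
    colat = np.arcsin(np.clip(rho / lens_radius, 0.0, 1.0))
    az = np.arctan2(y, x)
    return colat, az


def _pair_greedy(proj_xy: np.ndarray, visible: np.ndarray, tree: cKDTree,
                 eq_xy: np.ndarray, tolerance: float):
    """Greedy one-to-one pairing by increasing distance; returns index pairs."""
    vis_idx = np.nonzero(visible)[0]
    if len(vis_idx) == 0:
        return [], 0.0
    d, j = tree.query(proj_xy[vis_idx], k=1, distance_upper_bound=tolerance)
    ok = np.isfinite(d)
    cand = sorted(zip(d[ok], vis_idx[ok], j[ok]))
    used_ant, used_eq = set(), set()
    pairs, dists = [], []
    for dist, ia, ie in cand:
        if ia in used_ant or ie in used_eq:
            continue
        used_ant.add(ia)
        used_eq.add(ie)
        pairs.append((int(ia), int(ie)))
        dists.append(dist)
    mean_resid = float(np.mean(dists)) if dists else math.inf
    return pairs, mean_resid


def match_constellations(
    anterior_edu: Sequence[NucleusRecord],
    equatorial_edu: Sequence[NucleusRecord],
    lens_radius: float,
    tolerance: float = 12.0,
    coarse_step_deg: float = 1.0,
    anterior_center: Optional[PlanarPoint] = None,
    min_inliers: int = 3,
    max_invert_colatitude: float = math.radians(86.0),
) -> ConstellationMatch:
    """Recover the azimuthal offset between the two views from EdU patterns.

    Anterior records projecting beyond ``max_invert_colatitude`` are ignored:
    near the projection rim the inversion ρ → colatitude is amplified by
    1/cos(colatitude), so a µm-scale centroid error there corrupts the
    predicted equatorial height by tens of µm.

    Raises :class:`RegistrationError` when no rotation (in either mirror
    state) achieves ``min_inliers`` paired nuclei — the two stacks then do
    not share a visible germinative-zone field.
    """
    if len(anterior_edu) < 3 or len(equatorial_edu) < 3:
        raise RegistrationError(
            f"need >= 3 EdU records in each view, got {len(anterior_edu)} anterior "
            f"and {len(equatorial_edu)} equatorial"
        )
    if tolerance <= 0:
        raise ParameterError("tolerance must be positive")
    colat_all, az_all = _invert_anterior(anterior_edu, lens_radius, anterior_center)
    usable = colat_all <= max_invert_colatitude
    if usable.sum() < 3:
        raise RegistrationError(
            "fewer than 3 anterior EdU records lie within the invertible "
            "part of the polar projection"
        )
    anterior_edu = [r for r, u in zip(anterior_edu, usable) if u]
    colat, az = colat_all[usable], az_all[usable]
    eq_xy = np.array([(r.centroid.x, r.centroid.y) for r in equatorial_edu])
    tree = cKDTree(eq_xy)
    y_pred = lens_radius * np.cos(colat)  # invariant under rotation

    def score(psi: float, mirror: bool):
        x_pred, _ = geometry.equatorial_project_xy(colat, az, lens_radius, psi, mirror)
        visible = geometry.equatorial_visible(colat, az, psi)
        proj = np.column_stack([x_pred, y_pred])
        return _pair_greedy(proj, visible, tree, eq_xy, tolerance)

    best = None  # (n_inliers, -resid, psi, mirror, pairs, resid)
    step = math.radians(coarse_step_deg)
    for mirror in (False, True):
        for psi in np.arange(0.0, TWO_PI, step):
            pairs, resid = score(float(psi), mirror)
            key = (len(pairs), -resid)
            if best is None or key > best[0]:
                best = (key, float(psi), mirror, pairs, resid)
    if best is None or len(best[3]) < min_inliers:
        n = 0 if best is None else len(best[3])
        raise RegistrationError(
            f"registration failed: best rotation pairs only {n} nuclei "
            f"(need {min_inliers}); the views may not share a germinative-zone field"
        )
    _, psi, mirror, pairs, resid = best

    # Refine: alternate 1-D least squares on the inlier pairs with re-pairing.
    for _ in range(4):
        ia = np.array([p[0] for p in pairs])
        ie = np.array([p[1] for p in pairs])
        cx, ax_ = colat[ia], az[ia]
        target = eq_xy[ie, 0]

        def obj(p):
            xp, _ = geometry.equatorial_project_xy(cx, ax_, lens_radius, p, mirror)
            return float(np.mean((xp - target) ** 2))

        res = minimize_scalar(
            obj, bounds=(psi - 2 * step, psi + 2 * step), method="bounded"
        )
        psi_new = float(res.x)
        pairs_new, resid_new = score(psi_new, mirror)
        if len(pairs_new) < len(pairs):
            break
        improved = len(pairs_new) > len(pairs) or resid_new < resid - 1e-9
        psi, pairs, resid = psi_new, pairs_new, resid_new
        if not improved:
            break

    id_pairs = [
        (anterior_edu[ia].id, equatorial_edu[ie].id) for ia, ie in pairs
    ]
    return ConstellationMatch(
        pairs=id_pairs,
        view_azimuth=psi % TWO_PI,
        mirrored=mirror,
        mean_pair_residual=resid,
        lens_radius=lens_radius,
    )


def select_fiduciary(
    match: ConstellationMatch,
    anterior_edu: Sequence[NucleusRecord],
    equatorial_edu: Sequence[NucleusRecord],
    rank: int = 0,
    max_colatitude: float = math.radians(88.0),
) -> Fiduciary:
    """Select the fiduciary pair: nearest the equatorial projection's centre.

    Among inlier pairs, picks the one with the smallest |equatorial x| (so
    the equatorial sector sits in the centre of the projection); exact ties
    are broken toward larger colatitude (closer to the margin, minimising
    the band sampled in the equatorial view).  Pairs at colatitude above
    ``max_colatitude`` are skipped: at grazing incidence the anterior
    projection of the nucleus is degenerate.  ``rank`` selects the k-th best
    candidate, which gives replicate measurements their independent
    fiduciary choices.
    """
    if match.n_inliers == 0:
        raise RegistrationError("no inlier pairs to select a fiduciary from")
    ant_by_id = {r.id: r for r in anterior_edu}
    eq_by_id = {r.id: r for r in equatorial_edu}
    candidates = []
    for ia, ie in match.pairs:
        eq = eq_by_id[ie]
        colat = geometry.colatitude_from_height(eq.centroid.y, match.lens_radius)
        if colat > max_colatitude:
            continue
        candidates.append((abs(eq.centroid.x), -colat, ia, ie, colat))
    if not candidates:
        raise RegistrationError(
            "no inlier pair below the maximum fiduciary colatitude"
        )
    candidates.sort()
    if rank >= len(candidates):
        rank = len(candidates) - 1
    _, _, ia, ie, colat = candidates[rank]
    return Fiduciary(
        anterior_position=ant_by_id[ia].centroid,
        equatorial_position=eq_by_id[ie].centroid,
        colatitude=colat,
        id_pair=(ia, ie),
    )
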