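# Methods

This note documents the model and the numerical choices behind `lenscount`:
what the measurement assumes, what the synthetic lens emulates (and what it
does not), and where the design was genuinely open.

## Geometry

The lens is modelled as a sphere. Strictly the lens is a slightly oblate
spheroid, but the measurement itself treats it as a sphere — a circle is
fitted to the projected outline — and the package follows that choice; the
resulting latitude errors are well below the other error sources. All
coordinates are physical µm; angles are degrees in configuration files and
radians internally. In equatorial projections, y increases toward the
anterior pole; the origin of every projection is the projection centre.

Two estimates of the lens radius exist and they are *not* interchangeable:

* the **outline circle fit** (Taubin algebraic least squares on the contour
  of the thresholded polar projection) is biased outward by roughly half a
  nucleus diameter, because the contour follows the intensity edge of the
  outermost nuclei, not their centres;
* the **shell sphere fit** (least squares on bright voxels of the
  equatorial stack, with 3σ robust trimming) recovers the surface radius to
  well under a voxel on synthetic data.

The pipeline therefore uses the circle fit for the projection centre and
the reported diameter *D*, but the sphere fit for every quantitative
conversion (ρ ↔ colatitude inversion, trapezoid chord widths, margin
height). Near the projection rim the inversion error is amplified by
1/cos θ, so a few-µm radius bias would otherwise corrupt predicted
equatorial heights by tens of µm and derail the registration.

Both counting regions are closed sets: a centroid exactly on the boundary
is counted. The trapezoid's legs are straight segments (the region is the
isosceles trapezoid that approximates the 10° longitude lune between two
latitudes); summing 36 such chords under-covers the true ring by ≈0.1%,
negligible against counting noise. The 60° sector is anchored with the
fiduciary on its arc at one angular edge (`placement="edge"`); under the
lens's azimuthal symmetry the orientation convention cannot bias the count,
and a bisector-centred mode is available. The sector has no inner exclusion
disk: cells are counted from the projection centre outward.

## Synthetic lens

Defaults are the study conditions: radius 1,250 µm (a 2.5 mm, 8-week mouse
lens), 44,000 epithelial cells, epithelial margin at 95° colatitude,
germinative zone 75–95°, EdU fraction 0.08 in the zone and 0.002 centrally,
9,000 meridional-row nuclei in regular columns over the 5° beyond the
margin, and 4,000 fiber-cell nuclei 40–70 µm beneath the surface in the
lens bow (88–108°). Nuclei are 8 µm across; stacks are rendered at
2.25 µm/pixel laterally (the 1.15 mm / 512 px field of the source imaging)
with 25 µm optical sections of 30 µm axial FWHM.

**Density profile.** The epithelium is sparse centrally and most dense at
the margin. Surface density is flat from the pole to a configurable ramp
start (default 75°, the germinative-zone onset) and rises linearly in
colatitude to `density_gradient` (default 9) at the margin. A pure
linear-in-colatitude profile (`density_ramp_start=0`) is available, but no
purely linear profile can reproduce the observed partition of cells between
cap and band: the band-to-cap ratio of a linear profile is bounded near
0.54, whereas the measured partition (~15,000 cap vs ~25,200 band at a
fiduciary near 80°) requires ≈1.7. The default gradient was set once, from
the closed-form band/cap integral ratio, to reproduce that partition; it is
a calibration of the simulator to the measured partition, not an asserted
biological constant.

**Hard-core point process.** Nuclei are solid bodies in a monolayer, so
positions are sampled with a minimum centre separation (default 6 µm for
8 µm nuclei). Colatitudes are drawn first from the density law — making the
latitude marginal exact by construction — and overlaps are then resolved by
re-proposing azimuths (plus, for stubborn near-margin clusters, a latitude
jitter with σ ≈ the exclusion radius of arc, negligible against band
widths). At the margin the target density is ~80% of the hard-disc jamming
density, so a handful of overlapping doublets (≲0.05%) may survive; they
are kept and logged. `exclusion_radius=0` gives the pure inhomogeneous
random sample, which the distribution tests use.

**Rendering.** Each visible nucleus becomes a blob with lateral FWHM equal
to the nucleus diameter and axial FWHM equal to the optical-section
thickness, plus additive Gaussian noise (σ = 5 on an amplitude of 200,
clipped at zero). The default lateral profile is a solid disc blurred by a
σ = 1.2 µm lateral PSF — a confocal image of a stained nucleus is a
sharp-edged object, since the lateral PSF of a 10× objective is far smaller
than a nucleus. This matters: a *Gaussian* of FWHM 8 µm has such heavy
tails that two nuclei at near-contact spacing merge into a single
unresolvable bump, and no detector could count a germinative zone at
realistic packing; a Gaussian mode (`blob_profile="gaussian"`) is kept for
comparison. Not emulated: depth-dependent attenuation, refraction through
the lens, chromatic effects, nucleus shape variation (margin nuclei in real
lenses elongate), and cell-cycle dynamics. Passing tests therefore show the
*measurement geometry and counting logic* are sound at realistic densities
and noise, not that the detector is robust to every optical artefact of
real confocal data.

## Detection

The detector implements a size-and-brightness contract: local background
subtraction (flat default: the 5th-percentile level; a block-percentile
surface for fluctuating backgrounds), a threshold at
`intensity_above_background` (default 50), Richardson–Lucy deconvolution
(default 50 iterations) with a kernel matched to the expected nucleus image
(disc of `expected_diameter` = 8 µm blurred by the PSF), local maxima at a
minimum separation of 0.3 diameters as markers, and watershed flooding of
the *deconvolved* response within the threshold mask. Flooding the response
rather than the raw intensity makes the tiles of a dense carpet near-Voronoi
cells of the markers, keeping their equivalent diameters inside the accepted
4–16 µm band; flooding the raw intensity produced sliver and double tiles
that the size filter then discarded. Centroids are intensity-weighted
("centre of mass"); a binary-centroid mode exists for sensitivity analysis.

Known limitations, quantified in the tests: pairs closer than ~0.7
diameters may merge (counted as one); in the polar projection the radial
direction is compressed by cos θ, so beyond ~70° colatitude genuinely
unresolvable projected pairs appear and recall falls with θ. Detection
confined to a region of interest crops to the ROI bounding box first
(deconvolution cost scales with area), with a pad so boundary nuclei are
segmented whole.

## Registration and the fiduciary

The two calibrated orthographic views of a sphere differ only by the
equatorial view azimuth ψ and a possible mirror flip. Anterior EdU
centroids are inverted to (θ, φ) on the fitted sphere — records beyond 86°
are excluded from the inversion, where 1/cos θ makes it ill-conditioned —
and a 1° grid over ψ × {unmirrored, mirrored} is scored by greedy
one-to-one pairing against equatorial EdU centroids within a tolerance
(default 12 µm = 1.5 nucleus diameters). The best rotation (most inliers,
ties by residual) is polished by alternating 1-D least squares and
re-pairing. Fewer than 3 inliers raises a registration error: the stacks do
not share a visible germinative-zone field.

The fiduciary is the inlier pair nearest the horizontal centre of the
equatorial projection (so the trapezoid sits where longitude lines are
straightest), ties broken toward larger colatitude, restricted to
colatitude ≤ 80°. The restriction is a deliberate convention: the fiduciary
sets the cap/band partition, and keeping it in the lower germinative zone
leaves the anterior sector inside the part of the polar projection where
nuclei are still resolvable, while the equatorial view — which images the
dense pre-equatorial band face-on — covers the rest. Its colatitude is
computed from the equatorial height (arccos(y/R)), and the sector radius
from that same colatitude (ρ = R sin θ), so cap and band are complementary
by construction; using the raw anterior centroid distance instead would let
a few-µm localisation error at high colatitude shift the partition by
degrees of latitude. Replicate measurements of a lens re-run the counting
stage with the next-ranked fiduciary and a rotated sector.

## Extrapolation and error budget

Sector counts are multiplied by 360/angle and rounded only at that final
step (intermediate rounding would bias the ×36 band extrapolation). The
replicate-spread statistic is the symmetric relative difference
|e₁−e₂| / mean(e₁,e₂) × 100, summarised as mean ± SD over pairs.

On synthetic lenses at the default study conditions the estimator carries:
(i) sampling noise from counting 1/6 and 1/36 of the population (≈2% and
≈4% SD respectively); (ii) a small negative detection bias concentrated in
the outer anterior annulus and the dense margin; (iii) sub-1% geometry
errors (registration ~0.1°, radius ~0.1%). The acceptance suite measures
the combined effect as the mean absolute error of the recovered total over
20 seeded lenses (gate: ≤10%) and reports replicate spread alongside.

## Problem sizes

Full-scale validation uses the default 2.5 mm lens (≈57,000 rendered
nuclei; anterior stacks ≈1140² × 53 voxels at 2.25 µm laterally / 25 µm
axially). Unit tests run a geometrically identical 0.8 mm lens (4,500
epithelial cells) at the same surface density, which exercises every code
path in about a second per lens. Registration fidelity is assessed on
idealised ground-truth records (localisation jitter σ = 1 µm) to isolate it
from detection.
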