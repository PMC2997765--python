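import math

import numpy as np
import pytest
from scipy import stats
from scipy.spatial import cKDTree

from lenscount import (
    LensSimParams,
    render_stack,
    sample_epithelium,
    true_count_in_region,
)
from lenscount import geometry as G
from lenscount.errors import ParameterError
from lenscount.geometry import PlanarPoint
from lenscount.synthetic import (
    CLS_EPITHELIAL,
    CLS_FIBER,
    CLS_MERIDIONAL,
    _unit_xyz,
    lateral_blob_profile,
)
from tests.conftest import small_lens_params


def quick_params(**overrides):
    base = dict(
        lens_radius=625.0,
        n_epithelial=1000,
        n_meridional=100,
        n_fiber=50,
        exclusion_radius=0.0,
        seed=7,
    )
    base.update(overrides)
    return LensSimParams(**base)


class TestSampling:
    def test_exact_counts_and_determinism(self):
        params = quick_params()
        gt = sample_epithelium(params)
        assert gt.class_counts() == {
            CLS_EPITHELIAL: 1000,
            CLS_MERIDIONAL: 100,
            CLS_FIBER: 50,
        }
        gt2 = sample_epithelium(quick_params())
        for field in ("colatitude", "azimuth", "depth", "edu"):
            assert np.array_equal(getattr(gt, field), getattr(gt2, field))

    def test_invalid_zone_bounds_rejected(self):
        with pytest.raises(ParameterError):
            sample_epithelium(
                quick_params(germinative_zone=(math.radians(80), math.radians(70)))
            )
        with pytest.raises(ParameterError):
            sample_epithelium(quick_params(edu_fraction_gz=1.5))

    def test_flat_gradient_matches_uniform_cap_law(self):
        """With density_gradient=1 the colatitude law is uniform-on-cap.

        Checked against the analytic cap CDF (1-cos θ)/(1-cos θ_m) by a KS
        test at α = 0.01, n = 10,000.
        """
        params = quick_params(n_epithelial=10_000, density_gradient=1.0)
        gt = sample_epithelium(params)
        colat = gt.colatitude[gt.mask(cls=CLS_EPITHELIAL)]
        cm = math.cos(params.margin_colatitude)

        def cdf(theta):
            return (1.0 - np.cos(theta)) / (1.0 - cm)

        res = stats.ks_1samp(colat, cdf)
        assert res.pvalue > 0.01

    def test_edu_fraction_within_binomial_bound(self):
        params = quick_params(n_epithelial=20_000)
        gt = sample_epithelium(params)
        ep = gt.mask(cls=CLS_EPITHELIAL)
        lo, hi = params.germinative_zone
        in_gz = ep & (gt.colatitude >= lo) & (gt.colatitude <= hi)
        n, p = int(in_gz.sum()), params.edu_fraction_gz
        assert n > 5000
        edu = int((gt.edu & in_gz).sum())
        assert abs(edu - n * p) <= 3 * math.sqrt(n * p * (1 - p))

    @staticmethod
    def _band_density(params):
        gt = sample_epithelium(params)
        colat = gt.colatitude[gt.mask(cls=CLS_EPITHELIAL)]
        edges = np.linspace(0.0, params.margin_colatitude, 11)
        counts, _ = np.histogram(colat, edges)
        areas = np.cos(edges[:-1]) - np.cos(edges[1:])
        return counts, counts / areas

    def test_linear_profile_density_nondecreasing_toward_margin(self):
        """Linear-profile density per unit area rises pole→margin (≤1 inversion)."""
        params = quick_params(n_epithelial=25_000, density_ramp_start=0.0)
        _, density = self._band_density(params)
        assert int((np.diff(density) < 0).sum()) <= 1

    def test_default_profile_density_nondecreasing_beyond_noise(self):
        """Default ramp profile: any inversion is within counting noise."""
        params = quick_params(n_epithelial=25_000)
        counts, density = self._band_density(params)
        rel_noise = 3.0 / np.sqrt(np.maximum(counts[:-1], 1))
        assert np.all(density[1:] >= density[:-1] * (1.0 - rel_noise))

    def test_hard_core_exclusion_is_respected(self):
        params = quick_params(n_epithelial=4000, exclusion_radius=6.0)
        gt = sample_epithelium(params)
        ep = gt.mask(cls=CLS_EPITHELIAL)
        xyz = _unit_xyz(gt.colatitude[ep], gt.azimuth[ep]) * params.lens_radius
        pairs = cKDTree(xyz).query_pairs(6.0)
        assert len(pairs) <= max(2, int(5e-4 * 4000))

    def test_class_placement_invariants(self):
        params = quick_params()
        gt = sample_epithelium(params)
        ep = gt.mask(cls=CLS_EPITHELIAL)
        mer = gt.mask(cls=CLS_MERIDIONAL)
        fib = gt.mask(cls=CLS_FIBER)
        assert gt.colatitude[ep].max() <= params.margin_colatitude
        assert np.all(gt.depth[ep] == 0)
        assert gt.colatitude[mer].min() >= params.margin_colatitude - 1e-9
        assert gt.depth[fib].min() >= params.fiber_depth


class TestTrueCountOracle:
    def test_empty_ground_truth_counts_zero(self):
        gt = sample_epithelium(quick_params(n_epithelial=0, n_meridional=0, n_fiber=0))
        sector = G.AnteriorSector(PlanarPoint(0, 0), 500.0, 0.0, math.pi / 3)
        assert true_count_in_region(gt, sector) == 0

    def test_full_disk_sector_counts_anterior_hemisphere(self):
        params = quick_params()
        gt = sample_epithelium(params)
        sector = G.AnteriorSector(
            PlanarPoint(0, 0), params.lens_radius, 0.0, 2 * math.pi
        )
        ep = gt.mask(cls=CLS_EPITHELIAL)
        expected = int((gt.colatitude[ep] <= math.pi / 2).sum())
        assert true_count_in_region(gt, sector) == expected

    def test_restates_per_nucleus_membership(self):
        params = quick_params()
        gt = sample_epithelium(params)
        sector = G.AnteriorSector(PlanarPoint(10.0, -5.0), 400.0, 1.1, math.pi / 3)
        brute = 0
        ep = gt.mask(cls=CLS_EPITHELIAL)
        for i in np.nonzero(ep)[0]:
            if gt.colatitude[i] > math.pi / 2:
                continue
            q = G.polar_project(
                G.SphericalPoint(gt.colatitude[i], gt.azimuth[i], params.lens_radius)
            )
            brute += G.point_in_sector(q, sector)
        assert true_count_in_region(gt, sector) == brute


class TestRendering:
    def test_single_nucleus_peaks_at_its_voxel(self):
        params = quick_params(
            n_epithelial=1, n_meridional=0, n_fiber=0, noise_sd=0.0
        )
        gt = sample_epithelium(params)
        stack = render_stack(gt, "anterior", 0.0, "dna", params)
        k, r, c = np.unravel_index(np.argmax(stack.data), stack.data.shape)
        x, y = G.polar_project_xy(gt.colatitude[0], gt.azimuth[0], params.lens_radius)
        assert abs(stack.x_coords()[c] - x) <= params.voxel_size
        assert abs(stack.y_coords()[r] - y) <= params.voxel_size
        z = params.lens_radius * math.cos(gt.colatitude[0])
        assert abs(stack.z_coords()[k] - z) <= params.z_step

    def test_zero_nuclei_noise_free_stack_is_blank(self):
        params = quick_params(n_epithelial=0, n_meridional=0, n_fiber=0, noise_sd=0.0)
        gt = sample_epithelium(params)
        stack = render_stack(gt, "equatorial", 0.0, "dna", params)
        assert float(np.abs(stack.data).max()) == 0.0

    def test_two_distant_nuclei_give_two_local_maxima(self):
        params = quick_params(n_epithelial=2, n_meridional=0, n_fiber=0, noise_sd=0.0)
        gt = sample_epithelium(params)
        # Place them explicitly 5 diameters apart near the pole.
        gt.colatitude[:] = [0.01, 0.01 + 5 * 8.0 / params.lens_radius]
        gt.azimuth[:] = [0.0, 0.0]
        stack = render_stack(gt, "anterior", 0.0, "dna", params)
        proj = stack.data.max(axis=0)
        from skimage.feature import peak_local_max

        peaks = peak_local_max(proj, min_distance=2)
        assert len(peaks) == 2
        got = {
            (stack.x_coords()[c], stack.y_coords()[r]) for r, c in peaks
        }
        for colat, az in zip(gt.colatitude, gt.azimuth):
            x, y = G.polar_project_xy(colat, az, params.lens_radius)
            assert any(
                math.hypot(gx - x, gy - y) <= 2 * params.voxel_size for gx, gy in got
            )

    def test_edu_channel_renders_only_edu_positive(self):
        params = quick_params(noise_sd=0.0)
        gt = sample_epithelium(params)
        if not gt.edu.any():  # force at least one positive
            gt.edu[0] = True
        edu_stack = render_stack(gt, "anterior", 0.0, "edu", params)
        dna_stack = render_stack(gt, "anterior", 0.0, "dna", params)
        assert edu_stack.data.sum() < dna_stack.data.sum()
        assert edu_stack.data.max() > 0

    def test_rendering_is_bit_deterministic(self):
        params = quick_params(n_epithelial=200)
        gt = sample_epithelium(params)
        a = render_stack(gt, "equatorial", 0.3, "dna", params)
        b = render_stack(gt, "equatorial", 0.3, "dna", params)
        assert np.array_equal(a.data, b.data)

    def test_blob_profile_fwhm_matches_diameter(self):
        for profile in ("disc", "gaussian"):
            half = lateral_blob_profile(4.0, 8.0, 1.2, profile)
            assert half == pytest.approx(0.5, abs=1e-9)


def test_small_lens_fixture_is_consistent(small_gt, small_params):
    counts = small_gt.class_counts()
    assert counts[CLS_EPITHELIAL] == small_params.n_epithelial
    assert counts[CLS_MERIDIONAL] == small_params.n_meridional
    assert counts[CLS_FIBER] == small_params.n_fiber


def test_ground_truth_csv_round_trip(tmp_path, small_gt, small_params):
    path = tmp_path / "gt.csv"
    small_gt.to_csv(path)
    from lenscount.synthetic import GroundTruth

    loaded = GroundTruth.from_csv(path, small_params)
    assert np.allclose(loaded.colatitude, small_gt.colatitude)
    assert np.array_equal(loaded.edu, small_gt.edu)
    assert list(loaded.cls) == list(small_gt.cls)
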