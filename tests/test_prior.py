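import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.special import ndtr

from risp import (
    ChannelData,
    ImageGrid,
    ReconImage,
    build_prior,
    coherence_map,
    gaussian_cdf,
    make_disk_phantom,
    make_subset_plan,
    prior_integral,
    probability_map,
    simulate_channel_data,
)
from risp.prior import CoherenceMap


def _images(grid, stack):
    return [ReconImage(grid, arr) for arr in stack]


TINY = ImageGrid((1, 2), (1.0, 1.0))


class TestSubsetPlan:
    def test_plan_shape_matches_request(self):
        plan = make_subset_plan(256, 80, 100, seed=3)
        assert plan.k == 100
        assert all(len(set(sub)) == 80 for sub in plan.subsets)
        assert all(0 <= i < 256 for sub in plan.subsets for i in sub)

    def test_s_must_be_below_n(self):
        assert make_subset_plan(10, 9, 2, seed=0).s == 9
        with pytest.raises(ValueError):
            make_subset_plan(10, 10, 2, seed=0)

    def test_same_seed_same_plan(self):
        assert make_subset_plan(64, 8, 30, seed=5) == make_subset_plan(64, 8, 30, seed=5)

    def test_disjoint_mode_partitions_elements(self):
        plan = make_subset_plan(64, 8, 8, seed=2, disjoint=True)
        flat = [i for sub in plan.subsets for i in sub]
        assert sorted(flat) == list(range(64))

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            make_subset_plan(64, 8, 1, seed=0)


class TestCoherenceMap:
    def test_identical_nonzero_images_have_unit_coherence(self, small_grid):
        imgs = _images(small_grid, [np.full(small_grid.shape, 2.5)] * 4)
        assert np.all(coherence_map(imgs).D == 1.0)

    def test_two_image_example(self):
        # pixel values {1, 3}: D = (1+3)^2 / (2*(1+9)) = 0.8
        imgs = _images(TINY, [np.array([[1.0, 1.0]]), np.array([[3.0, -1.0]])])
        coh = coherence_map(imgs)
        assert coh.D[0, 0] == pytest.approx(0.8, abs=1e-15)
        # {1, -1}: numerator cancels
        assert coh.D[0, 1] == 0.0

    def test_all_zero_pixels_get_zero(self, small_grid):
        imgs = _images(small_grid, [np.zeros(small_grid.shape)] * 3)
        coh = coherence_map(imgs)
        assert np.all(coh.D == 0.0)

    def test_statistics_match_field(self, rng, small_grid):
        imgs = _images(small_grid, rng.normal(size=(5, *small_grid.shape)))
        coh = coherence_map(imgs)
        assert coh.vmin == coh.D.min() and coh.vmax == coh.D.max()
        assert coh.mu == (coh.vmax + coh.vmin) / 2
        assert coh.sigma == (coh.vmax - coh.vmin) / 6

    @given(
        k=st.integers(2, 10),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_coherence_bounded_by_cauchy_schwarz(self, k, seed):
        r = np.random.default_rng(seed)
        stack = r.normal(size=(k, 16, 16))
        coh = coherence_map(_images(ImageGrid((16, 16), (1.0, 1.0)), stack))
        assert np.all(coh.D >= 0.0) and np.all(coh.D <= 1.0)

    def test_mismatched_grids_rejected(self, small_grid):
        other = ImageGrid((32, 32), (1.0, 1.0))
        with pytest.raises(ValueError):
            coherence_map(
                [
                    ReconImage(small_grid, np.zeros(small_grid.shape)),
                    ReconImage(other, np.zeros(other.shape)),
                ]
            )


class TestGaussianCdf:
    def test_symmetry_and_one_sigma(self):
        assert gaussian_cdf(0.5, 0.5, 0.1) == pytest.approx(0.5, abs=1e-15)
        assert gaussian_cdf(0.6, 0.5, 0.1) == pytest.approx(0.841344746, abs=1e-9)

    def test_limits(self):
        assert gaussian_cdf(-1e12, 0.0, 1.0) == pytest.approx(0.0, abs=1e-15)
        assert gaussian_cdf(1e12, 0.0, 1.0) == pytest.approx(1.0, abs=1e-15)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_cdf(0.0, 0.0, 0.0)


class TestPriorIntegral:
    def test_upper_limit_at_vmax_gives_half_range(self):
        # symmetry of the CDF about mu makes the full integral (vmax-vmin)/2
        assert prior_integral(1.0, 0.0, 1.0, 0.5, 1 / 6) == pytest.approx(0.5, abs=1e-12)

    def test_lower_limit_gives_zero(self):
        assert prior_integral(0.0, 0.0, 1.0, 0.5, 1 / 6) == pytest.approx(0.0, abs=1e-15)

    def test_midpoint_value_matches_quadrature_oracle(self):
        assert prior_integral(0.5, 0.0, 1.0, 0.5, 1 / 6) == pytest.approx(
            0.06642668768, abs=1e-9
        )

    def test_matches_adaptive_quadrature_on_random_triples(self, rng):
        for _ in range(200):
            vmin, width = rng.uniform(-1, 1), rng.uniform(1e-3, 2)
            vmax = vmin + width
            d = rng.uniform(vmin, vmax)
            mu, sigma = (vmax + vmin) / 2, width / 6
            expected, _ = integrate.quad(lambda v: ndtr((v - mu) / sigma), vmin, d)
            assert prior_integral(d, vmin, vmax, mu, sigma) == pytest.approx(
                expected, abs=1e-8
            )

    def test_d_outside_range_rejected(self):
        with pytest.raises(ValueError):
            prior_integral(1.5, 0.0, 1.0, 0.5, 1 / 6)


class TestProbabilityMap:
    def test_two_pixel_example(self):
        coh = CoherenceMap(TINY, np.array([[0.0, 1.0]]), 0.0, 1.0, 0.5, 1 / 6)
        pmap = probability_map(coh)
        np.testing.assert_allclose(pmap.P, [[0.0, 0.5]], atol=1e-12)
        np.testing.assert_allclose(pmap.Pnorm, [[0.0, 1.0]], atol=1e-12)

    def test_pnorm_preserves_coherence_ordering(self, rng):
        D = rng.uniform(size=(8, 8))
        vmin, vmax = float(D.min()), float(D.max())
        coh = CoherenceMap(
            ImageGrid((8, 8), (1.0, 1.0)), D, vmin, vmax, (vmax + vmin) / 2, (vmax - vmin) / 6
        )
        pmap = probability_map(coh)
        order = np.argsort(D.ravel())
        assert np.all(np.diff(pmap.Pnorm.ravel()[order]) >= -1e-15)

    def test_matches_brute_force_quadrature_pipeline(self, rng):
        """Every pixel recomputed with numerical quadrature instead of the closed form."""
        D = rng.uniform(size=(8, 8))
        vmin, vmax = float(D.min()), float(D.max())
        mu, sigma = (vmax + vmin) / 2, (vmax - vmin) / 6
        coh = CoherenceMap(ImageGrid((8, 8), (1.0, 1.0)), D, vmin, vmax, mu, sigma)
        pmap = probability_map(coh)
        P = np.empty_like(D)
        for i in range(8):
            for j in range(8):
                q, _ = integrate.quad(
                    lambda v: ndtr((v - mu) / sigma), vmin, D[i, j], epsabs=1e-12
                )
                P[i, j] = D[i, j] * q
        pnorm = (P - P.min()) / (P.max() - P.min())
        np.testing.assert_allclose(pmap.Pnorm, pnorm, atol=1e-6)

    def test_constant_coherence_gives_inert_prior(self, small_grid):
        coh = CoherenceMap(small_grid, np.full(small_grid.shape, 0.4), 0.4, 0.4, 0.4, 0.0)
        pmap = probability_map(coh)
        np.testing.assert_array_equal(pmap.Pnorm, 1.0)


class TestBuildPrior:
    def test_point_source_gets_high_probability(self, centered_point_data, odd_grid):
        data, phantom = centered_point_data
        plan = make_subset_plan(32, 8, 20, seed=11)
        pmap = build_prior(data, odd_grid, plan, algo="ubp")
        assert pmap.Pnorm[32, 32] >= 0.9

    def test_prior_localizes_on_signal_but_not_on_noise(
        self, centered_point_data, odd_grid, ring32, acq, rng
    ):
        """The prior concentrates around a true source; pure noise gives a
        spatially indifferent map (no preferred region).

        Note the *global* mean of Pnorm does not separate the two cases:
        overlapping subsets share elements, which floors the coherence of
        even pure noise near s/N everywhere. Localization does separate
        them.
        """
        data, _ = centered_point_data
        plan = make_subset_plan(32, 8, 20, seed=11)
        p_source = build_prior(data, odd_grid, plan, algo="ubp")
        noise = ChannelData(rng.normal(size=(32, 256)), ring32, acq)
        p_noise = build_prior(noise, odd_grid, plan, algo="ubp")

        def concentration(pmap):
            return pmap.Pnorm[30:35, 30:35].mean() / pmap.Pnorm.mean()

        assert concentration(p_source) > 2.0
        assert concentration(p_noise) < 1.5
        assert p_noise.Pnorm[32, 32] < p_source.Pnorm[32, 32]

    def test_fixed_seed_is_bit_identical(self, ring_data, small_grid):
        plan = make_subset_plan(32, 8, 10, seed=3)
        a = build_prior(ring_data, small_grid, plan)
        b = build_prior(ring_data, small_grid, plan)
        np.testing.assert_array_equal(a.Pnorm, b.Pnorm)

    def test_subset_image_matches_direct_reconstruction(self, ring_data, small_grid):
        """The per-element shortcut reproduces a direct subset reconstruction."""
        from risp import ubp_reconstruct
        from risp.prior import coherence_map as _cm

        plan = make_subset_plan(32, 8, 2, seed=3)
        pmap_fast = build_prior(ring_data, small_grid, plan)
        imgs = [
            ubp_reconstruct(ring_data, small_grid, list(sub)) for sub in plan.subsets
        ]
        pmap_direct = probability_map(_cm(imgs))
        np.testing.assert_allclose(pmap_fast.Pnorm, pmap_direct.Pnorm, atol=1e-10)

    def test_plan_geometry_mismatch_rejected(self, ring_data, small_grid):
        plan = make_subset_plan(64, 8, 5, seed=0)
        with pytest.raises(ValueError):
            build_prior(ring_data, small_grid, plan)
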