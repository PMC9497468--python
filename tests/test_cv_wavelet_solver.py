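"""Chan-Vese ingredients, the Shannon-Cosine interval basis, homotopy
stepping and the two segmentation solvers."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bendseg.cv_wavelet_solver import (
    CollapsedContourError,
    CVParams,
    WaveletBasis,
    boundary_mask_from_coefficients,
    curvature_term,
    cv_energy,
    cv_rhs,
    homotopy_step,
    interval_weights,
    region_means,
    regularized_delta,
    segment,
    segment_cv_reference,
    shannon_cosine,
    signed_distance,
    wavelet_compress,
    wavelet_decompose,
    wavelet_reconstruct,
)


class TestDelta:
    def test_peak_value(self):
        assert regularized_delta(np.zeros(1), 1.0)[0] == pytest.approx(1 / np.pi)

    def test_vanishes_far_from_zero(self):
        assert regularized_delta(np.array([1e6]), 1.0)[0] < 1e-9

    def test_integrates_to_one(self):
        phi = np.linspace(-2000, 2000, 2_000_001)
        val = np.trapezoid(regularized_delta(phi, 1.3), phi)
        assert val == pytest.approx(1.0, abs=1e-3)


class TestRegionMeans:
    def test_two_phase_disc(self):
        yy, xx = np.mgrid[0:64, 0:64]
        phi = 14.0 - np.hypot(yy - 31.5, xx - 31.5)
        img = np.where(phi >= 0, 0.2, 0.8)
        c1, c2 = region_means(img, phi)
        assert (c1, c2) == (pytest.approx(0.2), pytest.approx(0.8))

    def test_constant_image(self):
        yy, xx = np.mgrid[0:16, 0:16]
        phi = 5.0 - np.hypot(yy - 8, xx - 8)
        c1, c2 = region_means(np.full((16, 16), 0.4), phi)
        assert c1 == pytest.approx(0.4)
        assert c2 == pytest.approx(0.4)

    def test_matches_masked_means(self):
        rng = np.random.default_rng(0)
        img = rng.random((20, 20))
        phi = rng.standard_normal((20, 20))
        c1, c2 = region_means(img, phi)
        assert c1 == pytest.approx(img[phi >= 0].mean())
        assert c2 == pytest.approx(img[phi < 0].mean())

    def test_collapsed_contour_signalled(self):
        with pytest.raises(CollapsedContourError):
            region_means(np.ones((8, 8)), np.ones((8, 8)))


class TestCurvatureTerm:
    def test_circle_curvature_near_zero_level(self):
        yy, xx = np.mgrid[0:64, 0:64]
        r = 12.0
        phi = r - np.hypot(yy - 31.5, xx - 31.5)
        kappa = curvature_term(phi)
        ring = np.abs(phi) < 1.0
        # sign convention: interior positive phi gives curvature -1/r on the ring
        assert np.median(np.abs(kappa[ring])) == pytest.approx(1 / r, rel=0.15)

    def test_planar_phi_has_zero_curvature(self):
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        kappa = curvature_term(0.3 * yy - 0.7 * xx + 2.0)
        assert np.abs(kappa[2:-2, 2:-2]).max() < 1e-10

    def test_sign_flip_is_odd(self):
        rng = np.random.default_rng(1)
        from scipy import ndimage

        phi = ndimage.gaussian_filter(rng.standard_normal((32, 32)), 2)
        assert np.allclose(curvature_term(-phi), -curvature_term(phi), atol=1e-8)


class TestCvRhs:
    def test_stationary_two_phase_flat_interface(self):
        """With symmetric weights the forces balance on an anti-aliased
        interface row, where the intensity sits midway between the means."""
        img = np.zeros((33, 32))
        img[:16] = 0.8
        img[16] = 0.5
        img[17:] = 0.2
        yy = np.mgrid[0:33, 0:32][0].astype(float)
        phi = 16.0 - yy
        params = CVParams(mu=0.0)
        rhs = cv_rhs(img, phi, params, means=(0.8, 0.2))
        assert np.abs(rhs[16]).max() < 1e-12

    def test_zero_lambdas_leave_pure_length_flow(self):
        rng = np.random.default_rng(2)
        from scipy import ndimage

        img = rng.random((32, 32))
        phi = ndimage.gaussian_filter(rng.standard_normal((32, 32)), 3)
        with pytest.raises(ValueError):
            CVParams(lambda1=0.0)  # contract: data weights strictly positive
        # isolate the length term by equal region weights on a constant image
        params = CVParams(mu=0.7)
        rhs = cv_rhs(np.full((32, 32), 0.5), phi, params)
        expected = regularized_delta(phi, params.eps) * params.mu * curvature_term(phi)
        assert np.allclose(rhs, expected, atol=1e-12)

    def test_rhs_equals_sum_of_terms(self):
        rng = np.random.default_rng(3)
        from scipy import ndimage

        img = rng.random((24, 24))
        phi = ndimage.gaussian_filter(rng.standard_normal((24, 24)), 2)
        params = CVParams(mu=0.3, lambda1=1.2, lambda2=0.8)
        c1, c2 = region_means(img, phi)
        oracle = regularized_delta(phi, params.eps) * (
            params.mu * curvature_term(phi)
            - params.lambda1 * (img - c1) ** 2
            + params.lambda2 * (img - c2) ** 2
        )
        assert np.allclose(cv_rhs(img, phi, params), oracle)


class TestShannonCosineBasis:
    def test_interpolation_property_on_grid(self):
        basis = WaveletBasis()
        assert shannon_cosine(0.5, basis, 4, 8) == pytest.approx(1.0)
        for k in (5, 6, 7, 9, 10):
            assert shannon_cosine(k / 16, basis, 4, 8) == pytest.approx(0.0, abs=1e-12)

    def test_compact_support(self):
        basis = WaveletBasis()
        # support is |t| < N/2 in grid units
        assert shannon_cosine(8 / 16 + 3.2 / 16, basis, 4, 8) == 0.0

    def test_window_weights_sum_to_one(self):
        basis = WaveletBasis()
        assert sum(basis.cosine_weights) == pytest.approx(1.0)

    def test_interval_weights_interpolate(self):
        basis = WaveletBasis()
        j = 4
        for k in (0, 1, 7, 15, 16):
            assert interval_weights(k, j, k / 16, basis) == pytest.approx(1.0)

    def test_partition_of_unity_at_collocation_midpoints(self):
        basis = WaveletBasis()
        j = 4
        mids = (np.arange(2**j) + 0.5) / 2**j
        total = sum(interval_weights(k, j, mids, basis) for k in range(2**j + 1))
        assert np.abs(total - 1.0).max() < 1e-6

    def test_out_of_range_node_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            interval_weights(20, 4, 0.5, WaveletBasis())


class TestWaveletDecomposition:
    def test_bilinear_functions_have_no_details(self):
        basis = WaveletBasis()
        nodes = basis.level_nodes(6)
        yy, xx = np.meshgrid(nodes, nodes, indexing="ij")
        f = 0.3 + 1.7 * yy - 0.4 * xx + 2.2 * yy * xx
        dec = wavelet_decompose(f, basis)
        assert dec.max_detail() < 1e-8

    def test_round_trip_is_identity(self):
        basis = WaveletBasis()
        rng = np.random.default_rng(4)
        f = rng.random((65, 65))
        rec = wavelet_reconstruct(wavelet_decompose(f, basis))
        assert np.abs(rec - f).max() < 1e-10

    def test_sharp_ridge_concentrates_details(self):
        basis = WaveletBasis()
        nodes = basis.level_nodes(6)
        yy, xx = np.meshgrid(nodes, nodes, indexing="ij")
        f = np.tanh((xx - 0.5) * 80)
        dec = wavelet_decompose(f, basis)
        for j, (a1, a2, a3) in dec.details.items():
            # significant details stay within ~2 level-j cells of the ridge
            tol = 2.5 * 2.0**-j
            for arr in (a1, a2, a3):
                big = np.abs(arr) > 0.05 * dec.max_detail()
                if big.any():
                    col_pos = np.where(big)[1] / (arr.shape[1] - 1 or 1)
                    assert np.abs(col_pos - 0.5).max() < tol

    def test_non_dyadic_grid_rejected(self):
        with pytest.raises(ValueError, match="dyadic"):
            wavelet_decompose(np.zeros((64, 64)), WaveletBasis())


class TestBoundaryMask:
    def test_flags_hug_the_interface(self):
        basis = WaveletBasis()
        yy, xx = np.meshgrid(np.arange(65), np.arange(65), indexing="ij")
        phi = np.tanh((20.0 - np.hypot(yy - 32.0, xx - 32.0)) / 3.0)
        pts = boundary_mask_from_coefficients(wavelet_decompose(phi, basis), 0.95)
        assert len(pts)
        dist = np.abs(np.hypot(pts[:, 0] - 32, pts[:, 1] - 32) - 20.0)
        # flagged points live within ~2 cells of the contour at their own
        # level; the coarsest detail level here has 8-cell spacing
        assert dist.max() <= 16.0
        assert np.median(dist) <= 4.0

    def test_constant_phi_flags_nothing(self):
        basis = WaveletBasis()
        dec = wavelet_decompose(np.ones((65, 65)), basis)
        assert len(boundary_mask_from_coefficients(dec, 0.5)) == 0

    def test_threshold_monotonicity(self):
        basis = WaveletBasis()
        rng = np.random.default_rng(5)
        dec = wavelet_decompose(rng.random((65, 65)), basis)
        n_low = len(boundary_mask_from_coefficients(dec, 0.80))
        n_high = len(boundary_mask_from_coefficients(dec, 0.95))
        assert n_high <= n_low


class TestHomotopyStep:
    def test_stationary_rhs_is_fixed_point(self):
        rng = np.random.default_rng(6)
        phi = rng.random((16, 16))
        out = homotopy_step(None, phi, CVParams(), rhs=lambda t, p: np.zeros_like(p))
        assert np.array_equal(out, phi)

    def test_linear_in_time_rhs_is_exact(self):
        """Trapezoidal steps integrate phi' = a + b t exactly."""
        rng = np.random.default_rng(7)
        a = rng.random((8, 8))
        b = rng.random((8, 8))
        phi0 = rng.random((8, 8))
        params = CVParams(dt=0.25, normalize_force=False)
        phi = phi0.copy()
        t = 0.0
        for _ in range(8):
            phi = homotopy_step(None, phi, params, rhs=lambda tt, p: a + b * tt, t=t)
            t += params.dt
        exact = phi0 + a * t + 0.5 * b * t * t
        assert np.abs(phi - exact).max() < 1e-12

    def test_second_order_convergence(self):
        """Halving dt cuts the error on a manufactured flow by ~4x."""
        rng = np.random.default_rng(8)
        phi0 = rng.random((12, 12))
        amp = rng.random((12, 12))
        rhs = lambda t, p: amp * np.cos(t) - p  # noqa: E731

        def integrate(dt, T=1.0):
            phi, t = phi0.copy(), 0.0
            params = CVParams(dt=dt, normalize_force=False)
            while t < T - 1e-12:
                phi = homotopy_step(None, phi, params, rhs=rhs, t=t)
                t += dt
            return phi

        ref = integrate(1 / 512)
        e1 = np.abs(integrate(1 / 8) - ref).max()
        e2 = np.abs(integrate(1 / 16) - ref).max()
        assert 3.5 <= e1 / e2 <= 4.5

    def test_energy_decreases_on_disc_phantom(self, disc_phantom_64):
        img, _ = disc_phantom_64
        yy, xx = np.mgrid[0:64, 0:64]
        phi = 19.0 - np.hypot(yy - 31.5, xx - 31.5)
        params = CVParams()
        e0 = cv_energy(img, phi, params)
        for _ in range(5):
            phi = homotopy_step(img, phi, params)
        assert cv_energy(img, phi, params) <= e0 + 1e-9


class TestSegment:
    def test_clean_disc_is_recovered(self, disc_phantom_64):
        from bendseg.evaluation import dice_score

        img, truth = disc_phantom_64
        res = segment(img)
        assert dice_score(res.mask, truth) >= 0.98

    def test_blurred_low_contrast_blob(self):
        from scipy import ndimage

        from bendseg.evaluation import dice_score

        rng = np.random.default_rng(1)
        yy, xx = np.mgrid[0:64, 0:64]
        sdf = 14.0 - np.hypot(yy - 31.5, xx - 31.5)
        img = 0.25 + 0.1 * (0.5 * (1 + np.tanh(sdf)))
        img = ndimage.gaussian_filter(img, 2.0)
        img = np.clip(img + 0.02 * rng.standard_normal((64, 64)), 0, 1)
        res = segment(img, params=CVParams(mu=0.02))
        assert dice_score(res.mask, sdf >= 0) >= 0.90

    def test_constant_image_collapses_gracefully(self):
        res = segment(np.full((64, 64), 0.5))
        assert res.collapsed
        assert not res.mask.any()

    def test_energy_trace_monotone_on_noiseless_phantom(self, disc_phantom_64):
        img, _ = disc_phantom_64
        res = segment(img)
        e = np.array(res.energy_trace)
        rel_up = np.diff(e) / np.abs(e[:-1])
        assert rel_up.max() <= 1e-6

    def test_solvers_agree_across_seeds_and_contrasts(self):
        agreements = []
        for seed in (0, 1, 2):
            for contrast in (0.5, 0.2):
                rng = np.random.default_rng(seed)
                yy, xx = np.mgrid[0:64, 0:64]
                sdf = 14.0 - np.hypot(yy - 31.5, xx - 31.5)
                img = 0.25 + contrast * (0.5 * (1 + np.tanh(sdf)))
                img = np.clip(img + 0.01 * rng.standard_normal((64, 64)), 0, 1)
                a = segment(img).mask
                b = segment_cv_reference(img).mask
                agreements.append(np.mean(a == b))
        assert min(agreements) >= 0.99

    def test_zero_iterations_returns_initialization(self, disc_phantom_64):
        img, _ = disc_phantom_64
        res = segment_cv_reference(img, params=CVParams(max_iter=0))
        yy, xx = np.mgrid[0:64, 0:64]
        init = (0.3 * 64 - np.hypot(yy - 31.5, xx - 31.5)) >= 0
        assert np.array_equal(res.mask, init)

    def test_roi_outside_image_rejected(self, disc_phantom_64):
        img, _ = disc_phantom_64
        with pytest.raises(ValueError, match="roi"):
            segment(img, roi_bbox=(0, 0, 100, 100))

    def test_mask_is_exactly_nonnegative_phi(self, disc_phantom_64):
        img, _ = disc_phantom_64
        res = segment(img)
        y0 = res.phi[res.mask]
        y1 = res.phi[~res.mask]
        assert (y0 >= 0).all() and (y1 < 0).all()


def test_signed_distance_symmetry():
    mask = np.zeros((32, 32), bool)
    mask[10:20, 10:20] = True
    sd = signed_distance(mask)
    assert (sd[mask] > 0).all() and (sd[~mask] < 0).all()


def test_wavelet_compress_preserves_smooth_levelset():
    basis = WaveletBasis()
    yy, xx = np.meshgrid(np.arange(65), np.arange(65), indexing="ij")
    phi = 20.0 - np.hypot(yy - 32.0, xx - 32.0)
    out = wavelet_compress(phi, basis)
    assert np.abs(out - phi).max() < 0.1
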