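import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from scampi import (
    CollinearityError,
    EmptyDesignError,
    GrayscaleImage,
    InsufficientSamplesError,
    InvalidImageError,
    LagSimSpec,
    LagStructure,
    build_lagged_design,
    fit_image,
    fit_ols,
    reconstruct_model_image,
    select_lag_order,
    simulate_lag_image,
    vectorize_image,
)

from oracles import brute_force_design, brute_force_ols


class TestGrayscaleImage:
    def test_rejects_empty(self):
        with pytest.raises(InvalidImageError):
            GrayscaleImage(np.empty((0, 0)))

    def test_rejects_nonfinite(self):
        with pytest.raises(InvalidImageError):
            GrayscaleImage(np.array([[1.0, np.nan], [0.0, 1.0]]))

    def test_rejects_1d(self):
        with pytest.raises(InvalidImageError):
            GrayscaleImage(np.arange(5.0))

    def test_casts_to_float64(self):
        img = GrayscaleImage(np.array([[1, 2], [3, 4]], dtype=np.uint16))
        assert img.pixels.dtype == np.float64


class TestLagStructure:
    def test_order_one_offsets(self):
        assert LagStructure(1).offsets == ((0, 1), (1, 0), (1, 1))

    @pytest.mark.parametrize("L", [1, 2, 3, 4])
    def test_param_count(self, L):
        lags = LagStructure(L)
        assert lags.n_params == (L + 1) ** 2 - 1
        assert len(lags.offsets) == lags.n_params
        assert (0, 0) not in lags.offsets

    def test_rejects_zero_order(self):
        with pytest.raises(ValueError):
            LagStructure(0)


class TestVectorizeImage:
    def test_2x2_column_major(self):
        img = GrayscaleImage(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_array_equal(vectorize_image(img), [1.0, 3.0, 2.0, 4.0])

    def test_length_is_mn(self, rng):
        img = GrayscaleImage(rng.random((7, 11)))
        assert vectorize_image(img).shape == (77,)

    def test_280x280_length(self, rng):
        img = GrayscaleImage(rng.random((280, 280)))
        assert vectorize_image(img).shape == (78400,)

    @given(arrays(np.float64, (4, 5), elements=st.floats(-1e6, 1e6)))
    def test_index_identity(self, px):
        img = GrayscaleImage(px)
        vec = vectorize_image(img)
        m = px.shape[0]
        for i in range(px.shape[0]):
            for j in range(px.shape[1]):
                assert vec[j * m + i] == px[i, j]


class TestBuildLaggedDesign:
    def test_3x3_enumeration(self, tiny_image):
        data = build_lagged_design(tiny_image, LagStructure(1))
        np.testing.assert_array_equal(data.response, [5.0, 8.0, 6.0, 9.0])
        # offset order (0,1), (1,0), (1,1): left, upper, diagonal neighbours
        np.testing.assert_array_equal(data.design[:, 0], [4.0, 7.0, 5.0, 8.0])
        np.testing.assert_array_equal(data.design[:, 1], [2.0, 5.0, 3.0, 6.0])
        np.testing.assert_array_equal(data.design[:, 2], [1.0, 4.0, 2.0, 5.0])

    @pytest.mark.parametrize("shape,L", [((280, 280), 1), ((50, 40), 2), ((9, 17), 3)])
    def test_sizes(self, rng, shape, L):
        img = GrayscaleImage(rng.random(shape))
        data = build_lagged_design(img, LagStructure(L))
        assert data.n_samples == (shape[0] - L) * (shape[1] - L)
        assert data.n_params == (L + 1) ** 2 - 1

    def test_matches_brute_force(self, rng):
        for L in (1, 2):
            px = rng.random((8, 10))
            data = build_lagged_design(GrayscaleImage(px), LagStructure(L))
            y, X, offsets = brute_force_design(px, L)
            np.testing.assert_array_equal(data.response, y)
            np.testing.assert_array_equal(data.design, X)
            assert list(data.lags.offsets) == offsets

    def test_constant_image_columns_equal_response(self):
        img = GrayscaleImage(np.full((6, 6), 3.5))
        data = build_lagged_design(img, LagStructure(1))
        for h in range(3):
            np.testing.assert_array_equal(data.design[:, h], data.response)

    def test_lag_too_large(self, rng):
        img = GrayscaleImage(rng.random((4, 4)))
        with pytest.raises(EmptyDesignError):
            build_lagged_design(img, LagStructure(4))


class TestFitOls:
    def test_zero_noise_recursion_exact(self):
        spec = LagSimSpec(
            shape=(64, 64),
            beta=(0.6, 0.3, 0.05),
            innovation_sd=0.0,
            boundary_mean=10.0,
            boundary_sd=2.0,
            seed=3,
        )
        fit = fit_image(simulate_lag_image(spec))
        np.testing.assert_allclose(fit.beta, [0.6, 0.3, 0.05], atol=1e-8)
        assert abs(fit.r_squared - 1.0) < 1e-10

    def test_residual_identity(self, lag_image):
        img, _ = lag_image
        data = build_lagged_design(img, LagStructure(1))
        fit = fit_ols(data)
        np.testing.assert_array_equal(
            fit.residuals, data.response - data.design @ fit.beta
        )

    def test_white_cov_symmetric_psd(self, lag_image):
        img, _ = lag_image
        fit = fit_image(img)
        np.testing.assert_array_equal(fit.white_cov, fit.white_cov.T)
        assert np.all(np.linalg.eigvalsh(fit.white_cov) >= -1e-18)

    def test_constant_image_collinear(self):
        img = GrayscaleImage(np.full((10, 10), 2.0))
        with pytest.raises(CollinearityError) as exc_info:
            fit_image(img)
        assert exc_info.value.columns  # names the offending lag columns

    def test_insufficient_samples(self):
        img = GrayscaleImage(np.array([[1.0, 2.0], [3.0, 5.0]]))
        with pytest.raises(InsufficientSamplesError):
            fit_image(img)  # N=1 < k=3

    def test_oracle_equivalence_small_images(self, rng):
        for _ in range(10):
            px = rng.random((rng.integers(5, 13), rng.integers(5, 13))) * 100
            img = GrayscaleImage(px)
            fit = fit_image(img)
            y, X, _ = brute_force_design(px, 1)
            beta, cov, t_stats, _ = brute_force_ols(y, X)
            np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
            np.testing.assert_allclose(fit.white_cov, cov, atol=1e-8)
            np.testing.assert_allclose(fit.t_stats, t_stats, atol=1e-8)

    def test_scale_invariance(self, lag_image):
        img, _ = lag_image
        fit1 = fit_image(img)
        c = 7.3
        fit2 = fit_image(GrayscaleImage(img.pixels * c))
        np.testing.assert_allclose(fit2.beta, fit1.beta, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(fit2.t_stats, fit1.t_stats, rtol=1e-8)
        np.testing.assert_allclose(
            fit2.residuals, c * fit1.residuals, rtol=1e-8, atol=1e-6
        )

    def test_transpose_symmetry(self, lag_image):
        img, _ = lag_image
        fit = fit_image(img)
        fit_t = fit_image(GrayscaleImage(img.pixels.T))
        assert abs(fit_t.beta[0] - fit.beta[1]) < 1e-10
        assert abs(fit_t.beta[1] - fit.beta[0]) < 1e-10
        assert abs(fit_t.beta[2] - fit.beta[2]) < 1e-10

    def test_uncentered_r_squared_definition(self, lag_image):
        img, _ = lag_image
        data = build_lagged_design(img, LagStructure(1))
        fit = fit_ols(data)
        expected = 1.0 - np.sum(fit.residuals**2) / np.sum(data.response**2)
        assert abs(fit.r_squared - expected) < 1e-12
        assert 0.0 <= fit.r_squared <= 1.0


class TestSelectLagOrder:
    def test_one_lag_model_selected(self):
        spec = LagSimSpec(
            shape=(160, 160),
            beta=(0.55, 0.35, 0.05),
            innovation_sd=4.0,
            boundary_mean=80.0,
            boundary_sd=4.0,
            seed=5,
        )
        fit = select_lag_order(simulate_lag_image(spec))
        assert fit.lag_order == 1
        assert fit.significant
        assert np.all(fit.p_values < 0.05)

    def test_white_noise_flagged_insignificant(self, rng):
        img = GrayscaleImage(rng.normal(0.0, 1.0, (200, 200)))
        fit = select_lag_order(img)
        assert fit.lag_order == 1
        assert not fit.significant

    def test_wald_reported(self, lag_image):
        img, _ = lag_image
        fit = select_lag_order(img)
        assert np.isfinite(fit.wald_chi2)
        assert 0.0 <= fit.wald_p <= 1.0
        assert fit.wald_significant

    def test_max_order_respected(self, lag_image):
        img, _ = lag_image
        fit = select_lag_order(img, max_order=1)
        assert fit.lag_order == 1


class TestReconstructModelImage:
    def test_shape_shrinks_by_lag(self, rng):
        img = GrayscaleImage(rng.random((280, 280)))
        fit = fit_image(img)
        model = reconstruct_model_image(img, fit)
        assert model.shape == (279, 279)

    def test_zero_noise_reconstruction_exact(self):
        spec = LagSimSpec(
            shape=(32, 32),
            beta=(0.5, 0.3, 0.1),
            innovation_sd=0.0,
            boundary_mean=10.0,
            boundary_sd=1.0,
            seed=9,
        )
        img = simulate_lag_image(spec)
        fit = fit_image(img)
        model = reconstruct_model_image(img, fit)
        np.testing.assert_allclose(model.pixels, img.pixels[1:, 1:], atol=1e-8)

    def test_model_plus_residual_is_observed(self, lag_image):
        img, _ = lag_image
        fit = fit_image(img)
        model = reconstruct_model_image(img, fit)
        resid_img = fit.residuals.reshape(model.shape, order="F")
        np.testing.assert_allclose(
            model.pixels + resid_img, img.pixels[1:, 1:], rtol=0, atol=1e-9
        )

    def test_mismatched_image_rejected(self, lag_image, rng):
        img, _ = lag_image
        fit = fit_image(img)
        other = GrayscaleImage(rng.random((40, 40)))
        with pytest.raises(InvalidImageError):
            reconstruct_model_image(other, fit)


@settings(max_examples=25, deadline=None)
@given(
    scale=st.floats(0.01, 1e4),
    seed=st.integers(0, 2**31 - 1),
)
def test_scale_invariance_property(scale, seed):
    rng = np.random.default_rng(seed)
    px = rng.random((16, 16)) + 0.1
    f1 = fit_image(GrayscaleImage(px))
    f2 = fit_image(GrayscaleImage(px * scale))
    np.testing.assert_allclose(f2.beta, f1.beta, rtol=1e-8, atol=1e-10)
    np.testing.assert_allclose(f2.t_stats, f1.t_stats, rtol=1e-6, atol=1e-8)
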