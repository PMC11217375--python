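"""Optimizer components: spectral operators, updates, time step, pyramid."""

import numpy as np
import pytest
from scipy.fft import dctn, idctn

from divcurlreg.fields import Volume, VectorField, deriv
from divcurlreg.helmholtz import HelmholtzState, solenoidal_residual
from divcurlreg.optimizer import (
    OptimizerConfig,
    PyramidConfig,
    RegularizerSpec,
    compute_time_step,
    constraint_force,
    dct_eigenvalues,
    prune_outliers,
    pyramid_levels,
    register_single_level,
    semi_implicit_update,
    smooth_and_downsample,
    update_multiplier,
)
from divcurlreg.similarity import LCCConfig


class TestDCTEigenvalues:
    def test_constant_mode_is_null_for_derivative_orders(self):
        lam = dct_eigenvalues((5, 6, 7), 1).eigen_grid
        assert lam[0, 0, 0] == 0.0
        assert np.all(lam >= 0)

    def test_order_zero_is_identity(self):
        np.testing.assert_allclose(dct_eigenvalues((4, 4, 4), 0).eigen_grid, 1.0)

    def test_printed_formula_at_corner_mode(self):
        # shape (2,2,2), highest mode: 6 - 3*2*cos(pi/2) = 6
        lam = dct_eigenvalues((2, 2, 2), 1).eigen_grid
        assert lam[1, 1, 1] == pytest.approx(6.0)

    def test_matches_neumann_stencil(self, rng):
        """IDCT diag(Lambda^1) DCT equals the reflected-boundary 7-point
        negative Laplacian applied in the spatial domain."""
        shape = (6, 6, 6)
        x = rng.standard_normal(shape)
        lam = dct_eigenvalues(shape, 1).eigen_grid
        spec = idctn(dctn(x, type=2, norm="ortho") * lam, type=2, norm="ortho")
        xp = np.pad(x, 1, mode="edge")
        sten = np.zeros(shape)
        for ax in range(3):
            hi = [slice(1, -1)] * 3
            lo = [slice(1, -1)] * 3
            hi[ax] = slice(2, None)
            lo[ax] = slice(0, -2)
            sten += 2 * x - xp[tuple(hi)] - xp[tuple(lo)]
        assert np.abs(spec - sten).max() < 1e-10


class TestSemiImplicitUpdate:
    def test_constant_field_unchanged_for_derivative_orders(self):
        f = np.full((8, 8, 8), 2.5)
        out = semi_implicit_update(f, np.zeros_like(f), [(1, 5.0)], t=0.1)
        np.testing.assert_allclose(out, f, atol=1e-12)

    def test_order_zero_uniform_shrinkage(self):
        f = np.random.default_rng(0).standard_normal((8, 8, 8))
        out = semi_implicit_update(f, np.zeros_like(f), [(0, 3.0)], t=0.5)
        np.testing.assert_allclose(out, f / (1 + 3.0 * 0.5), atol=1e-12)

    def test_single_mode_attenuation(self):
        shape = (8, 8, 8)
        # a single DCT-II basis function
        spec = np.zeros(shape)
        spec[2, 1, 3] = 1.0
        f = idctn(spec, type=2, norm="ortho")
        lam = dct_eigenvalues(shape, 2).eigen_grid[2, 1, 3]
        out = semi_implicit_update(f, np.zeros(shape), [(2, 1.5)], t=0.2)
        np.testing.assert_allclose(out, f / (1 + 1.5 * 0.2 * lam), atol=1e-12)

    def test_spectral_energy_nonincreasing(self, rng):
        """With zero explicit terms the step is a pure spectral smoother."""
        shape = (10, 10, 10)
        f = rng.standard_normal(shape)
        lam = dct_eigenvalues(shape, 1).eigen_grid
        for terms in ([(1, 1.0)], [(0, 0.5), (2, 2.0)]):
            out = semi_implicit_update(f, np.zeros(shape), terms, t=0.3)
            e_in = np.sum(lam * dctn(f, type=2, norm="ortho") ** 2)
            e_out = np.sum(lam * dctn(out, type=2, norm="ortho") ** 2)
            assert e_out <= e_in + 1e-12

    def test_multiterm_single_term_equivalence(self, rng):
        f = rng.standard_normal((8, 8, 8))
        ex = rng.standard_normal((8, 8, 8))
        a = semi_implicit_update(f, ex, [(1, 2.0)], t=0.1)
        b = semi_implicit_update(f, ex, RegularizerSpec.from_weights(2.0, 1, 0, 0).div_terms, t=0.1)
        np.testing.assert_array_equal(a, b)


class TestConstraintForce:
    def test_zero_state(self):
        f = HelmholtzState.zeros((6, 6, 6))
        f.theta = 5.0
        for comp in constraint_force(f):
            np.testing.assert_allclose(comp, 0.0)

    def test_multiplier_ramp(self):
        shape = (8, 8, 8)
        f = HelmholtzState.zeros(shape)
        f.lam = np.broadcast_to(np.arange(8.0)[:, None, None], shape).copy()
        f.theta = 0.0
        fx, fy, fz = constraint_force(f)
        inner = (slice(1, -1),) * 3
        np.testing.assert_allclose(fx[inner], 1.0, atol=1e-13)
        np.testing.assert_allclose(fy, 0.0, atol=1e-13)

    def test_matches_stencil_oracle(self, rng):
        shape = (7, 8, 9)
        f = HelmholtzState(*(rng.standard_normal(shape) for _ in range(4)),
                           lam=rng.standard_normal(shape), theta=2.5)
        C = solenoidal_residual(f)
        force = constraint_force(f)
        for ax in range(3):
            np.testing.assert_allclose(
                force[ax], 2.5 * deriv(C, ax) + deriv(f.lam, ax), atol=1e-13
            )


class TestComputeTimeStep:
    def test_direct_substitution(self):
        g = [np.zeros((4, 4, 4)) for _ in range(4)]
        g[0][1, 1, 1] = 0.02
        assert compute_time_step(g, 0.02) == pytest.approx(1.0)

    def test_norm_two_gives_t_and_theta(self):
        g = [np.zeros((4, 4, 4)) for _ in range(4)]
        g[1][0, 0, 0] = 2.0
        t = compute_time_step(g, 0.02)
        assert t == pytest.approx(0.01)
        assert 0.4 / t == pytest.approx(40.0)

    def test_four_channel_euclidean_norm(self):
        g = [np.full((3, 3, 3), 1.0) for _ in range(4)]
        assert compute_time_step(g, 0.02) == pytest.approx(0.02 / 2.0)

    def test_vanishing_gradient_capped(self, caplog):
        g = [np.zeros((4, 4, 4)) for _ in range(4)]
        with caplog.at_level("WARNING"):
            t = compute_time_step(g, 0.02)
        assert t == 1e3
        assert any("vanishing" in r.message for r in caplog.records)

    def test_nonfinite_rejected(self):
        g = [np.full((3, 3, 3), np.nan)] * 4
        with pytest.raises(FloatingPointError):
            compute_time_step(g, 0.02)

    def test_bound_holds_exactly(self, rng):
        g = [rng.standard_normal((6, 6, 6)) for _ in range(4)]
        t = compute_time_step(g, 0.02)
        norm = np.sqrt(sum(x**2 for x in g))
        assert t * norm.max() <= 0.02 * (1 + 1e-12)


class TestPruneOutliers:
    def test_inband_unchanged(self):
        a = np.linspace(-1, 1, 27).reshape(3, 3, 3)
        np.testing.assert_array_equal(prune_outliers(a, 3.0), a)

    def test_constant_field_unchanged(self):
        a = np.full((4, 4, 4), 7.0)
        np.testing.assert_array_equal(prune_outliers(a, 3.0), a)

    def test_extreme_value_clamped_to_nearest_inlier(self):
        a = np.ones(100)
        a[-1] = 1000.0
        out = prune_outliers(a.reshape(10, 5, 2), 3.0)
        mu, sd = a.mean(), a.std()
        assert a[-1] > mu + 3 * sd  # oracle: it really is an outlier
        assert out.ravel()[-1] == 1.0
        np.testing.assert_array_equal(out.ravel()[:-1], 1.0)

    def test_band_from_independent_mean_sd(self, rng):
        a = rng.standard_normal((8, 8, 8)) * 2.0 + 1.0
        out = prune_outliers(a, 2.0)
        mu, sd = a.mean(), a.std()
        inband = a[(a >= mu - 2 * sd) & (a <= mu + 2 * sd)]
        assert out.min() == inband.min() and out.max() == inband.max()


class TestUpdateMultiplier:
    def test_zero_residual_keeps_lambda(self):
        f = HelmholtzState.zeros((6, 6, 6))
        f.theta = 10.0
        lam0 = f.lam.copy()
        update_multiplier(f)
        np.testing.assert_array_equal(f.lam, lam0)

    def test_substitution(self):
        shape = (8, 8, 8)
        f = HelmholtzState.zeros(shape)
        # f2 = x/2 ramp gives C = 0.5 on the interior
        f.f2 = 0.5 * np.broadcast_to(np.arange(8.0)[:, None, None], shape).copy()
        f.theta = 10.0
        update_multiplier(f)
        inner = (slice(1, -1),) * 3
        np.testing.assert_allclose(f.lam[inner], 5.0, atol=1e-12)


class TestPyramid:
    @pytest.mark.parametrize("shape,expect", [
        ((256, 256, 128), [8, 4, 2, 1]),
        ((64, 64, 32), [2, 1]),
        ((16, 16, 16), [1]),
        ((12, 64, 64), [1]),
    ])
    def test_levels_rule(self, shape, expect):
        assert pyramid_levels(shape, 16) == expect

    def test_downsample_identity_at_s1(self, random_volume):
        img = random_volume((16, 16, 16))
        out = smooth_and_downsample(img, 1)
        np.testing.assert_array_equal(out.data, img.data)

    def test_downsample_constant_preserved(self):
        img = Volume(np.full((32, 32, 16), 4.2), spacing=(1, 1, 2))
        out = smooth_and_downsample(img, 4)
        assert out.shape == (8, 8, 4)
        np.testing.assert_allclose(out.data, 4.2, atol=1e-10)
        assert out.spacing == (4.0, 4.0, 8.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PyramidConfig(min_dim=4)


class TestRegularizerSpec:
    def test_requires_a_term(self):
        with pytest.raises(ValueError):
            RegularizerSpec([], [])

    def test_rejects_bad_orders_and_weights(self):
        with pytest.raises(ValueError):
            RegularizerSpec.from_weights(1.0, 7, 1.0, 1)
        with pytest.raises(ValueError):
            RegularizerSpec.from_weights(-1.0, 1, 1.0, 1)


class TestRegisterSingleLevel:
    def test_identical_images_stay_near_identity(self):
        from divcurlreg.synthetic import gen_blob_image

        F = gen_blob_image((24, 24, 24), seed=3)
        res = register_single_level(
            F, F, HelmholtzState.zeros(F.shape),
            RegularizerSpec.from_weights(1.0, 1, 1.0, 1),
            OptimizerConfig(iterations_per_level=30), LCCConfig(),
        )
        mag = res.displacement.magnitude()
        assert np.percentile(mag, 99) <= 0.1
        assert len(res.diagnostics) == 30
        assert all("mean_abs_C" in r for r in res.diagnostics)

    def test_shape_mismatch_rejected(self):
        from divcurlreg.synthetic import gen_blob_image

        F = gen_blob_image((24, 24, 24), seed=3)
        with pytest.raises(ValueError):
            register_single_level(
                F, F, HelmholtzState.zeros((16, 16, 16)),
                RegularizerSpec.from_weights(1.0, 1, 1.0, 1),
            )
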