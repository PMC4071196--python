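"""Covariance calculus: closed forms vs quadrature and finite-difference oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from fluxgp import (
    CovarianceConditioningError,
    HyperParams,
    KernelSpec,
    ModelSpec,
    build_joint_covariance,
    cov_uu,
    cov_uy,
    cov_yy,
    single_output_spec,
    standard_two_output_spec,
)
from fluxgp.covariance import cholesky_with_jitter

from conftest import random_kernel


def quad_cov(h: KernelSpec, g: KernelSpec, d: float) -> float:
    """Convolution-integral oracle: int h(t-s) g(t'-s) ds with t - t' = d."""
    f = lambda s: (h.amplitude * math.exp(-0.5 * h.inv_width * (d - s) ** 2)
                   * g.amplitude * math.exp(-0.5 * g.inv_width * (-s) ** 2))
    val, _ = quad(f, -60, 60, limit=200)
    return val


class TestKernelSpec:
    @pytest.mark.parametrize("amp,width", [(-1.0, 1.0), (0.0, 1.0), (1.0, -2.0),
                                           (1.0, 0.0), (np.nan, 1.0), (1.0, np.inf)])
    def test_rejects_non_positive_parameters(self, amp, width):
        with pytest.raises(ValueError):
            KernelSpec(amp, width, "s", "a")


class TestCovYY:
    def test_unit_kernels_at_zero_lag(self):
        k = [KernelSpec(1.0, 1.0, "s", "a")]
        assert cov_yy(k, k, 0.0) == pytest.approx(math.sqrt(math.pi), rel=1e-12)

    def test_no_shared_source_is_zero(self):
        ki = [KernelSpec(1.0, 1.0, "s1", "a")]
        kj = [KernelSpec(1.0, 1.0, "s2", "b")]
        assert cov_yy(ki, kj, 0.3) == 0.0

    def test_matches_quadrature_of_convolution_integral(self):
        h = KernelSpec(1.3, 2.0, "s", "a")
        g = KernelSpec(0.7, 0.5, "s", "b")
        closed = cov_yy([h], [g], 0.8)
        assert closed == pytest.approx(quad_cov(h, g, 0.8), rel=1e-6)

    def test_quadrature_oracle_random_pairs(self, rng):
        for _ in range(20):
            h = random_kernel(rng)
            g = random_kernel(rng, output="b")
            d = float(rng.uniform(-3, 3))
            assert cov_yy([h], [g], d) == pytest.approx(quad_cov(h, g, d), rel=1e-6)

    @given(st.floats(-5, 5))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_autocovariance_even_in_lag(self, d):
        k = [KernelSpec(1.1, 0.8, "s", "a"), KernelSpec(0.5, 2.3, "p", "a")]
        assert cov_yy(k, k, d) == pytest.approx(cov_yy(k, k, -d), rel=1e-12, abs=1e-14)


class TestDerivativeCovariances:
    def test_cov_uy_zero_at_zero_lag(self):
        k = [KernelSpec(1.4, 0.7, "s", "a")]
        assert cov_uy(k, k, 0.0) == 0.0

    def test_cov_uy_matches_central_difference(self):
        k = [KernelSpec(1.0, 1.0, "s", "a")]
        eps = 1e-5
        fd = (cov_yy(k, k, 0.5 + eps) - cov_yy(k, k, 0.5 - eps)) / (2 * eps)
        assert abs(cov_uy(k, k, 0.5) - fd) < 1e-6

    @given(st.floats(-4, 4))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_cov_uy_odd_in_lag(self, d):
        k = [KernelSpec(0.9, 1.7, "s", "a")]
        assert cov_uy(k, k, d) == pytest.approx(-cov_uy(k, k, -d), rel=1e-12, abs=1e-14)

    def test_cov_uu_unit_kernels_at_zero_lag(self):
        k = [KernelSpec(1.0, 1.0, "s", "a")]
        assert cov_uu(k, k, 0.0) == pytest.approx(math.sqrt(math.pi) / 2, rel=1e-12)

    def test_cov_uu_matches_second_difference(self, rng):
        h = [random_kernel(rng)]
        g = [random_kernel(rng, output="b")]
        eps = 1e-4
        fd = -(cov_yy(h, g, 0.7 + eps) - 2 * cov_yy(h, g, 0.7) + cov_yy(h, g, 0.7 - eps)) / eps**2
        assert cov_uu(h, g, 0.7) == pytest.approx(fd, rel=1e-4)

    def test_derivative_variance_strictly_positive(self, rng):
        for _ in range(10):
            k = [random_kernel(rng)]
            assert cov_uu(k, k, 0.0) > 0

    def test_finite_difference_consistency_200_draws(self):
        """First and second differences of cov_yy reproduce cov_uy / cov_uu."""
        rng = np.random.default_rng(11)
        eps1, eps2 = 1e-5, 1e-4
        for _ in range(200):
            h = [random_kernel(rng)]
            g = [random_kernel(rng, output="b")]
            d = float(rng.uniform(-3, 3))
            fd1 = (cov_yy(h, g, d + eps1) - cov_yy(h, g, d - eps1)) / (2 * eps1)
            assert abs(cov_uy(h, g, d) - fd1) < 1e-5
            fd2 = -(cov_yy(h, g, d + eps2) - 2 * cov_yy(h, g, d)
                    + cov_yy(h, g, d - eps2)) / eps2**2
            assert abs(cov_uu(h, g, d) - fd2) < 1e-5


class TestBuildJointCovariance:
    def test_single_output_reduces_to_squared_exponential(self):
        """One output, one kernel: SE Gram with variance A^2 sqrt(pi/b), 1/l^2 = b/2."""
        spec = single_output_spec()
        A, b, sd = 1.7, 0.6, 0.1
        theta = HyperParams(np.log([A]), np.log([b]), np.log([sd]))
        t = np.linspace(0, 5, 12)
        blocks = build_joint_covariance(spec, theta, {"y": t})
        d2 = np.subtract.outer(t, t) ** 2
        se = A**2 * np.sqrt(np.pi / b) * np.exp(-0.5 * (b / 2) * d2)
        se[np.diag_indices(12)] += sd**2 + blocks.jitter
        np.testing.assert_allclose(blocks.K_obs, se, atol=1e-12)

    def test_positive_semidefinite_for_random_hyperparameters(self):
        spec = standard_two_output_spec()
        rng = np.random.default_rng(4)
        t = np.linspace(0, 4, 6)
        for _ in range(20):
            vec = rng.normal(0, 1, spec.n_params)
            theta = HyperParams.from_packed(spec, vec)
            blocks = build_joint_covariance(spec, theta, {"z1": t, "z2": t},
                                            {"z1": t + 0.25, "z2": t + 0.25})
            K = blocks.assembled()
            w = np.linalg.eigvalsh(0.5 * (K + K.T))
            assert w.min() >= -1e-8 * w.max()

    def test_unshared_outputs_have_zero_cross_block(self):
        spec = ModelSpec(outputs=("a", "b"), sources=("sa", "sb"),
                         edges=(("sa", "a"), ("sb", "b")))
        theta = HyperParams(np.zeros(2), np.zeros(2), np.log([0.1, 0.1]))
        t = np.linspace(0, 3, 5)
        blocks = build_joint_covariance(spec, theta, {"a": t, "b": t})
        off = blocks.K_obs[blocks.obs_slices["a"], blocks.obs_slices["b"]]
        np.testing.assert_array_equal(off, 0.0)

    def test_assembled_matrix_symmetric(self, rng):
        spec = standard_two_output_spec()
        theta = HyperParams.from_packed(spec, rng.normal(size=spec.n_params))
        t = np.linspace(0, 4, 7)
        K = build_joint_covariance(spec, theta, {"z1": t, "z2": t[:4]},
                                   {"z1": t + 0.3, "z2": t}).assembled()
        np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_non_finite_hyperparameters_rejected(self):
        spec = single_output_spec()
        with pytest.raises(ValueError):
            HyperParams(np.array([np.nan]), np.array([0.0]), np.array([0.0]))

    def test_unknown_output_rejected(self):
        spec = single_output_spec()
        theta = HyperParams(np.zeros(1), np.zeros(1), np.zeros(1))
        with pytest.raises(KeyError):
            build_joint_covariance(spec, theta, {"nope": [0.0, 1.0]})


class TestCholeskyJitter:
    def test_conditioning_error_names_block(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(CovarianceConditioningError, match="observation"):
            cholesky_with_jitter(K, name="observation")

    def test_near_singular_rescued_by_jitter(self):
        K = np.ones((3, 3))  # rank 1, PSD
        L, jitter = cholesky_with_jitter(K)
        assert jitter > 0
        np.testing.assert_allclose(L @ L.T, K + jitter * np.eye(3), atol=1e-12)


class TestPriorSamplingConsistency:
    def test_empirical_covariance_of_prior_draws_matches_K(self):
        """20,000 joint prior draws on a 5-point grid reproduce K within 3 MC SE."""
        spec = single_output_spec()
        theta = HyperParams(np.log([1.2]), np.log([0.8]), np.log([1e-6]))
        t = np.linspace(0, 4, 5)
        blocks = build_joint_covariance(spec, theta, {}, {"y": t})
        K = blocks.test_cov()
        rng = np.random.default_rng(2024)
        L = np.linalg.cholesky(K + 1e-12 * np.eye(len(K)))
        n = 20_000
        draws = rng.standard_normal((n, len(K))) @ L.T
        emp = draws.T @ draws / n
        se = np.sqrt((np.outer(np.diag(K), np.diag(K)) + K**2) / n)
        assert np.all(np.abs(emp - K) <= 3.0 * se)
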