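"""Model structure, marginal likelihood (MVN oracle) and MAP estimation."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from fluxgp import (
    HyperParams,
    ModelSpec,
    PriorSpec,
    TimeSeriesSet,
    build_joint_covariance,
    ecoli_three_output_spec,
    gen_oscillators,
    log_marginal_likelihood,
    map_estimate,
    single_output_spec,
    standard_two_output_spec,
)


class TestModelSpecs:
    def test_two_output_structure(self):
        spec = standard_two_output_spec()
        assert len(spec.sources) == 3
        assert spec.n_edges == 4
        assert spec.n_outputs == 2
        assert spec.n_params == 10

    def test_two_output_free_count_with_fixed_amplitudes_and_noise(self):
        spec = standard_two_output_spec()
        names = spec.param_names
        fixed = [n for n in names if n.startswith("logA") or n.startswith("logsd")]
        mask = np.array([n in fixed for n in names])
        theta = HyperParams.from_packed(spec, np.zeros(spec.n_params), fixed_mask=mask)
        assert theta.n_free == 4  # only the four kernel widths remain

    def test_shared_source_induces_cross_covariance(self):
        spec = standard_two_output_spec()
        theta = HyperParams.from_packed(spec, np.zeros(spec.n_params))
        t = np.linspace(0, 3, 4)
        blocks = build_joint_covariance(spec, theta, {"z1": t, "z2": t})
        off = blocks.K_obs[blocks.obs_slices["z1"], blocks.obs_slices["z2"]]
        assert np.abs(off).max() > 0.1

    def test_ecoli_structure_has_17_hyperparameters(self):
        spec = ecoli_three_output_spec()
        assert spec.n_edges == 7
        assert len(spec.sources) == 5
        assert spec.n_params == 17

    def test_ecoli_akg_gln_independent_given_no_glu_bridge(self):
        """aKG and GLN share no source directly: their cross block is zero."""
        spec = ecoli_three_output_spec()
        theta = HyperParams.from_packed(spec, np.zeros(spec.n_params))
        t = np.linspace(0, 2, 3)
        blocks = build_joint_covariance(spec, theta, {"aKG": t, "GLN": t})
        off = blocks.K_obs[blocks.obs_slices["aKG"], blocks.obs_slices["GLN"]]
        np.testing.assert_array_equal(off, 0.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(outputs=("a",), sources=("s",), edges=())  # output unfed
        with pytest.raises(ValueError):
            ModelSpec(outputs=("a",), sources=("s",), edges=(("s", "a"), ("s", "a")))

    def test_spec_roundtrips_through_dict(self):
        spec = ecoli_three_output_spec()
        assert ModelSpec.from_dict(spec.to_dict()) == spec


class TestLogMarginalLikelihood:
    def test_single_observation_closed_form(self):
        """One output, y=0 at t=0: univariate normal with variance v + sd^2."""
        spec = single_output_spec()
        A, b, sd = 1.3, 0.7, 0.2
        theta = HyperParams(np.log([A]), np.log([b]), np.log([sd]))
        data = TimeSeriesSet.from_records([("y", 0.0, 0.0)])
        v = A**2 * np.sqrt(np.pi / b)
        expected = -0.5 * np.log(2 * np.pi * (v + sd**2))
        assert log_marginal_likelihood(spec, theta, data) == pytest.approx(expected, abs=1e-8)

    def test_matches_dense_mvn_oracle(self, small_data, rng):
        spec = standard_two_output_spec()
        for _ in range(5):
            theta = HyperParams.from_packed(spec, rng.normal(size=spec.n_params))
            obs_times = {o: small_data.times(o) for o in small_data.outputs}
            K = build_joint_covariance(spec, theta, obs_times).K_obs
            y = np.concatenate([small_data.values(o) for o in small_data.outputs])
            oracle = multivariate_normal(mean=np.zeros(len(y)), cov=K).logpdf(y)
            assert log_marginal_likelihood(spec, theta, small_data) == pytest.approx(
                oracle, abs=1e-9)

    def test_invariant_to_observation_order(self, small_data):
        spec = standard_two_output_spec()
        theta = HyperParams.from_packed(spec, np.full(spec.n_params, -0.3))
        ll = log_marginal_likelihood(spec, theta, small_data)
        shuffled = TimeSeriesSet(small_data.frame.sample(frac=1.0, random_state=7))
        assert log_marginal_likelihood(spec, theta, shuffled) == pytest.approx(ll, abs=1e-12)

    def test_invariant_to_source_relabelling(self, small_data):
        spec = standard_two_output_spec()
        relabelled = ModelSpec(
            outputs=spec.outputs,
            sources=tuple(f"src{k}" for k in range(len(spec.sources))),
            edges=tuple((f"src{spec.sources.index(s)}", o) for s, o in spec.edges),
        )
        theta = HyperParams.from_packed(spec, np.full(spec.n_params, 0.2))
        assert log_marginal_likelihood(spec, theta, small_data) == pytest.approx(
            log_marginal_likelihood(relabelled, theta, small_data), abs=1e-12)


class TestMAPEstimate:
    def test_deterministic_given_seed(self, small_data):
        spec = standard_two_output_spec()
        priors = PriorSpec.from_data(spec, small_data)
        a = map_estimate(spec, priors, small_data, n_starts=1, seed=9, max_iter=300)
        b = map_estimate(spec, priors, small_data, n_starts=1, seed=9, max_iter=300)
        np.testing.assert_array_equal(a.theta.packed(), b.theta.packed())

    def test_single_output_parameter_recovery(self):
        """Recover effective length-scale and noise sd within 25% on n=40."""
        A, b, sd = 1.0, 0.5, 0.1
        rng = np.random.default_rng(42)
        t = np.linspace(0, 10, 40)
        spec = single_output_spec()
        truth = HyperParams(np.log([A]), np.log([b]), np.log([sd]))
        K = build_joint_covariance(spec, truth, {"y": t}).K_obs
        y = np.linalg.cholesky(K) @ rng.standard_normal(len(t))
        data = TimeSeriesSet.from_arrays({"y": (t, y)})
        priors = PriorSpec.from_data(spec, data)
        fit = map_estimate(spec, priors, data, n_starts=8, seed=1)
        ell_true = np.sqrt(2.0 / b)
        ell_hat = float(np.sqrt(2.0 / fit.theta.inv_widths[0]))
        assert abs(ell_hat - ell_true) / ell_true < 0.25
        assert abs(fit.theta.noise_sd[0] - sd) / sd < 0.25

    def test_scale_equivariance(self):
        """Scaling data by c (and shifting amplitude/noise priors by log c)
        scales recovered amplitudes and noise by c, widths unchanged."""
        sim = gen_oscillators(seed=12, obs_times=np.linspace(0, 10, 15))
        data = sim.observations
        c = 5.0
        df = data.frame.copy()
        df["value"] *= c
        data_scaled = TimeSeriesSet(df)
        spec = standard_two_output_spec()
        priors = PriorSpec.from_data(spec, data)
        shift = np.zeros(spec.n_params)
        E = spec.n_edges
        shift[:E] = np.log(c)
        shift[2 * E:] = np.log(c)
        priors_scaled = PriorSpec(priors.loc + shift, priors.scale)
        fit = map_estimate(spec, priors, data, n_starts=2, seed=3, max_iter=800)
        fit_scaled = map_estimate(spec, priors_scaled, data_scaled, n_starts=2,
                                  seed=3, max_iter=800)
        np.testing.assert_allclose(fit_scaled.theta.amplitudes,
                                   c * fit.theta.amplitudes, rtol=1e-3)
        np.testing.assert_allclose(fit_scaled.theta.inv_widths,
                                   fit.theta.inv_widths, rtol=1e-3)
        np.testing.assert_allclose(fit_scaled.theta.noise_sd,
                                   c * fit.theta.noise_sd, rtol=1e-3)

    def test_fixed_parameters_stay_fixed(self, small_data):
        spec = standard_two_output_spec()
        priors = PriorSpec.from_data(spec, small_data)
        fixed = {"logsd[z1]": np.log(0.05), "logsd[z2]": np.log(0.07)}
        fit = map_estimate(spec, priors, small_data, n_starts=1, seed=2,
                           fixed=fixed, max_iter=200)
        assert fit.theta.noise_sd[0] == pytest.approx(0.05)
        assert fit.theta.noise_sd[1] == pytest.approx(0.07)

    def test_centering_returns_output_means(self, small_data):
        spec = standard_two_output_spec()
        priors = PriorSpec.from_data(spec, small_data)
        fit = map_estimate(spec, priors, small_data, n_starts=1, seed=2,
                           center=True, max_iter=50)
        for o in ("z1", "z2"):
            assert fit.output_means[o] == pytest.approx(
                float(np.mean(small_data.values(o))))

    def test_hyperparams_roundtrip_through_dict(self, small_data):
        spec = standard_two_output_spec()
        theta = HyperParams.from_packed(spec, np.arange(spec.n_params, dtype=float) / 7)
        back = HyperParams.from_dict(spec, theta.to_dict(spec))
        np.testing.assert_allclose(back.packed(), theta.packed())

    def test_prior_override_by_name(self):
        spec = single_output_spec()
        priors = PriorSpec.default(spec).with_overrides(
            spec, {"logsd[y]": (-3.0, 0.5)})
        k = spec.param_names.index("logsd[y]")
        assert priors.loc[k] == -3.0 and priors.scale[k] == 0.5
        with pytest.raises(KeyError):
            priors.with_overrides(spec, {"nope": (0.0, 1.0)})
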