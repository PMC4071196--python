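"""Joint and marginal posterior prediction for original and derivative processes.

Because a convolution-constructed GP and its time derivative share the same
latent white-noise input, the vector of observations, latent function values
and derivative values at any finite set of points is jointly Gaussian.
Conditioning that joint Gaussian on the observations yields, in one linear
solve, posterior means and covariances for both the signals and their time
derivatives — the quantity the flux layer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular

from .covariance import build_joint_covariance, cholesky_with_jitter
from .io import TimeSeriesSet
from .model import (
    HyperParams,
    MAPResult,
    ModelSpec,
    PriorSpec,
    _obs_vector,
    laplace_covariance,
    neg_log_posterior,
)

__all__ = [
    "PosteriorPrediction",
    "posterior_joint",
    "posterior_marginal",
    "posterior_joint_hyperavg",
]

#: Variances more negative than -NEG_VAR_TOL * scale indicate a real bug.
NEG_VAR_TOL = 1e-10


@dataclass
class PosteriorPrediction:
    """Posterior over function values and derivatives on a test grid.

    The joint layout stacks all function values first (outputs in model
    order, each with its own times), then all derivatives in the same order;
    ``function_slices`` / ``derivative_slices`` index into the joint vector.
    Variances are of the latent (noise-free) functions unless the prediction
    was built with ``include_noise=True``.
    """

    outputs: tuple[str, ...]
    test_times: dict[str, np.ndarray]
    mean_function: dict[str, np.ndarray]
    var_function: dict[str, np.ndarray]
    mean_derivative: dict[str, np.ndarray]
    var_derivative: dict[str, np.ndarray]
    joint_mean: np.ndarray | None = None
    joint_cov: np.ndarray | None = None
    function_slices: dict[str, slice] = field(default_factory=dict)
    derivative_slices: dict[str, slice] = field(default_factory=dict)

    def band(self, output: str, quantity: str = "function", width: float = 2.0):
        """(lower, upper) mean +/- ``width`` posterior sd band for one output."""
        mean = getattr(self, f"mean_{quantity}")[output]
        sd = np.sqrt(getattr(self, f"var_{quantity}")[output])
        return mean - width * sd, mean + width * sd

    def sample(self, n: int, seed: int | None = None) -> np.ndarray:
        """Draw ``n`` joint samples of [functions; derivatives]; shape (n, 2T)."""
        if self.joint_cov is None:
            raise ValueError("prediction was built without the full joint covariance")
        rng = np.random.default_rng(seed)
        L, _ = cholesky_with_jitter(self.joint_cov, name="posterior")
        z = rng.standard_normal((n, L.shape[0]))
        return self.joint_mean[None, :] + z @ L.T

    def derivative_cov_at(self, k: int, outputs: Sequence[str] | None = None) -> np.ndarray:
        """Cross-output covariance of the derivatives at time index ``k``.

        Requires every requested output to share a common test grid; ``k``
        indexes into that grid.
        """
        if self.joint_cov is None:
            raise ValueError("prediction was built without the full joint covariance")
        outputs = list(outputs or self.outputs)
        idx = [self.derivative_slices[o].start + k for o in outputs]
        return self.joint_cov[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: output, time, quantity in {function, derivative}, mean, sd."""
        rows = []
        for o in self.outputs:
            t = self.test_times[o]
            for quantity, mean, var in [
                ("function", self.mean_function[o], self.var_function[o]),
                ("derivative", self.mean_derivative[o], self.var_derivative[o]),
            ]:
                rows.append(pd.DataFrame({
                    "output": o,
                    "time": t,
                    "quantity": quantity,
                    "mean": mean,
                    "sd": np.sqrt(var),
                }))
        return pd.concat(rows, ignore_index=True)


def _clip_variances(diag: np.ndarray, scale: float) -> np.ndarray:
    tol = NEG_VAR_TOL * max(1.0, scale)
    if np.any(diag < -tol):
        worst = float(diag.min())
        raise FloatingPointError(
            f"posterior variance {worst:g} is more negative than round-off tolerance"
        )
    return np.clip(diag, 0.0, None)


def posterior_joint(
    spec: ModelSpec,
    theta: HyperParams,
    data: TimeSeriesSet | None,
    test_times: Mapping[str, Sequence[float]],
    include_noise: bool = False,
    mean_offsets: Mapping[str, float] | None = None,
) -> PosteriorPrediction:
    """Joint Gaussian posterior over functions and derivatives at test points.

    With no data (``data=None``) the prior is returned.  ``mean_offsets``
    adds back per-output means removed before fitting (centred fits); they
    shift the function means only.
    """
    test_times = {o: np.atleast_1d(np.asarray(t, float)) for o, t in test_times.items()}
    for o in test_times:
        if o not in spec.outputs:
            raise KeyError(f"unknown output {o!r}; model outputs are {list(spec.outputs)}")

    if data is not None:
        obs_times, y = _obs_vector(spec, data)
    else:
        obs_times, y = {}, np.zeros(0)
    blocks = build_joint_covariance(spec, theta, obs_times, test_times)
    prior_cov = blocks.test_cov()
    if blocks.n_obs:
        L, _ = cholesky_with_jitter(blocks.K_obs, name="observation")
        X = blocks.cross()  # (N, 2T)
        alpha = cho_solve((L, True), y)
        mean = X.T @ alpha
        V = solve_triangular(L, X, lower=True)
        cov = prior_cov - V.T @ V
    else:
        mean = np.zeros(prior_cov.shape[0])
        cov = prior_cov
    cov = 0.5 * (cov + cov.T)
    scale = float(np.max(np.diag(prior_cov))) if prior_cov.size else 1.0
    diag = _clip_variances(np.diag(cov).copy(), scale)
    np.fill_diagonal(cov, diag)

    T = blocks.n_test
    outputs = tuple(o for o in spec.outputs if o in blocks.test_slices)
    mean_offsets = dict(mean_offsets or {})
    mean_f, var_f, mean_d, var_d = {}, {}, {}, {}
    fslices, dslices = {}, {}
    noise_sd = dict(zip(spec.outputs, theta.noise_sd))
    for o in outputs:
        s = blocks.test_slices[o]
        ds = slice(T + s.start, T + s.stop)
        fslices[o] = s
        dslices[o] = ds
        mean_f[o] = mean[s] + mean_offsets.get(o, 0.0)
        var_f[o] = diag[s].copy()
        if include_noise:
            var_f[o] = var_f[o] + noise_sd[o] ** 2
        mean_d[o] = mean[ds]
        var_d[o] = diag[ds].copy()
    joint_mean = mean.copy()
    for o in outputs:
        joint_mean[fslices[o]] += mean_offsets.get(o, 0.0)

    return PosteriorPrediction(
        outputs=outputs,
        test_times={o: test_times[o] for o in outputs},
        mean_function=mean_f,
        var_function=var_f,
        mean_derivative=mean_d,
        var_derivative=var_d,
        joint_mean=joint_mean,
        joint_cov=cov,
        function_slices=fslices,
        derivative_slices=dslices,
    )


def posterior_joint_hyperavg(
    spec: ModelSpec,
    priors: PriorSpec,
    data: TimeSeriesSet,
    result: MAPResult,
    test_times: Mapping[str, Sequence[float]],
    n_draws: int = 40,
    seed: int = 0,
    step: float = 0.05,
    level: float = 0.99,
    mean_offsets: Mapping[str, float] | None = None,
) -> PosteriorPrediction:
    """Joint posterior averaged over hyperparameter uncertainty (Laplace).

    A plug-in MAP posterior understates uncertainty because it treats the
    fitted hyperparameters as exact; derivative and flux bands are
    particularly sensitive.  Here hyperparameters are drawn from the Laplace
    approximation around the MAP (draws falling outside the ``level``
    highest-posterior-density chi-square region are rejected as
    approximation artefacts), a plug-in posterior is computed for each
    accepted draw, and the Gaussian mixture is moment-matched:
    ``mean = E[mean_k]``, ``cov = E[cov_k] + Cov[mean_k]``.

    Falls back to the plug-in posterior if no draw is accepted.
    """
    from scipy.stats import chi2

    theta = result.theta
    free = ~theta.fixed_mask
    idx = np.where(free)[0]
    cov_theta = laplace_covariance(spec, priors, data, result, step=step)
    L = np.linalg.cholesky(cov_theta + 1e-10 * np.eye(len(idx)))
    x0 = theta.packed()
    f0 = neg_log_posterior(spec, priors, data, theta)
    cap = f0 + 0.5 * chi2.ppf(level, len(idx))
    rng = np.random.default_rng(seed)

    template = None
    means, covs = [], []
    tries = 0
    while len(means) < n_draws and tries < 20 * n_draws:
        tries += 1
        x = x0.copy()
        x[idx] = x0[idx] + L @ rng.standard_normal(len(idx))
        th = HyperParams.from_packed(spec, x, fixed_mask=theta.fixed_mask)
        if neg_log_posterior(spec, priors, data, th) > cap:
            continue
        p = posterior_joint(spec, th, data, test_times, mean_offsets=mean_offsets)
        template = p
        means.append(p.joint_mean)
        covs.append(p.joint_cov)
    if not means:
        return posterior_joint(spec, theta, data, test_times, mean_offsets=mean_offsets)

    M = np.mean(means, axis=0)
    spread = np.cov(np.asarray(means).T, bias=True) if len(means) > 1 else 0.0
    C = np.mean(covs, axis=0) + np.atleast_2d(spread)
    C = 0.5 * (C + C.T)
    p = template
    p.joint_mean = M
    p.joint_cov = C
    diag = np.diag(C)
    for o in p.outputs:
        fs, ds = p.function_slices[o], p.derivative_slices[o]
        p.mean_function[o] = M[fs]
        p.var_function[o] = diag[fs].copy()
        p.mean_derivative[o] = M[ds]
        p.var_derivative[o] = diag[ds].copy()
    return p


def posterior_marginal(
    spec: ModelSpec,
    theta: HyperParams,
    data: TimeSeriesSet | None,
    test_times: Sequence[float],
    output_id: str,
    include_noise: bool = False,
    mean_offsets: Mapping[str, float] | None = None,
) -> PosteriorPrediction:
    """Marginal posterior for a single output and its derivative.

    Identical to the corresponding diagonal of :func:`posterior_joint`; data
    from *all* outputs still informs the prediction through the shared
    sources.
    """
    if output_id not in spec.outputs:
        raise KeyError(f"unknown output {output_id!r}; model outputs are {list(spec.outputs)}")
    return posterior_joint(
        spec, theta, data, {output_id: test_times},
        include_noise=include_noise, mean_offsets=mean_offsets,
    )
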