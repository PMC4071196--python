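"""Model specification, marginal likelihood, priors and MAP hyperparameter fitting.

A :class:`ModelSpec` declares the convolution network: which latent
white-noise sources feed which outputs.  Each (source, output) edge carries
one Gaussian kernel with an amplitude and an inverse squared width; each
output additionally carries an i.i.d. Gaussian observation-noise standard
deviation.  All hyperparameters are stored and optimized in log space, which
enforces positivity without constrained optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .covariance import KernelSpec, build_joint_covariance, cholesky_with_jitter
from .io import TimeSeriesSet

__all__ = [
    "ModelSpec",
    "HyperParams",
    "PriorSpec",
    "MAPResult",
    "single_output_spec",
    "standard_two_output_spec",
    "ecoli_three_output_spec",
    "log_marginal_likelihood",
    "map_estimate",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Convolution-network structure: outputs, latent sources and their edges.

    ``edges`` is an ordered tuple of ``(source, output)`` pairs; each edge
    carries exactly one Gaussian kernel.  A source with edges to two or more
    outputs induces cross-correlation between them; a single-edge source is
    private to its output.
    """

    outputs: tuple[str, ...]
    sources: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(set(self.outputs)) != len(self.outputs):
            raise ValueError("duplicate output labels")
        if len(set(self.sources)) != len(self.sources):
            raise ValueError("duplicate source labels")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate (source, output) edges")
        for s, o in self.edges:
            if s not in self.sources:
                raise ValueError(f"edge references unknown source {s!r}")
            if o not in self.outputs:
                raise ValueError(f"edge references unknown output {o!r}")
        fed = {o for _, o in self.edges}
        missing = [o for o in self.outputs if o not in fed]
        if missing:
            raise ValueError(f"outputs without any incident edge: {missing}")

    @property
    def n_outputs(self) -> int:
        return len(self.outputs)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_params(self) -> int:
        """Total hyperparameter count: 2 per edge plus one noise sd per output."""
        return 2 * self.n_edges + self.n_outputs

    @property
    def param_names(self) -> tuple[str, ...]:
        names = [f"logA[{s}->{o}]" for s, o in self.edges]
        names += [f"logb[{s}->{o}]" for s, o in self.edges]
        names += [f"logsd[{o}]" for o in self.outputs]
        return tuple(names)

    def kernel_sets(self, theta: "HyperParams") -> dict[str, list[KernelSpec]]:
        """Kernels grouped by output at the given hyperparameters."""
        A = theta.amplitudes
        b = theta.inv_widths
        out: dict[str, list[KernelSpec]] = {o: [] for o in self.outputs}
        for k, (s, o) in enumerate(self.edges):
            out[o].append(KernelSpec(float(A[k]), float(b[k]), s, o))
        return out

    def to_dict(self) -> dict:
        return {
            "outputs": list(self.outputs),
            "sources": list(self.sources),
            "edges": [list(e) for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            outputs=tuple(d["outputs"]),
            sources=tuple(d["sources"]),
            edges=tuple((s, o) for s, o in d["edges"]),
        )


def single_output_spec(output: str = "y") -> ModelSpec:
    """One output fed by one private source: an ordinary squared-exponential GP."""
    return ModelSpec(outputs=(output,), sources=(f"src_{output}",), edges=((f"src_{output}", output),))


def standard_two_output_spec(outputs: Sequence[str] = ("z1", "z2")) -> ModelSpec:
    """Two outputs, each a superposition of a shared and a private convolution GP.

    Each signal is the sum of two convolution GPs (one driven by the shared
    source, one by its private source) plus additive observation noise:
    3 sources, 4 edges, 2 noise terms, hence 10 free hyperparameters.
    """
    o1, o2 = outputs
    return ModelSpec(
        outputs=(o1, o2),
        sources=("shared", f"private_{o1}", f"private_{o2}"),
        edges=(
            ("shared", o1),
            ("shared", o2),
            (f"private_{o1}", o1),
            (f"private_{o2}", o2),
        ),
    )


def ecoli_three_output_spec(outputs: Sequence[str] = ("aKG", "GLU", "GLN")) -> ModelSpec:
    """Three-metabolite nitrogen-assimilation model structure.

    alpha-ketoglutarate (aKG) is a sum of a private GP, a GP shared with
    glutamate (GLU) and noise; GLU is a sum of a private GP, the GP shared with
    aKG, a GP shared with glutamine (GLN) and noise; GLN is a private GP plus
    the GP shared with GLU plus noise.  7 kernels + 3 noise terms = 17
    hyperparameters.
    """
    akg, glu, gln = outputs
    return ModelSpec(
        outputs=(akg, glu, gln),
        sources=(f"private_{akg}", f"private_{glu}", f"private_{gln}",
                 f"shared_{akg}_{glu}", f"shared_{glu}_{gln}"),
        edges=(
            (f"private_{akg}", akg),
            (f"shared_{akg}_{glu}", akg),
            (f"private_{glu}", glu),
            (f"shared_{akg}_{glu}", glu),
            (f"shared_{glu}_{gln}", glu),
            (f"private_{gln}", gln),
            (f"shared_{glu}_{gln}", gln),
        ),
    )


@dataclass
class HyperParams:
    """Log-space hyperparameters for a :class:`ModelSpec`.

    The packed ordering is ``[log amplitudes (per edge), log inverse widths
    (per edge), log noise sd (per output)]``.  ``fixed_mask`` marks packed
    entries held constant during optimization.
    """

    log_amplitudes: np.ndarray
    log_inv_widths: np.ndarray
    log_noise_sd: np.ndarray
    fixed_mask: np.ndarray | None = None

    def __post_init__(self):
        self.log_amplitudes = np.atleast_1d(np.asarray(self.log_amplitudes, float))
        self.log_inv_widths = np.atleast_1d(np.asarray(self.log_inv_widths, float))
        self.log_noise_sd = np.atleast_1d(np.asarray(self.log_noise_sd, float))
        if self.log_amplitudes.shape != self.log_inv_widths.shape:
            raise ValueError("log_amplitudes and log_inv_widths must have equal length")
        n = self.n_params
        if self.fixed_mask is None:
            self.fixed_mask = np.zeros(n, dtype=bool)
        else:
            self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
            if self.fixed_mask.shape != (n,):
                raise ValueError(f"fixed_mask must have length {n}")
        for arr, name in [(self.log_amplitudes, "log_amplitudes"),
                          (self.log_inv_widths, "log_inv_widths"),
                          (self.log_noise_sd, "log_noise_sd")]:
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def n_params(self) -> int:
        return 2 * len(self.log_amplitudes) + len(self.log_noise_sd)

    @property
    def n_free(self) -> int:
        return int(np.count_nonzero(~self.fixed_mask))

    @property
    def amplitudes(self) -> np.ndarray:
        return np.exp(self.log_amplitudes)

    @property
    def inv_widths(self) -> np.ndarray:
        return np.exp(self.log_inv_widths)

    @property
    def noise_sd(self) -> np.ndarray:
        return np.exp(self.log_noise_sd)

    def packed(self) -> np.ndarray:
        return np.concatenate([self.log_amplitudes, self.log_inv_widths, self.log_noise_sd])

    @classmethod
    def from_packed(cls, spec: ModelSpec, vec: np.ndarray,
                    fixed_mask: np.ndarray | None = None) -> "HyperParams":
        vec = np.asarray(vec, float)
        if vec.shape != (spec.n_params,):
            raise ValueError(f"packed vector must have length {spec.n_params}")
        E = spec.n_edges
        return cls(vec[:E], vec[E:2 * E], vec[2 * E:], fixed_mask=fixed_mask)

    def to_dict(self, spec: ModelSpec) -> dict:
        return {name: float(v) for name, v in zip(spec.param_names, self.packed())}

    @classmethod
    def from_dict(cls, spec: ModelSpec, d: Mapping[str, float]) -> "HyperParams":
        vec = np.array([float(d[name]) for name in spec.param_names])
        return cls.from_packed(spec, vec)


@dataclass
class PriorSpec:
    """Independent Gaussian priors on the log-scale hyperparameters."""

    loc: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.loc = np.atleast_1d(np.asarray(self.loc, float))
        self.scale = np.atleast_1d(np.asarray(self.scale, float))
        if self.loc.shape != self.scale.shape:
            raise ValueError("prior loc and scale must have equal length")
        if not np.all(np.isfinite(self.loc)) or not np.all(self.scale > 0):
            raise ValueError("prior loc must be finite and scale positive")

    @classmethod
    def default(cls, spec: ModelSpec, loc: float = 0.0, scale: float = 1.5) -> "PriorSpec":
        n = spec.n_params
        return cls(np.full(n, float(loc)), np.full(n, float(scale)))

    @classmethod
    def from_data(cls, spec: ModelSpec, data: TimeSeriesSet,
                  scale: float = 1.0) -> "PriorSpec":
        """Weakly-informative priors centred on data-derived scales.

        Kernel widths are centred so the implied length-scale is a quarter of
        the observed time span; amplitudes so the per-output prior variance is
        split evenly across that output's kernels; noise at 10% of each
        output's sample standard deviation.
        """
        loc = np.zeros(spec.n_params)
        E = spec.n_edges
        per_output_sd = {}
        per_output_span = {}
        for o in spec.outputs:
            if o in data.outputs:
                v = data.values(o)
                t = data.times(o)
                per_output_sd[o] = max(float(np.std(v)), 1e-8)
                per_output_span[o] = max(float(np.ptp(t)), 1e-8)
            else:
                per_output_sd[o] = 1.0
                per_output_span[o] = 1.0
        kernels_per_output = {o: 0 for o in spec.outputs}
        for _, o in spec.edges:
            kernels_per_output[o] += 1
        for k, (_, o) in enumerate(spec.edges):
            ell = per_output_span[o] / 4.0
            b0 = 2.0 / ell**2
            loc[E + k] = np.log(b0)
            # prior variance of one kernel's GP is A^2 sqrt(pi / b)
            var_target = per_output_sd[o] ** 2 / kernels_per_output[o]
            loc[k] = 0.5 * np.log(var_target / np.sqrt(np.pi / b0))
        for i, o in enumerate(spec.outputs):
            loc[2 * E + i] = np.log(0.1 * per_output_sd[o])
        return cls(loc, np.full(spec.n_params, float(scale)))

    def with_overrides(self, spec: ModelSpec,
                       overrides: Mapping[str, tuple[float, float]]) -> "PriorSpec":
        loc = self.loc.copy()
        scale = self.scale.copy()
        names = spec.param_names
        for name, (m, s) in overrides.items():
            if name not in names:
                raise KeyError(f"unknown hyperparameter {name!r}")
            k = names.index(name)
            loc[k], scale[k] = float(m), float(s)
        return PriorSpec(loc, scale)

    def log_density(self, vec: np.ndarray, mask: np.ndarray | None = None) -> float:
        vec = np.asarray(vec, float)
        z = (vec - self.loc) / self.scale
        terms = -0.5 * z * z - np.log(self.scale) - 0.5 * LOG2PI
        if mask is not None:
            terms = terms[mask]
        return float(np.sum(terms))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return self.loc + self.scale * rng.standard_normal(self.loc.shape)


def _obs_vector(spec: ModelSpec, data: TimeSeriesSet):
    """Observation times per output and the stacked y vector in model order."""
    obs_times = {}
    ys = []
    for o in spec.outputs:
        if o in data.outputs:
            obs_times[o] = data.times(o)
            ys.append(data.values(o))
    if not ys:
        raise ValueError("data contains no observations for any model output")
    return obs_times, np.concatenate(ys)


def log_marginal_likelihood(spec: ModelSpec, theta: HyperParams,
                            data: TimeSeriesSet) -> float:
    """Gaussian marginal log-likelihood of the observations.

    ``-1/2 y^T K^{-1} y - 1/2 log|K| - N/2 log(2 pi)`` with ``K`` the
    observation-block covariance (signal plus noise), computed via Cholesky.
    """
    obs_times, y = _obs_vector(spec, data)
    blocks = build_joint_covariance(spec, theta, obs_times)
    L, _ = cholesky_with_jitter(blocks.K_obs, name="observation")
    alpha = np.linalg.solve(L, y)
    n = len(y)
    return float(-0.5 * alpha @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * LOG2PI)


@dataclass
class MAPResult:
    """Outcome of a multistart MAP optimization."""

    theta: HyperParams
    log_posterior: float
    log_likelihood: float
    n_starts: int
    seed: int
    improved: bool
    start_values: np.ndarray = field(default_factory=lambda: np.array([]))
    output_means: dict[str, float] = field(default_factory=dict)

    def to_dict(self, spec: ModelSpec) -> dict:
        d = {
            "hyperparameters": self.theta.to_dict(spec),
            "log_posterior": float(self.log_posterior),
            "log_likelihood": float(self.log_likelihood),
            "n_starts": self.n_starts,
            "seed": int(self.seed),
            "improved": bool(self.improved),
        }
        if self.output_means:
            d["output_means"] = {k: float(v) for k, v in self.output_means.items()}
        return d


def neg_log_posterior(spec: ModelSpec, priors: PriorSpec, data: TimeSeriesSet,
                      theta: HyperParams) -> float:
    """Negative unnormalized log posterior at ``theta`` (free-parameter prior only)."""
    vec = theta.packed()
    if np.max(np.abs(vec)) > 40:
        return np.inf
    try:
        ll = log_marginal_likelihood(spec, theta, data)
    except np.linalg.LinAlgError:
        return np.inf
    return -(ll + priors.log_density(vec, mask=~theta.fixed_mask))


def laplace_covariance(
    spec: ModelSpec,
    priors: PriorSpec,
    data: TimeSeriesSet,
    result: "MAPResult",
    step: float = 0.05,
) -> np.ndarray:
    """Laplace-approximation covariance of the free hyperparameters at the MAP.

    The Hessian of the negative log posterior is estimated by central finite
    differences in log space.  Directions of spurious low or negative
    curvature (finite-difference noise, or a simplex endpoint short of the
    exact optimum) are floored at the smallest prior precision, so the
    approximate posterior is never wider than the prior in any direction.
    """
    theta = result.theta
    free = ~theta.fixed_mask
    idx = np.where(free)[0]
    n = len(idx)
    x0 = theta.packed()

    def f(vec):
        return neg_log_posterior(spec, priors, data,
                                 HyperParams.from_packed(spec, vec, fixed_mask=theta.fixed_mask))

    H = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            xpp = x0.copy(); xpp[idx[a]] += step; xpp[idx[b]] += step
            xpm = x0.copy(); xpm[idx[a]] += step; xpm[idx[b]] -= step
            xmp = x0.copy(); xmp[idx[a]] -= step; xmp[idx[b]] += step
            xmm = x0.copy(); xmm[idx[a]] -= step; xmm[idx[b]] -= step
            val = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * step * step)
            H[a, b] = H[b, a] = val if np.isfinite(val) else 0.0
    w, V = np.linalg.eigh(0.5 * (H + H.T))
    w = np.maximum(w, float(np.min(1.0 / priors.scale[idx] ** 2)))
    return (V / w) @ V.T


def map_estimate(
    spec: ModelSpec,
    priors: PriorSpec,
    data: TimeSeriesSet,
    n_starts: int = 10,
    seed: int = 0,
    fixed: Mapping[str, float] | None = None,
    center: bool = False,
    max_iter: int = 2000,
    fatol: float = 1e-8,
    simplex_step: float = 0.25,
) -> MAPResult:
    """Multistart Nelder-Mead MAP estimate of the hyperparameters.

    Starting points are drawn from the priors (the first start sits at the
    prior mode); each start is refined with a derivative-free simplex search.
    The initial simplex is ``x0 + simplex_step * e_k``, which makes the search
    path exactly equivariant under translations in log space (e.g. rescaling
    the data and shifting the amplitude/noise priors accordingly).

    Parameters
    ----------
    fixed : mapping, optional
        Hyperparameters held constant, keyed by ``spec.param_names`` entries,
        values on the log scale.
    center : bool
        Subtract each output's sample mean before fitting (the GP prior has
        zero mean); the removed means are returned in ``output_means`` so
        prediction can restore them.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    output_means: dict[str, float] = {}
    if center:
        data, output_means = data.centered()

    names = spec.param_names
    fixed = dict(fixed or {})
    for name in fixed:
        if name not in names:
            raise KeyError(f"unknown hyperparameter {name!r}")
    fixed_mask = np.array([name in fixed for name in names])
    base = priors.loc.copy()
    for name, val in fixed.items():
        base[names.index(name)] = float(val)
    free = ~fixed_mask

    def unpack(x_free: np.ndarray) -> HyperParams:
        vec = base.copy()
        vec[free] = x_free
        return HyperParams.from_packed(spec, vec, fixed_mask=fixed_mask)

    def objective(x_free: np.ndarray) -> float:
        if not np.all(np.isfinite(x_free)) or np.max(np.abs(x_free)) > 40:
            return np.inf
        theta = unpack(x_free)
        try:
            ll = log_marginal_likelihood(spec, theta, data)
        except np.linalg.LinAlgError:
            return np.inf
        vec = theta.packed()
        return -(ll + priors.log_density(vec, mask=free))

    rng = np.random.default_rng(seed)
    starts = [priors.loc[free]]
    for _ in range(n_starts - 1):
        starts.append(priors.sample(rng)[free])

    best_x, best_f = None, np.inf
    start_values = []
    initial_best = np.inf
    for x0 in starts:
        f0 = objective(x0)
        start_values.append(f0)
        initial_best = min(initial_best, f0)
        if not np.isfinite(f0):
            continue
        dim = len(x0)
        simplex = np.vstack([x0] + [x0 + simplex_step * np.eye(dim)[k] for k in range(dim)])
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": max_iter,
                "fatol": fatol,
                "xatol": 1e-6,
                "initial_simplex": simplex,
                "adaptive": dim > 6,
            },
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    if best_x is None:
        warnings.warn("all optimization starts had non-finite objective; "
                      "returning the prior mode", RuntimeWarning)
        best_x, best_f = priors.loc[free], objective(priors.loc[free])
    improved = best_f < initial_best - 1e-12
    if not improved:
        warnings.warn("no start improved on its initial point", RuntimeWarning)

    theta = unpack(np.asarray(best_x))
    ll = log_marginal_likelihood(spec, theta, data)
    return MAPResult(
        theta=theta,
        log_posterior=-best_f,
        log_likelihood=ll,
        n_starts=n_starts,
        seed=seed,
        improved=improved,
        start_values=np.asarray(start_values),
        output_means=output_means,
    )
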