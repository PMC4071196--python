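"""Synthetic time-course generators with ground-truth derivatives and fluxes.

Four generators emulate the case studies the package targets:

* two noisy sinusoids (analytic derivatives),
* a two-metabolite linear pathway with inhibition and activation
  (saturable kinetics),
* a branched pathway with two regulatory signals (power-law, S-system style
  rate laws),
* a three-metabolite nitrogen-assimilation-like chain (alpha-ketoglutarate ->
  glutamate -> glutamine) with a decaying input flux after an ammonium spike
  and a "mutant" mode that scales down the glutamine-synthetase-like rate.

Every generator returns a dense truth grid (states, derivatives, fluxes, all
mutually consistent with ``dx/dt = S v``), noisy observations reproducible
from a seed, and the stoichiometry of the modelled metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .flux import Stoichiometry
from .io import TimeSeriesSet

__all__ = [
    "SimulationResult",
    "gen_oscillators",
    "gen_linear_pathway",
    "gen_branched_pathway",
    "gen_nitrogen_like",
]

TRUTH_GRID_POINTS = 200
RTOL, ATOL = 1e-8, 1e-10


@dataclass
class SimulationResult:
    """Ground truth plus noisy observations from one generator run."""

    times: np.ndarray
    states: dict[str, np.ndarray]
    derivatives: dict[str, np.ndarray]
    fluxes: dict[str, np.ndarray]
    observations: TimeSeriesSet
    truth_at_obs: dict[str, np.ndarray]
    noise_sd: dict[str, float]
    seed: int
    stoichiometry: Stoichiometry | None = None
    params: dict = field(default_factory=dict)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write observations and the truth bundle as delimited text."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        obs_path = directory / "observations.csv"
        self.observations.to_csv(obs_path)
        paths["observations"] = obs_path
        truth = pd.DataFrame({"time": self.times})
        for name, x in self.states.items():
            truth[f"state_{name}"] = x
        for name, dx in self.derivatives.items():
            truth[f"deriv_{name}"] = dx
        for name, v in self.fluxes.items():
            truth[f"flux_{name}"] = v
        truth_path = directory / "truth.csv"
        truth.to_csv(truth_path, index=False)
        paths["truth"] = truth_path
        return paths


def _default_obs_times(t_end: float, n: int = 20) -> np.ndarray:
    return np.linspace(0.0, t_end, n)


def _noise_sd_from_range(states: Mapping[str, np.ndarray],
                         sigma, outputs: Sequence[str],
                         frac: float = 0.01) -> dict[str, float]:
    """Per-output noise sd; default is ``frac`` of each output's dynamic range."""
    if sigma is None:
        return {o: max(frac * float(np.ptp(states[o])), 1e-12) for o in outputs}
    if np.isscalar(sigma):
        return {o: float(sigma) for o in outputs}
    return {o: float(sigma[o]) for o in outputs}


def _observe(dense: Callable[[np.ndarray], dict[str, np.ndarray]],
             obs_times: np.ndarray, noise_sd: Mapping[str, float],
             seed: int, outputs: Sequence[str]):
    rng = np.random.default_rng(seed)
    truth_at_obs = dense(obs_times)
    arrays = {}
    for o in outputs:  # fixed draw order => bit-reproducible per seed
        noise = rng.normal(0.0, noise_sd[o], size=len(obs_times))
        arrays[o] = (obs_times, truth_at_obs[o] + noise)
    obs = TimeSeriesSet.from_arrays(arrays)
    return obs, truth_at_obs


def gen_oscillators(
    amplitudes: Sequence[float] = (1.0, 0.7),
    angular_freqs: Sequence[float] = (1.0, 1.0),
    phases: Sequence[float] = (0.0, 0.8),
    sigma=None,
    obs_times: Sequence[float] | None = None,
    seed: int = 0,
    t_end: float = 10.0,
    outputs: Sequence[str] = ("z1", "z2"),
) -> SimulationResult:
    """Two noisy sinusoids ``A sin(w t + phi)`` with analytic derivative truth.

    Default observation noise is 5% of each signal's amplitude.  The two
    default signals share a frequency and differ in phase, the regime in
    which a shared latent source is informative.
    """
    A = np.asarray(amplitudes, float)
    w = np.asarray(angular_freqs, float)
    phi = np.asarray(phases, float)
    if not (len(A) == len(w) == len(phi) == len(outputs)):
        raise ValueError("amplitudes, angular_freqs, phases, outputs must align")
    obs_t = np.asarray(obs_times, float) if obs_times is not None else _default_obs_times(t_end, 30)
    grid = np.linspace(min(0.0, obs_t.min()), max(t_end, obs_t.max()), TRUTH_GRID_POINTS)

    def dense(t):
        return {o: A[i] * np.sin(w[i] * t + phi[i]) for i, o in enumerate(outputs)}

    def dense_deriv(t):
        return {o: A[i] * w[i] * np.cos(w[i] * t + phi[i]) for i, o in enumerate(outputs)}

    states = dense(grid)
    derivs = dense_deriv(grid)
    if sigma is None:
        noise_sd = {o: 0.05 * float(A[i]) for i, o in enumerate(outputs)}
    else:
        noise_sd = _noise_sd_from_range(states, sigma, outputs)
    obs, truth_at_obs = _observe(dense, obs_t, noise_sd, seed, outputs)
    return SimulationResult(
        times=grid, states=states, derivatives=derivs,
        fluxes={f"d{o}": derivs[o] for o in outputs},
        observations=obs, truth_at_obs=truth_at_obs, noise_sd=noise_sd, seed=seed,
        params={"amplitudes": A.tolist(), "angular_freqs": w.tolist(), "phases": phi.tolist()},
    )


# ---------------------------------------------------------------------------
# linear pathway: x1 --v1--> x2 --v2--> x3 --v3-->
#   v1 inhibited by x3, v2 activated by x3, v3 first-order efflux.

LINEAR_DEFAULTS = dict(k1=1.0, Ki=1.0, hi=2.0, k2=1.2, Ka=1.0, ha=2.0,
                       basal=0.1, k3=1.0)


def _linear_fluxes(x2, x3, x1, p):
    v1 = p["k1"] * x1 / (1.0 + (x3 / p["Ki"]) ** p["hi"])
    act = p["basal"] + (1.0 - p["basal"]) * x3 ** p["ha"] / (p["Ka"] ** p["ha"] + x3 ** p["ha"])
    v2 = p["k2"] * x2 * act
    v3 = p["k3"] * x3
    return v1, v2, v3


def gen_linear_pathway(
    params: Mapping[str, float] | None = None,
    x1_const: float = 2.0,
    init: Sequence[float] = (0.5, 0.2),
    sigma=None,
    obs_times: Sequence[float] | None = None,
    seed: int = 0,
    t_end: float = 10.0,
) -> SimulationResult:
    """Two-metabolite linear pathway with inhibition and activation.

    The conversion of the constant external substrate x1 into x2 (flux v1) is
    inhibited by the end product x3; the conversion of x2 into x3 (flux v2)
    is activated by x3 (with a small basal activity so the pathway can start
    from low x3); v3 is a first-order efflux.  Balances:
    ``dx2/dt = v1 - v2``, ``dx3/dt = v2 - v3``.
    """
    p = {**LINEAR_DEFAULTS, **(params or {})}
    if any(x <= 0 for x in init):
        raise ValueError("initial conditions must be positive")

    def rhs(t, x):
        x2, x3 = np.maximum(x, 1e-12)
        v1, v2, v3 = _linear_fluxes(x2, x3, x1_const, p)
        return [v1 - v2, v2 - v3]

    obs_t = np.asarray(obs_times, float) if obs_times is not None else _default_obs_times(t_end)
    grid = np.linspace(0.0, max(t_end, obs_t.max()), TRUTH_GRID_POINTS)
    sol = solve_ivp(rhs, (0.0, grid[-1]), list(init), method="LSODA",
                    rtol=RTOL, atol=ATOL, dense_output=True)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    def dense(t):
        x = sol.sol(np.asarray(t, float))
        return {"x2": x[0], "x3": x[1]}

    states = dense(grid)
    v1, v2, v3 = _linear_fluxes(states["x2"], states["x3"], x1_const, p)
    derivs = {"x2": v1 - v2, "x3": v2 - v3}
    st = Stoichiometry(
        metabolites=("x2", "x3"),
        fluxes=("v1", "v2", "v3"),
        S=np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]),
    )
    noise_sd = _noise_sd_from_range(states, sigma, ("x2", "x3"))
    obs, truth_at_obs = _observe(dense, obs_t, noise_sd, seed, ("x2", "x3"))
    return SimulationResult(
        times=grid, states=states, derivatives=derivs,
        fluxes={"v1": v1, "v2": v2, "v3": v3},
        observations=obs, truth_at_obs=truth_at_obs, noise_sd=noise_sd, seed=seed,
        stoichiometry=st, params={**p, "x1_const": x1_const, "init": list(init)},
    )


# ---------------------------------------------------------------------------
# branched pathway: v1 -> x1; x1 --v2--> x2 --v3--> x3;  x1 --v4--> (branch)
#   v2 inhibited by x3, v4 activated by x2.  Only x2, x3 are measured, so the
#   usable balances are dx2/dt = v2 - v3 and dx3/dt = v3: v2 and v3 are
#   estimable, v1 and v4 (which enter only the unmeasured x1 balance) are not.

BRANCHED_DEFAULTS = dict(a1=1.0, a2=1.5, g1=0.5, g3=-0.8,
                         a3=1.2, h2=0.75, a4=0.8, f1=0.5, f4=0.6)


def _branched_fluxes(x1, x2, x3, p):
    v1 = p["a1"] * np.ones_like(np.asarray(x1, float))
    v2 = p["a2"] * x1 ** p["g1"] * x3 ** p["g3"]
    v3 = p["a3"] * x2 ** p["h2"]
    v4 = p["a4"] * x1 ** p["f1"] * x2 ** p["f4"]
    return v1, v2, v3, v4


def gen_branched_pathway(
    params: Mapping[str, float] | None = None,
    init: Sequence[float] = (1.0, 0.6, 0.8),
    sigma=None,
    obs_times: Sequence[float] | None = None,
    seed: int = 0,
    t_end: float = 8.0,
) -> SimulationResult:
    """Branched pathway with power-law (S-system style) rate laws.

    x3 inhibits the conversion of x1 into x2 (negative exponent ``g3`` in
    v2); x2 positively regulates the branch reaction v4 (exponent ``f4``;
    setting it to 0 removes the regulation).  Exported stoichiometry covers
    the measured metabolites x2 and x3 only, so classification reports v2 and
    v3 as estimable and v1, v4 as underdetermined.
    """
    p = {**BRANCHED_DEFAULTS, **(params or {})}
    if any(x <= 0 for x in init):
        raise ValueError("initial conditions must be positive")

    def rhs(t, x):
        x1, x2, x3 = np.maximum(x, 1e-12)
        v1, v2, v3, v4 = _branched_fluxes(x1, x2, x3, p)
        return [v1 - v2 - v4, v2 - v3, v3]

    obs_t = np.asarray(obs_times, float) if obs_times is not None else _default_obs_times(t_end)
    grid = np.linspace(0.0, max(t_end, obs_t.max()), TRUTH_GRID_POINTS)
    sol = solve_ivp(rhs, (0.0, grid[-1]), list(init), method="LSODA",
                    rtol=RTOL, atol=ATOL, dense_output=True)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    def dense(t):
        x = sol.sol(np.asarray(t, float))
        return {"x2": x[1], "x3": x[2]}

    x = sol.sol(grid)
    states_all = {"x1": x[0], "x2": x[1], "x3": x[2]}
    v1, v2, v3, v4 = _branched_fluxes(x[0], x[1], x[2], p)
    derivs = {"x2": v2 - v3, "x3": v3}
    st = Stoichiometry(
        metabolites=("x2", "x3"),
        fluxes=("v1", "v2", "v3", "v4"),
        S=np.array([[0.0, 1.0, -1.0, 0.0],
                    [0.0, 0.0, 1.0, 0.0]]),
    )
    noise_sd = _noise_sd_from_range({"x2": x[1], "x3": x[2]}, sigma, ("x2", "x3"))
    obs, truth_at_obs = _observe(dense, obs_t, noise_sd, seed, ("x2", "x3"))
    return SimulationResult(
        times=grid, states={"x2": states_all["x2"], "x3": states_all["x3"]},
        derivatives=derivs,
        fluxes={"v1": v1, "v2": v2, "v3": v3, "v4": v4},
        observations=obs, truth_at_obs=truth_at_obs, noise_sd=noise_sd, seed=seed,
        stoichiometry=st,
        params={**p, "init": list(init), "x1_truth": states_all["x1"]},
    )


# ---------------------------------------------------------------------------
# nitrogen-assimilation-like chain: TCA --v1--> aKG --v2--> GLU --v3--> GLN
#   v1 is a decaying input after an ammonium spike; v2 is GDH-like
#   (Michaelis-Menten in aKG); v3 lumps the GS/GOGAT conversion of GLU to GLN
#   (Michaelis-Menten in GLU), scaled down in the mutant mode.

NITROGEN_DEFAULTS = dict(v1_base=0.2, v1_amp=1.5, v1_tau=2.0,
                         k2=1.5, K2=0.5, k3=1.2, K3=0.5)


def gen_nitrogen_like(
    params: Mapping[str, float] | None = None,
    init: Sequence[float] = (0.3, 0.5, 0.2),
    sigma=None,
    obs_times: Sequence[float] | None = None,
    seed: int = 0,
    t_end: float = 10.0,
    mutant_scale: float = 1.0,
    outputs: Sequence[str] = ("aKG", "GLU", "GLN"),
) -> SimulationResult:
    """Three-metabolite nitrogen-assimilation surrogate.

    ``mutant_scale`` multiplies the GS-like rate constant ``k3``; values
    below 1 emulate a strain with reduced glutamine-synthetase expression
    (lower GLU -> GLN flux).  Balances: ``d[aKG]/dt = v1 - v2``,
    ``d[GLU]/dt = v2 - v3``, ``d[GLN]/dt = v3``.
    """
    p = {**NITROGEN_DEFAULTS, **(params or {})}
    if any(x <= 0 for x in init):
        raise ValueError("initial conditions must be positive")
    if mutant_scale <= 0:
        raise ValueError("mutant_scale must be positive")
    akg_l, glu_l, gln_l = outputs

    def input_flux(t):
        return p["v1_base"] + p["v1_amp"] * np.exp(-np.asarray(t, float) / p["v1_tau"])

    def fluxes_of(t, akg, glu):
        v1 = input_flux(t)
        v2 = p["k2"] * akg / (p["K2"] + akg)
        v3 = mutant_scale * p["k3"] * glu / (p["K3"] + glu)
        return v1, v2, v3

    def rhs(t, x):
        akg, glu, _ = np.maximum(x, 1e-12)
        v1, v2, v3 = fluxes_of(t, akg, glu)
        return [v1 - v2, v2 - v3, v3]

    obs_t = np.asarray(obs_times, float) if obs_times is not None else _default_obs_times(t_end)
    grid = np.linspace(0.0, max(t_end, obs_t.max()), TRUTH_GRID_POINTS)
    sol = solve_ivp(rhs, (0.0, grid[-1]), list(init), method="LSODA",
                    rtol=RTOL, atol=ATOL, dense_output=True)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    def dense(t):
        x = sol.sol(np.asarray(t, float))
        return {akg_l: x[0], glu_l: x[1], gln_l: x[2]}

    states = dense(grid)
    v1, v2, v3 = fluxes_of(grid, states[akg_l], states[glu_l])
    derivs = {akg_l: v1 - v2, glu_l: v2 - v3, gln_l: v3}
    st = Stoichiometry(
        metabolites=(akg_l, glu_l, gln_l),
        fluxes=("v1", "v2", "v3"),
        S=np.array([[1.0, -1.0, 0.0],
                    [0.0, 1.0, -1.0],
                    [0.0, 0.0, 1.0]]),
    )
    noise_sd = _noise_sd_from_range(states, sigma, outputs)
    obs, truth_at_obs = _observe(dense, obs_t, noise_sd, seed, outputs)
    return SimulationResult(
        times=grid, states=states, derivatives=derivs,
        fluxes={"v1": v1, "v2": v2, "v3": v3},
        observations=obs, truth_at_obs=truth_at_obs, noise_sd=noise_sd, seed=seed,
        stoichiometry=st,
        params={**p, "init": list(init), "mutant_scale": mutant_scale},
    )
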