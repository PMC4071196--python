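"""Flux estimation: map derivative posteriors through a stoichiometric system.

Metabolite balances give the linear system ``dx/dt = S v`` between the
derivative trajectories of the modelled metabolites and the reaction fluxes.
After substituting any fluxes declared known, a flux is *estimable* when its
value is a unique linear functional of the derivatives and known fluxes —
equivalently, when its coordinate is orthogonal to the null space of the
reduced stoichiometric matrix.  Estimable fluxes inherit an exact Gaussian
posterior from the joint derivative posterior (linear maps of Gaussians);
non-estimable fluxes are reported with an explicit "underdetermined" status
rather than a silently regularized number.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .predict import PosteriorPrediction

__all__ = [
    "FluxStatus",
    "Stoichiometry",
    "FluxEstimate",
    "InconsistentSystemError",
    "classify_system",
    "estimate_fluxes",
]

_NULL_TOL = 1e-10


class InconsistentSystemError(ValueError):
    """Known fluxes are incompatible with the derivative data (overdetermined clash)."""


class FluxStatus(str, enum.Enum):
    KNOWN = "known"
    ESTIMABLE = "estimable"
    UNDERDETERMINED = "underdetermined"
    MINIMUM_NORM = "minimum_norm"


KnownFlux = Callable[[np.ndarray], np.ndarray] | tuple[np.ndarray, np.ndarray] | float


@dataclass
class Stoichiometry:
    """The linear map ``d(metabolites)/dt = S . fluxes``.

    ``S`` has one row per *modelled* metabolite (a metabolite must have a
    derivative posterior to contribute an equation) and one column per flux.
    ``known_fluxes`` maps flux labels to a constant, a callable ``f(t)``, or a
    ``(times, values)`` pair evaluated on the prediction grid.
    """

    metabolites: tuple[str, ...]
    fluxes: tuple[str, ...]
    S: np.ndarray
    known_fluxes: dict[str, KnownFlux] = field(default_factory=dict)

    def __post_init__(self):
        self.metabolites = tuple(self.metabolites)
        self.fluxes = tuple(self.fluxes)
        self.S = np.asarray(self.S, float)
        if len(set(self.metabolites)) != len(self.metabolites):
            raise ValueError("duplicate metabolite labels")
        if len(set(self.fluxes)) != len(self.fluxes):
            raise ValueError("duplicate flux labels")
        if self.S.shape != (len(self.metabolites), len(self.fluxes)):
            raise ValueError(
                f"S must be {len(self.metabolites)} x {len(self.fluxes)}, got {self.S.shape}"
            )
        if not np.all(np.isfinite(self.S)):
            raise ValueError("S contains non-finite coefficients")
        unknown = set(self.known_fluxes) - set(self.fluxes)
        if unknown:
            raise ValueError(f"known_fluxes reference unknown flux labels: {sorted(unknown)}")

    @property
    def unknown_fluxes(self) -> tuple[str, ...]:
        return tuple(f for f in self.fluxes if f not in self.known_fluxes)

    def reduced_matrix(self) -> np.ndarray:
        """Columns of S for the unknown fluxes."""
        idx = [self.fluxes.index(f) for f in self.unknown_fluxes]
        return self.S[:, idx]

    def known_matrix(self) -> np.ndarray:
        idx = [self.fluxes.index(f) for f in self.known_fluxes]
        return self.S[:, idx]


def classify_system(st: Stoichiometry) -> dict[str, FluxStatus]:
    """Per-flux determination status after substituting the known fluxes.

    A flux is estimable when its value is the same for every solution of the
    reduced system, i.e. its coordinate vector is orthogonal to the null
    space of ``S`` restricted to unknown fluxes.
    """
    status = {f: FluxStatus.KNOWN for f in st.known_fluxes}
    unknown = st.unknown_fluxes
    if not unknown:
        return status
    Su = st.reduced_matrix()
    N = null_space(Su)
    for j, f in enumerate(unknown):
        free = N.shape[1] > 0 and np.max(np.abs(N[j, :])) > _NULL_TOL
        status[f] = FluxStatus.UNDERDETERMINED if free else FluxStatus.ESTIMABLE
    return {f: status[f] for f in st.fluxes}


def system_classification(st: Stoichiometry) -> str:
    """Whole-system label: 'uniquely determined', 'underdetermined' or 'overdetermined'."""
    Su = st.reduced_matrix()
    r = np.linalg.matrix_rank(Su) if Su.size else 0
    if r < Su.shape[1]:
        return "underdetermined"
    if Su.shape[0] > r:
        return "overdetermined"
    return "uniquely determined"


def _known_values(st: Stoichiometry, times: np.ndarray,
                  interpolate: bool) -> np.ndarray:
    """Known-flux values on the grid, shape (n_known, T)."""
    vals = []
    for f, spec in st.known_fluxes.items():
        if callable(spec):
            v = np.asarray(spec(times), float)
            if v.shape != times.shape:
                v = np.broadcast_to(v, times.shape).astype(float)
        elif np.isscalar(spec):
            v = np.full_like(times, float(spec))
        else:
            kt, kv = (np.asarray(a, float) for a in spec)
            if kt.shape != kv.shape:
                raise ValueError(f"known flux {f!r}: times/values length mismatch")
            if np.array_equal(kt, times):
                v = kv
            elif interpolate:
                order = np.argsort(kt)
                v = np.interp(times, kt[order], kv[order])
            else:
                raise ValueError(
                    f"known flux {f!r} is tabulated on a different time grid than the "
                    "prediction; pass interpolate_known=True to allow linear interpolation"
                )
        vals.append(v)
    return np.vstack(vals) if vals else np.zeros((0, len(times)))


@dataclass
class FluxEstimate:
    """Gaussian flux trajectories plus per-flux determination status."""

    times: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    status: dict[str, FluxStatus]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, st in self.status.items():
            if f in self.mean:
                rows.append(pd.DataFrame({
                    "flux": f, "time": self.times, "mean": self.mean[f],
                    "sd": self.sd[f], "status": st.value,
                }))
            else:
                rows.append(pd.DataFrame({
                    "flux": [f], "time": [np.nan], "mean": [np.nan],
                    "sd": [np.nan], "status": [st.value],
                }))
        return pd.concat(rows, ignore_index=True)


def estimate_fluxes(
    st: Stoichiometry,
    pred: PosteriorPrediction,
    min_norm: bool = False,
    interpolate_known: bool = False,
) -> FluxEstimate:
    """Posterior flux trajectories from a joint derivative posterior.

    Every metabolite row of ``S`` must have a derivative posterior in
    ``pred``, all on an identical time grid.  For each estimable flux the
    solved system yields a row vector ``a`` with
    ``v_j(t) = a . (dx/dt(t) - S_known v_known(t))``; the posterior mean and
    the exactly propagated variance ``a' Sigma(t) a`` (from the cross-output
    joint derivative covariance at time ``t``) are returned.  With
    ``min_norm=True`` non-estimable fluxes additionally receive the
    minimum-norm (pseudoinverse) solution, flagged as such, with a warning.
    """
    missing = [m for m in st.metabolites if m not in pred.outputs]
    if missing:
        raise KeyError(f"no derivative posterior for metabolites {missing}")
    times = np.asarray(pred.test_times[st.metabolites[0]], float)
    for m in st.metabolites[1:]:
        if not np.array_equal(np.asarray(pred.test_times[m], float), times):
            raise ValueError(
                f"metabolite {m!r} is predicted on a different time grid than "
                f"{st.metabolites[0]!r}; flux estimation needs one shared grid"
            )
    if pred.joint_cov is None:
        raise ValueError("flux estimation requires a prediction with the full joint covariance")

    m = len(st.metabolites)
    T = len(times)
    D = np.vstack([pred.mean_derivative[mm] for mm in st.metabolites])  # (m, T)
    Vk = _known_values(st, times, interpolate_known)                    # (k, T)
    B = D - st.known_matrix() @ Vk                                      # rhs b(t), (m, T)

    # per-time cross-metabolite derivative covariance, (T, m, m)
    didx = np.array([[pred.derivative_slices[mm].start + k for mm in st.metabolites]
                     for k in range(T)])
    Sigma = pred.joint_cov[didx[:, :, None], didx[:, None, :]]

    status = classify_system(st)
    unknown = st.unknown_fluxes
    result_mean: dict[str, np.ndarray] = {}
    result_sd: dict[str, np.ndarray] = {}
    if unknown:
        Su = st.reduced_matrix()
        A = np.linalg.pinv(Su)  # (u, m); rows are the solution functionals

        rank = np.linalg.matrix_rank(Su)
        if Su.shape[0] > rank:
            _check_consistency(Su, A, B, Sigma)

        for j, f in enumerate(unknown):
            if status[f] is FluxStatus.ESTIMABLE:
                a = A[j]
            elif min_norm:
                a = A[j]
                status[f] = FluxStatus.MINIMUM_NORM
                warnings.warn(
                    f"flux {f!r} is not uniquely determined; reporting the "
                    "minimum-norm solution", RuntimeWarning,
                )
            else:
                continue
            result_mean[f] = a @ B
            var = np.einsum("i,tij,j->t", a, Sigma, a)
            result_sd[f] = np.sqrt(np.clip(var, 0.0, None))

    for f, spec in st.known_fluxes.items():
        vals = _known_values(
            Stoichiometry(st.metabolites, (f,), np.zeros((m, 1)), {f: spec}),
            times, interpolate_known,
        )[0]
        result_mean[f] = vals
        result_sd[f] = np.zeros_like(vals)

    return FluxEstimate(times=times, mean=result_mean, sd=result_sd,
                        status={f: status[f] for f in st.fluxes})


def _check_consistency(Su, A, B, Sigma):
    """Raise when redundant equations disagree far beyond posterior uncertainty."""
    P = np.eye(Su.shape[0]) - Su @ A  # projector onto the left null space
    resid = P @ B                     # (m, T)
    sd = np.sqrt(np.clip(np.einsum("ij,tjk,ik->it", P, Sigma, P), 0.0, None))
    z = np.abs(resid) / np.maximum(sd, 1e-12)
    row_scale = np.max(np.abs(P), axis=1)
    meaningful = row_scale > 1e-8
    if np.any(meaningful) and float(np.median(z[meaningful])) > 5.0:
        raise InconsistentSystemError(
            "the known fluxes are incompatible with the derivative posteriors: "
            "redundant balance equations disagree by more than 5 posterior sd"
        )
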