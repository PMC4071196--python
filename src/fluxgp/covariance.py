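"""Closed-form covariance calculus for process-convolution Gaussian processes.

Each output :math:`Y_i(t)` is a sum of convolutions of shared latent white-noise
sources with zero-centred Gaussian impulse-response kernels
:math:`h(t) = A \\exp(-\\tfrac12 b t^2)`.  Because the convolution of two
Gaussians is Gaussian, every auto- and cross-covariance — including those of
the derivative processes :math:`U_i = dY_i/dt` — has a closed form.  For a
kernel pair :math:`(h, g)` attached to the same source,

.. math::

    k_{hg}(d) = A_h A_g \\sqrt{\\frac{2\\pi}{b_h + b_g}}
                \\exp\\!\\Big(-\\tfrac12 \\frac{b_h b_g}{b_h + b_g} d^2\\Big),
    \\qquad d = t - t',

and the derivative covariances follow by differentiating in :math:`d`.
All scale is carried by the amplitudes: the latent white-noise sources have
unit spectral density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - type-only imports
    from .model import HyperParams, ModelSpec

__all__ = [
    "KernelSpec",
    "CovarianceBlocks",
    "CovarianceConditioningError",
    "cov_yy",
    "cov_uy",
    "cov_uu",
    "build_joint_covariance",
    "cholesky_with_jitter",
]

#: Relative jitter first added to the diagonal of the observation block.
JITTER_BASE = 1e-10
#: Largest relative jitter tried before a conditioning error is raised.
JITTER_MAX = 1e-6


class CovarianceConditioningError(np.linalg.LinAlgError):
    """A covariance block failed Cholesky factorization even after jitter escalation."""


@dataclass(frozen=True)
class KernelSpec:
    """A Gaussian impulse-response kernel on one (source, output) edge.

    Parameters
    ----------
    amplitude : float
        Kernel amplitude ``A`` (signal units); must be positive.
    inv_width : float
        Inverse squared width ``b`` (1/time^2) of the Gaussian kernel;
        must be positive.  Large ``b`` means a narrow kernel and hence a
        rough, short-memory output process.
    source_id, output_id : str
        Labels of the latent white-noise source and of the output the
        kernel feeds.
    """

    amplitude: float
    inv_width: float
    source_id: str
    output_id: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.amplitude) and self.amplitude > 0):
            raise ValueError(f"kernel amplitude must be finite and > 0, got {self.amplitude}")
        if not (np.isfinite(self.inv_width) and self.inv_width > 0):
            raise ValueError(f"kernel inv_width must be finite and > 0, got {self.inv_width}")


def _shared_pairs(
    kernels_i: Sequence[KernelSpec], kernels_j: Sequence[KernelSpec]
) -> list[tuple[float, float]]:
    """(coefficient, shape) for every kernel pair sharing a latent source.

    The pair term is ``coef * exp(-0.5 * shape * d**2)`` with
    ``shape = b_h * b_g / (b_h + b_g)``.
    """
    pairs = []
    for h in kernels_i:
        for g in kernels_j:
            if h.source_id != g.source_id:
                continue
            bsum = h.inv_width + g.inv_width
            shape = h.inv_width * g.inv_width / bsum
            coef = h.amplitude * g.amplitude * math.sqrt(2.0 * math.pi / bsum)
            pairs.append((coef, shape))
    return pairs


def cov_yy(
    kernels_i: Sequence[KernelSpec],
    kernels_j: Sequence[KernelSpec],
    d: float | np.ndarray,
):
    """Covariance of two original processes at temporal separation ``d = t - t'``.

    Sums the closed-form convolution term over all kernel pairs attached to a
    shared source.  Outputs with no shared source are independent and the
    covariance is exactly zero.
    """
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    for coef, shape in _shared_pairs(kernels_i, kernels_j):
        out = out + coef * np.exp(-0.5 * shape * d * d)
    return out if out.ndim else float(out)


def cov_uy(
    kernels_i: Sequence[KernelSpec],
    kernels_j: Sequence[KernelSpec],
    d: float | np.ndarray,
):
    """Covariance of a derivative process against an original process.

    Returns ``cov(U_i(t), Y_j(t'))`` with ``d = t - t'``; the derivative is
    taken on the *first* argument, so this is ``d/dd cov_yy(d)``.  It is an
    odd function of ``d``; ``cov(Y_i(t), U_j(t'))`` is its negative.
    """
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    for coef, shape in _shared_pairs(kernels_i, kernels_j):
        out = out - coef * shape * d * np.exp(-0.5 * shape * d * d)
    return out if out.ndim else float(out)


def cov_uu(
    kernels_i: Sequence[KernelSpec],
    kernels_j: Sequence[KernelSpec],
    d: float | np.ndarray,
):
    """Covariance of two derivative processes, ``-d^2/dd^2 cov_yy(d)``."""
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    for coef, shape in _shared_pairs(kernels_i, kernels_j):
        out = out + coef * shape * (1.0 - shape * d * d) * np.exp(-0.5 * shape * d * d)
    return out if out.ndim else float(out)


_KINDS = {"yy": cov_yy, "uy": cov_uy, "uu": cov_uu}


def _block(kernels_i, kernels_j, t1: np.ndarray, t2: np.ndarray, kind: str) -> np.ndarray:
    """Dense covariance block between two point sets; ``kind`` in {yy, uy, yu, uu}."""
    d = np.subtract.outer(np.asarray(t1, float), np.asarray(t2, float))
    if kind == "yu":  # derivative on the second argument flips the sign
        return -np.asarray(cov_uy(kernels_i, kernels_j, d))
    return np.asarray(_KINDS[kind](kernels_i, kernels_j, d))


def cholesky_with_jitter(K: np.ndarray, name: str = "covariance"):
    """Lower Cholesky factor of ``K``, escalating diagonal jitter if needed.

    Starts from ``JITTER_BASE * mean(diag)`` and multiplies by 10 up to
    ``JITTER_MAX * mean(diag)``; beyond that a
    :class:`CovarianceConditioningError` naming the offending block is raised.
    Returns ``(L, jitter_added)``.
    """
    K = np.asarray(K, float)
    if K.size == 0:
        return np.zeros_like(K), 0.0
    scale = float(np.mean(np.diag(K)))
    if not np.isfinite(scale):
        raise CovarianceConditioningError(f"{name} block has a non-finite diagonal")
    scale = max(abs(scale), np.finfo(float).tiny)
    jitter = 0.0
    while True:
        try:
            L = np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))
            return L, jitter
        except np.linalg.LinAlgError:
            jitter = JITTER_BASE * scale if jitter == 0.0 else jitter * 10.0
            if jitter > JITTER_MAX * scale:
                raise CovarianceConditioningError(
                    f"{name} block is not positive definite even after jitter "
                    f"escalation to {JITTER_MAX:g} x mean(diag)"
                ) from None


@dataclass
class CovarianceBlocks:
    """Assembled joint covariance over observations, test functions and test derivatives.

    Attributes
    ----------
    K_obs : (N, N) array
        Observation block: ``cov_yy`` plus per-observation noise variances and
        a small base jitter on the diagonal.
    cross_f, cross_d : (N, T) arrays
        Covariances of the observations against the test-point function values
        and derivative values respectively.
    CC, DC, DDC : (T, T) arrays
        Test blocks: function x function, derivative x function
        (``DC[a, b] = cov(U(t_a), Z(t_b))``), derivative x derivative.
    noise_diag : (N,) array
        Per-observation noise variances (sigma_i^2).
    obs_slices, test_slices : dict
        Index ranges per output inside the observation / test orderings.
    """

    K_obs: np.ndarray
    cross_f: np.ndarray
    cross_d: np.ndarray
    CC: np.ndarray
    DC: np.ndarray
    DDC: np.ndarray
    noise_diag: np.ndarray
    obs_slices: dict = field(default_factory=dict)
    test_slices: dict = field(default_factory=dict)
    jitter: float = 0.0

    @property
    def n_obs(self) -> int:
        return self.K_obs.shape[0]

    @property
    def n_test(self) -> int:
        return self.CC.shape[0]

    def cross(self) -> np.ndarray:
        """(N, 2T) covariance of observations against [functions; derivatives]."""
        return np.hstack([self.cross_f, self.cross_d])

    def test_cov(self) -> np.ndarray:
        """(2T, 2T) prior covariance of [functions; derivatives] at test points."""
        return np.block([[self.CC, self.DC.T], [self.DC, self.DDC]])

    def assembled(self) -> np.ndarray:
        """Full joint matrix over [observations; functions; derivatives]."""
        X = self.cross()
        return np.block([[self.K_obs, X], [X.T, self.test_cov()]])


def build_joint_covariance(
    spec: "ModelSpec",
    theta: "HyperParams",
    obs_times: Mapping[str, Sequence[float]],
    test_times: Mapping[str, Sequence[float]] | None = None,
) -> CovarianceBlocks:
    """Assemble all covariance blocks for a model at given hyperparameters.

    ``obs_times`` / ``test_times`` map output labels to 1-D time arrays; either
    may be empty (likelihood-only or prior-only use).  Outputs are laid out in
    the order of ``spec.outputs``; for the test blocks, all function values
    come first, then all derivatives, each in the same per-output order.
    """
    test_times = test_times or {}
    for label in list(obs_times) + list(test_times):
        if label not in spec.outputs:
            raise KeyError(f"unknown output {label!r}; model outputs are {list(spec.outputs)}")
    packed = theta.packed()
    if not np.all(np.isfinite(packed)):
        raise ValueError("hyperparameters must be finite")

    kernels = spec.kernel_sets(theta)
    noise_sd = dict(zip(spec.outputs, theta.noise_sd))

    obs_out = [o for o in spec.outputs if o in obs_times and len(np.atleast_1d(obs_times[o]))]
    test_out = [o for o in spec.outputs if o in test_times and len(np.atleast_1d(test_times[o]))]
    ot = {o: np.atleast_1d(np.asarray(obs_times[o], float)) for o in obs_out}
    tt = {o: np.atleast_1d(np.asarray(test_times[o], float)) for o in test_out}
    for o, t in list(ot.items()) + list(tt.items()):
        if not np.all(np.isfinite(t)):
            raise ValueError(f"non-finite time for output {o!r}")

    obs_slices, pos = {}, 0
    for o in obs_out:
        obs_slices[o] = slice(pos, pos + len(ot[o]))
        pos += len(ot[o])
    n_obs = pos
    test_slices, pos = {}, 0
    for o in test_out:
        test_slices[o] = slice(pos, pos + len(tt[o]))
        pos += len(tt[o])
    n_test = pos

    K_obs = np.zeros((n_obs, n_obs))
    noise_diag = np.zeros(n_obs)
    for i in obs_out:
        for j in obs_out:
            K_obs[obs_slices[i], obs_slices[j]] = _block(kernels[i], kernels[j], ot[i], ot[j], "yy")
        noise_diag[obs_slices[i]] = noise_sd[i] ** 2
    K_obs[np.diag_indices(n_obs)] += noise_diag
    K_obs = 0.5 * (K_obs + K_obs.T)
    jitter = 0.0
    if n_obs:
        jitter = JITTER_BASE * float(np.mean(np.diag(K_obs)))
        K_obs[np.diag_indices(n_obs)] += jitter

    cross_f = np.zeros((n_obs, n_test))
    cross_d = np.zeros((n_obs, n_test))
    for i in obs_out:
        for j in test_out:
            cross_f[obs_slices[i], test_slices[j]] = _block(kernels[i], kernels[j], ot[i], tt[j], "yy")
            cross_d[obs_slices[i], test_slices[j]] = _block(kernels[i], kernels[j], ot[i], tt[j], "yu")

    CC = np.zeros((n_test, n_test))
    DC = np.zeros((n_test, n_test))
    DDC = np.zeros((n_test, n_test))
    for i in test_out:
        for j in test_out:
            CC[test_slices[i], test_slices[j]] = _block(kernels[i], kernels[j], tt[i], tt[j], "yy")
            DC[test_slices[i], test_slices[j]] = _block(kernels[i], kernels[j], tt[i], tt[j], "uy")
            DDC[test_slices[i], test_slices[j]] = _block(kernels[i], kernels[j], tt[i], tt[j], "uu")
    CC = 0.5 * (CC + CC.T)
    DDC = 0.5 * (DDC + DDC.T)

    return CovarianceBlocks(
        K_obs=K_obs,
        cross_f=cross_f,
        cross_d=cross_d,
        CC=CC,
        DC=DC,
        DDC=DDC,
        noise_diag=noise_diag,
        obs_slices=obs_slices,
        test_slices=test_slices,
        jitter=jitter,
    )
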