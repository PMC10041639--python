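"""Reweighted anisotropic kernels and unbiased Markov transition matrices.

The construction follows the reweighted diffusion map.  From ``N`` samples
``x_k`` with statistical weights ``w_k = p(x_k)/q(x_k)`` (unit weights for
equilibrium data):

1. Gaussian locality kernel ``g_eps(x_k, x_l) = exp(-||x_k - x_l||^2 / 2 eps^2)``
   with the scale constant ``eps`` set to the median of all pairwise
   Euclidean distances in the active variable subspace.
2. Reweighted kernel density estimate ``rho(x) = sum_k w_k g_eps(x, x_k)``
   (self-term included), proportional to the *unbiased* density ``p``; at
   unit weights this is the plain kernel density estimate of the sampled
   density.
3. Reweighted anisotropic kernel
   ``K_kl = r(x_k, x_l) g_eps(x_k, x_l) / sqrt(rho(x_k) rho(x_l))`` with the
   diffusion-reweighting factor ``r(x_k, x_l) = w_k w_l``.
4. Row normalisation ``m_kl = K_kl / sum_l K_kl`` giving a row-stochastic
   Markov transition matrix ``M``.

With biased samples the reweighting makes ``M`` converge to the transition
matrix of the *unbiased* dynamics: in the row sums the sampled measure ``q``
combines with ``w / sqrt(rho) ~ (p/q) / sqrt(p)`` to the same
``sqrt(p)``-weighted averages that the standard anisotropic (alpha = 1/2)
diffusion map produces from equilibrium samples.  Equivalently this is the
target-measure diffusion map with the unbiased density as target, written in
terms of statistical weights.  At unit weights the kernel reduces exactly to
the standard anisotropic kernel.  Global rescaling of the weights multiplies
the kernel by a constant and cancels in the row normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import WeightedDataset
from .errors import DegenerateSubspaceError, ValidationError

__all__ = [
    "KernelMatrix",
    "TransitionMatrix",
    "estimate_scale",
    "gaussian_kernel",
    "density_estimate",
    "reweighting_factor",
    "reweighted_kernel",
    "transition_matrix",
]


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric positive kernel with its scale constant and density estimate.

    ``values`` is the ``N x N`` reweighted anisotropic kernel, ``epsilon`` the
    Gaussian bandwidth used, and ``density`` the (weight-reweighted) kernel
    density estimate ``rho`` at every sample.  For unbiased (unit-weight)
    data each density entry is >= 1 because the self-term contributes
    ``g = 1``.
    """

    values: np.ndarray
    epsilon: float
    density: np.ndarray


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic Markov transition matrix and its generating kernel."""

    values: np.ndarray
    source: KernelMatrix

    @property
    def n_states(self) -> int:
        return self.values.shape[0]


def _pair_distances(
    x: np.ndarray,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    n = x.shape[0]
    n_pairs = n * (n - 1) // 2
    if max_pairs is not None and n_pairs > max_pairs:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n - 1, size=max_pairs)
        j = np.where(j >= i, j + 1, j)  # j != i, uniform over off-diagonal pairs
        diff = x[i] - x[j]
        return np.sqrt(np.einsum("ij,ij->i", diff, diff))
    return pdist(x)


def estimate_scale(
    dataset: WeightedDataset,
    subset: Iterable[int] | None = None,
    *,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> float:
    """Median pairwise Euclidean distance in the chosen variable subspace.

    This is the Gaussian-kernel scale constant ``eps``.  All ``N(N-1)/2``
    pairs enter the median; ``max_pairs`` optionally caps the count with
    seeded subsampling for very large ``N``.

    Raises
    ------
    DegenerateSubspaceError
        If the median distance is zero (the samples coincide in the
        subspace); no fallback bandwidth is ever substituted.
    """
    idx = dataset.resolve_subset(subset)
    dists = _pair_distances(dataset.samples[:, idx], max_pairs, seed)
    eps = float(np.median(dists))
    if eps <= 0.0:
        raise DegenerateSubspaceError(idx)
    return eps


def gaussian_kernel(xk: np.ndarray, xl: np.ndarray, epsilon: float) -> float:
    """Pointwise Gaussian kernel ``exp(-||xk - xl||^2 / 2 eps^2)``."""
    xk = np.asarray(xk, dtype=np.float64)
    xl = np.asarray(xl, dtype=np.float64)
    if xk.shape != xl.shape:
        raise ValidationError(f"shape mismatch: {xk.shape} vs {xl.shape}")
    if not (np.all(np.isfinite(xk)) and np.all(np.isfinite(xl))):
        raise ValidationError("non-finite input to gaussian_kernel")
    if not epsilon > 0:
        raise ValidationError(f"epsilon must be positive, got {epsilon}")
    d2 = float(np.sum((xk - xl) ** 2))
    return float(np.exp(-d2 / (2.0 * epsilon**2)))


def _gaussian_kernel_matrix(x: np.ndarray, epsilon: float) -> np.ndarray:
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    return np.exp(-d2 / (2.0 * epsilon**2))


def density_estimate(
    dataset: WeightedDataset,
    subset: Iterable[int] | None = None,
    epsilon: float | None = None,
) -> np.ndarray:
    """Kernel density estimate ``rho_k = sum_l g_eps(x_k, x_l)`` (self-term in)."""
    idx = dataset.resolve_subset(subset)
    if epsilon is None:
        epsilon = estimate_scale(dataset, idx)
    if not epsilon > 0:
        raise ValidationError(f"epsilon must be positive, got {epsilon}")
    g = _gaussian_kernel_matrix(dataset.samples[:, idx], epsilon)
    return g.sum(axis=1)


def reweighting_factor(wk: float, wl: float) -> float:
    """Diffusion-reweighting factor ``r(x_k, x_l) = w_k w_l``.

    Symmetric in the two statistical weights; equals 1 for unbiased data.
    A common factor applied to both weights rescales ``r`` globally (after
    combining with the reweighted density normalisation), which cancels in
    the row normalisation of the transition matrix.
    """
    if not (wk > 0 and wl > 0) or not (np.isfinite(wk) and np.isfinite(wl)):
        raise ValidationError(
            f"statistical weights must be positive finite, got ({wk}, {wl})"
        )
    return float(wk * wl)


def reweighted_kernel(
    dataset: WeightedDataset,
    subset: Iterable[int] | None = None,
    epsilon: float | None = None,
) -> KernelMatrix:
    """Reweighted anisotropic kernel on a variable subspace.

    ``K_kl = w_k w_l g_eps(x_k, x_l) / sqrt(rho_k rho_l)`` with the
    reweighted density estimate ``rho_k = sum_l w_l g_eps(x_k, x_l)``.  When
    all weights are one this is the standard anisotropic diffusion-map
    kernel.
    """
    idx = dataset.resolve_subset(subset)
    if epsilon is None:
        epsilon = estimate_scale(dataset, idx)
    if not epsilon > 0:
        raise ValidationError(f"epsilon must be positive, got {epsilon}")
    g = _gaussian_kernel_matrix(dataset.samples[:, idx], epsilon)
    rho = g @ dataset.weights
    scale = dataset.weights / np.sqrt(rho)
    values = g * np.outer(scale, scale)
    return KernelMatrix(values=values, epsilon=float(epsilon), density=rho)


def transition_matrix(kernel: KernelMatrix) -> TransitionMatrix:
    """Row-normalise a kernel into a Markov transition matrix.

    Because the kernel is symmetric the chain is reversible with stationary
    density proportional to the kernel row sums.
    """
    row_sums = kernel.values.sum(axis=1)
    if np.any(row_sums <= 0) or not np.all(np.isfinite(row_sums)):
        bad = int(np.argmin(row_sums))
        raise ValidationError(
            f"kernel row {bad} has non-positive or non-finite sum "
            f"{row_sums[bad]}; cannot normalise"
        )
    values = kernel.values / row_sums[:, None]
    return TransitionMatrix(values=values, source=kernel)
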