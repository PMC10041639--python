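"""Synthetic benchmark generators with machine-readable ground truth.

Two families are provided:

* ``generate_hypercube`` -- clusters of isotropic Gaussians placed on
  vertices of an ``m``-dimensional hypercube, embedded among ``n - m``
  redundant columns that are random linear combinations of the informative
  coordinates plus noise.  The intrinsic (kinetically relevant) dimension is
  ``m`` by construction: the default ``m + 1`` cluster centers are the base
  vertex ``(-sep, ..., -sep)`` together with the ``m`` single-coordinate
  flips, so removing any informative coordinate merges exactly one cluster
  pair and destroys one slow eigenvalue.  The base cluster holds the
  majority of the samples (a dominant metastable state), which keeps the
  median-distance kernel bandwidth at the intra-cluster scale, and the
  redundant columns are scaled-down combinations with small additive noise
  so their contribution to pairwise distances is essentially proportional to
  the informative one (and hence cancels through the per-subspace bandwidth)
  -- see docs/methods.md for the full design rationale.  Column order is
  shuffled; the informative positions, cluster labels and mixing
  coefficients are returned as ground truth for recovery scoring.

* ``generate_biased_double_well`` -- Metropolis Monte Carlo samples of a 2-D
  double-well Boltzmann density, optionally tilted by a static Gaussian bias
  that fills the barrier region (an enhanced-sampling caricature).  The
  statistical weights ``w = p/q`` proportional to ``exp(beta V_bias)`` are
  returned alongside an unbiased reference sample of the same size, so the
  reweighting path can be tested against known ground truth.

All randomness flows through a single integer seed; identical parameters and
seed give bitwise-identical data sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import WeightedDataset
from .errors import ValidationError

__all__ = [
    "BenchmarkSpec",
    "HypercubeGroundTruth",
    "generate_hypercube",
    "generate_biased_double_well",
]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of the hypercube cluster generator.

    ``n_total`` configuration variables of which ``m_informative`` carry the
    cluster structure; ``n_clusters`` defaults to ``m + 1`` (a spanning set
    of vertices, see module docstring) and may not exceed ``2**m``.
    ``cluster_sep`` is the vertex half-spacing, ``cluster_sd`` the isotropic
    within-cluster standard deviation, ``base_weight`` the population of the
    dominant (base-vertex) cluster, ``redundant_scale`` the Euclidean norm of
    each redundant column's mixing-coefficient vector and ``noise_sd`` the
    additive noise on the redundant columns.
    """

    m_informative: int
    n_total: int = 10
    n_samples: int = 2500
    n_clusters: int | None = None
    cluster_sep: float = 1.0
    cluster_sd: float = 0.15
    base_weight: float = 0.75
    redundant_scale: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        m, n = self.m_informative, self.n_total
        if not 1 <= m <= n:
            raise ValidationError(f"need 1 <= m_informative <= n_total, got {m}, {n}")
        if self.n_samples < 3:
            raise ValidationError("need at least 3 samples")
        if self.n_clusters is None:
            object.__setattr__(self, "n_clusters", min(m + 1, 2**m))
        if not 1 <= self.n_clusters <= 2**m:
            raise ValidationError(
                f"n_clusters must be in [1, 2^m = {2**m}], got {self.n_clusters}"
            )
        if self.cluster_sep <= 0 or self.cluster_sd <= 0 or self.noise_sd < 0:
            raise ValidationError("cluster_sep, cluster_sd must be > 0; noise_sd >= 0")
        if not 0 < self.base_weight < 1:
            raise ValidationError("base_weight must be in (0, 1)")
        if self.redundant_scale <= 0:
            raise ValidationError("redundant_scale must be > 0")


@dataclass(frozen=True)
class HypercubeGroundTruth:
    """Provenance record of a generated hypercube data set."""

    informative_indices: tuple[int, ...]  # column positions after shuffling
    labels: np.ndarray  # cluster label per sample
    centers: np.ndarray  # (n_clusters, m) vertex coordinates
    coefficients: np.ndarray  # (n_total - m, m) redundant-column mixing matrix
    permutation: np.ndarray  # column i of the data set is original column perm[i]


def _spanning_vertices(m: int, n_clusters: int, sep: float, rng) -> np.ndarray:
    """Cluster centers on hypercube vertices, spanning all m dimensions.

    The first ``m + 1`` centers are the base vertex (all ``-sep``) and its
    single-coordinate flips; further centers (if requested) are distinct
    random vertices.
    """
    base = -np.ones(m)
    centers = [base.copy()]
    for i in range(m):
        v = base.copy()
        v[i] = 1.0
        centers.append(v)
    centers = np.asarray(centers[:n_clusters])
    if n_clusters > m + 1:
        seen = {tuple(v) for v in centers}
        extra = []
        while len(extra) < n_clusters - (m + 1):
            v = rng.choice([-1.0, 1.0], size=m)
            if tuple(v) not in seen:
                seen.add(tuple(v))
                extra.append(v)
        centers = np.vstack([centers, extra])
    return centers * sep


def generate_hypercube(
    spec: BenchmarkSpec,
) -> tuple[WeightedDataset, HypercubeGroundTruth]:
    """Generate a unit-weight hypercube cluster data set with ground truth."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.m_informative, spec.n_total
    centers = _spanning_vertices(m, spec.n_clusters, spec.cluster_sep, rng)
    # dominant base cluster, remaining population shared by the other vertices
    probs = np.full(spec.n_clusters, (1.0 - spec.base_weight) / max(spec.n_clusters - 1, 1))
    probs[0] = spec.base_weight if spec.n_clusters > 1 else 1.0
    labels = rng.choice(spec.n_clusters, size=spec.n_samples, p=probs)
    informative = centers[labels] + rng.normal(
        0.0, spec.cluster_sd, size=(spec.n_samples, m)
    )
    n_redundant = n - m
    coefficients = rng.normal(size=(n_redundant, m))
    if n_redundant:
        coefficients *= spec.redundant_scale / np.linalg.norm(
            coefficients, axis=1, keepdims=True
        )
        redundant = informative @ coefficients.T + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_samples, n_redundant)
        )
        columns = np.hstack([informative, redundant])
    else:
        columns = informative
    permutation = rng.permutation(n)
    samples = columns[:, permutation]
    informative_indices = tuple(
        int(i) for i in range(n) if permutation[i] < m
    )
    dataset = WeightedDataset(samples)
    truth = HypercubeGroundTruth(
        informative_indices=informative_indices,
        labels=labels,
        centers=centers,
        coefficients=coefficients,
        permutation=permutation,
    )
    return dataset, truth


# -- biased double well -------------------------------------------------------


def _double_well_potential(x: float, y: float) -> float:
    """Tilted double well: U = 4 (x^2 - 1)^2 + 0.55 x + 3 y^2.

    Wells near x = +-1 separated by a ~4 kT barrier; the tilt makes the left
    well dominant (~70/30 population split), so the median pairwise distance
    stays at the intra-well scale and both well populations must be
    recovered by the reweighting.
    """
    return 4.0 * (x * x - 1.0) ** 2 + 0.55 * x + 3.0 * y * y


def _metropolis_2d(
    potential: Callable[[float, float], float],
    n_samples: int,
    beta: float,
    rng,
    step_sd: float = 0.5,
    burn_in: int = 2000,
    thin: int = 40,
) -> np.ndarray:
    x, y = -1.0, 0.0
    u = potential(x, y)
    total = burn_in + n_samples * thin
    steps = rng.normal(0.0, step_sd, size=(total, 2))
    accept = rng.random(total)
    out = np.empty((n_samples, 2))
    k = 0
    for t in range(total):
        xp, yp = x + steps[t, 0], y + steps[t, 1]
        up = potential(xp, yp)
        if up <= u or accept[t] < np.exp(-beta * (up - u)):
            x, y, u = xp, yp, up
        if t >= burn_in and (t - burn_in) % thin == thin - 1:
            out[k] = (x, y)
            k += 1
    return out


def generate_biased_double_well(
    n_samples: int = 2500,
    beta: float = 1.0,
    bias_strength: float = 3.0,
    n_noise_dims: int = 0,
    seed: int = 0,
    noise_sd: float = 0.5,
) -> tuple[WeightedDataset, WeightedDataset]:
    """Biased double-well samples with importance weights, plus unbiased reference.

    The biased chain samples ``q ∝ exp(-beta (U + V_b))`` with the static bias
    ``V_b(x) = -bias_strength * exp(-x^2 / 2)`` that lowers the barrier at
    ``x = 0``.  The bias is spatially smooth (unit width, comparable to the
    kernel bandwidth) so the importance weights vary on a scale the kernel
    can resolve.  The statistical weights ``w = p/q ∝ exp(beta V_b)`` are
    normalised to mean one.  ``bias_strength = 0`` gives unit weights.

    Returns ``(biased, unbiased)`` data sets of the same size, each with
    ``2 + n_noise_dims`` columns (``x``, ``y`` and pure-noise padding).
    """
    if bias_strength < 0:
        raise ValidationError(f"bias_strength must be >= 0, got {bias_strength}")
    if beta <= 0:
        raise ValidationError(f"beta must be positive, got {beta}")
    if n_noise_dims < 0:
        raise ValidationError("n_noise_dims must be >= 0")
    rng = np.random.default_rng(seed)

    def bias(x: float) -> float:
        return -bias_strength * np.exp(-x * x / 2.0)

    def biased_potential(x: float, y: float) -> float:
        return _double_well_potential(x, y) + bias(x)

    xy_biased = _metropolis_2d(biased_potential, n_samples, beta, rng)
    xy_unbiased = _metropolis_2d(_double_well_potential, n_samples, beta, rng)

    log_w = beta * np.array([bias(x) for x in xy_biased[:, 0]])
    log_w -= log_w.max()
    weights = np.exp(log_w)
    weights /= weights.mean()

    names = ["x", "y"] + [f"noise{i}" for i in range(n_noise_dims)]
    if n_noise_dims:
        pad_b = rng.normal(0.0, noise_sd, size=(n_samples, n_noise_dims))
        pad_u = rng.normal(0.0, noise_sd, size=(n_samples, n_noise_dims))
        xy_biased = np.hstack([xy_biased, pad_b])
        xy_unbiased = np.hstack([xy_unbiased, pad_u])

    biased = WeightedDataset(xy_biased, weights, names)
    unbiased = WeightedDataset(xy_unbiased, None, names)
    return biased, unbiased
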