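"""Spectral decomposition of transition matrices and the spectral loss.

The Markov transition matrix ``M = D^{-1} K`` (``K`` symmetric kernel,
``D = diag(K 1)``) is similar to the symmetric matrix
``A = D^{-1/2} K D^{-1/2}``, so its spectrum is real and lies in ``[-1, 1]``
with ``lambda_0 = 1``.  Eigenvalues are sorted by decreasing value; the right
eigenfunctions ``psi_k`` of ``M`` are recovered from the eigenvectors ``v_k``
of ``A`` as ``psi_k = D^{-1/2} v_k`` and the stationary (equilibrium) density
-- the left zeroth eigenfunction -- is the normalised vector of kernel row
sums, exact by symmetry of ``K``.

Kinetic similarity between a partial representation (a subset of ``d``
configuration variables) and the complete one is measured by the spectral
loss: the alpha-normalised sum of absolute differences between the leading
``K`` sorted eigenvalues of the two transition matrices.  The normalisation
constant alpha is fixed a posteriori so the loss of the best single-variable
representation equals one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.linalg

from .errors import EigenSolverError, ValidationError
from .markov import TransitionMatrix

__all__ = [
    "SpectralDecomposition",
    "SpectralLossConfig",
    "decompose",
    "transition_spectrum",
    "spectral_loss",
    "normalize_trace",
    "equilibrium_density",
    "compare_eigenfunctions",
]


@dataclass(frozen=True)
class SpectralDecomposition:
    """Leading spectrum of a Markov transition matrix.

    ``eigenvalues`` are sorted decreasing (``lambda_0 = 1``);
    ``right_eigenfunctions`` holds ``psi_k`` column-wise (unit 2-norm, sign
    fixed so the largest-magnitude entry is positive); ``stationary_density``
    is the left zeroth eigenfunction normalised to sum to one.
    """

    eigenvalues: np.ndarray
    right_eigenfunctions: np.ndarray
    stationary_density: np.ndarray


@dataclass(frozen=True)
class SpectralLossConfig:
    """Configuration of the spectral loss.

    ``num_eigenvalues`` is the number ``K`` of leading eigenvalues entering
    the loss sum (capped at ``N`` when a matrix is smaller); ``alpha`` is the
    normalisation constant, conventionally set post hoc so that the loss of
    the best one-variable representation equals one.
    """

    num_eigenvalues: int = 10
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.num_eigenvalues < 2:
            raise ValidationError(
                f"need at least 2 eigenvalues in the loss, got {self.num_eigenvalues}"
            )
        if not self.alpha > 0:
            raise ValidationError(f"alpha must be positive, got {self.alpha}")


def _symmetric_conjugate(m: TransitionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, row_sums) with A = D^-1/2 K D^-1/2 symmetric, D = diag(row sums)."""
    kernel = m.source.values
    row_sums = kernel.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(row_sums)
    a = kernel * np.outer(inv_sqrt, inv_sqrt)
    return a, row_sums


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    # sign convention: largest-magnitude entry of each eigenvector is positive
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def decompose(m: TransitionMatrix, num_eigenvalues: int = 10) -> SpectralDecomposition:
    """Eigendecompose ``M psi = lambda psi``, keeping the top eigenpairs.

    Solves the symmetric conjugated problem so the spectrum is exactly real,
    then maps eigenvectors back to right eigenfunctions of ``M``.
    """
    n = m.n_states
    k = int(num_eigenvalues)
    if not 2 <= k <= n:
        raise ValidationError(f"num_eigenvalues must be in [2, {n}], got {k}")
    a, row_sums = _symmetric_conjugate(m)
    try:
        vals, vecs = scipy.linalg.eigh(a, subset_by_index=[n - k, n - 1])
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - LAPACK failure
        raise EigenSolverError(f"symmetric eigensolver failed: {exc}") from exc
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    psi = vecs / np.sqrt(row_sums)[:, None]
    psi /= np.linalg.norm(psi, axis=0)
    psi = _fix_signs(psi)
    pi = row_sums / row_sums.sum()
    return SpectralDecomposition(
        eigenvalues=vals, right_eigenfunctions=psi, stationary_density=pi
    )


def transition_spectrum(m: TransitionMatrix, num_eigenvalues: int = 10) -> np.ndarray:
    """Top eigenvalues only (decreasing), via the symmetric conjugation."""
    n = m.n_states
    k = int(num_eigenvalues)
    if not 2 <= k <= n:
        raise ValidationError(f"num_eigenvalues must be in [2, {n}], got {k}")
    a, _ = _symmetric_conjugate(m)
    try:
        vals = scipy.linalg.eigh(
            a, eigvals_only=True, subset_by_index=[n - k, n - 1]
        )
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise EigenSolverError(f"symmetric eigensolver failed: {exc}") from exc
    return vals[::-1]


def spectral_loss(
    reference: np.ndarray,
    partial: np.ndarray,
    config: SpectralLossConfig | None = None,
) -> float:
    """Spectral loss between two sorted eigenvalue spectra.

    ``sigma = alpha * sum_{k=0}^{K-1} |lambda_k - lambda_dk|``; zero exactly
    when the leading spectra agree.  Both inputs must be sorted decreasing
    and provide at least ``K`` eigenvalues.
    """
    if config is None:
        config = SpectralLossConfig()
    ref = np.asarray(reference, dtype=np.float64)
    par = np.asarray(partial, dtype=np.float64)
    k = config.num_eigenvalues
    if ref.size < k or par.size < k:
        raise ValidationError(
            f"need at least {k} eigenvalues in both spectra, "
            f"got {ref.size} and {par.size}"
        )
    for name, v in (("reference", ref[:k]), ("partial", par[:k])):
        if np.any(np.diff(v) > 1e-10):
            raise ValidationError(f"{name} spectrum is not sorted decreasing")
    return float(config.alpha * np.abs(ref[:k] - par[:k]).sum())


def normalize_trace(trace: Mapping[int, float]) -> dict[int, float]:
    """Divide every loss by the one-variable loss so sigma(d=1) == 1."""
    if 1 not in trace:
        raise ValidationError("trace has no entry for d = 1; cannot normalise")
    sigma1 = trace[1]
    if not sigma1 > 0:
        raise ValidationError(
            f"loss at d = 1 must be positive for normalisation, got {sigma1}"
        )
    return {d: v / sigma1 for d, v in trace.items()}


def equilibrium_density(decomposition: SpectralDecomposition) -> np.ndarray:
    """Stationary probability vector (left zeroth eigenfunction of ``M``)."""
    pi = decomposition.stationary_density
    if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValidationError("stationary density is not a probability vector")
    return pi


def compare_eigenfunctions(psi_a: np.ndarray, psi_b: np.ndarray) -> float:
    """Sign-invariant similarity of two eigenfunctions in ``[0, 1]``.

    Absolute Pearson correlation: eigenvector sign (and scale) is arbitrary,
    so 1 means identical up to an affine sign/scale change.
    """
    a = np.asarray(psi_a, dtype=np.float64).ravel()
    b = np.asarray(psi_b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("eigenfunction comparison requires nonconstant vectors")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(abs(r), 1.0))
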