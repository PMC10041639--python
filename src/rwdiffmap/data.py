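"""Weighted data sets of configuration variables.

A simulation trajectory is summarised as an ``N x n`` matrix of configuration
variables (features) -- interatomic distances, dihedral sines/cosines, or any
other per-frame descriptors.  When the trajectory comes from an
enhanced-sampling run the frames are drawn from a biased distribution ``q``
rather than the equilibrium distribution ``p``; each sample then carries a
statistical weight ``w_k = p(x_k) / q(x_k)``.  Unit weights mark equilibrium
(unbiased) data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["WeightedDataset"]


def _as_names(names: Sequence[str] | None, n: int) -> tuple[str, ...]:
    if names is None:
        width = max(2, len(str(n - 1)))
        return tuple(f"x{i:0{width}d}" for i in range(n))
    names = tuple(str(s) for s in names)
    if len(names) != n:
        raise ValidationError(
            f"expected {n} variable names, got {len(names)}"
        )
    if len(set(names)) != n:
        raise ValidationError("variable names must be unique")
    return names


@dataclass(frozen=True)
class WeightedDataset:
    """Samples of configuration variables with per-sample statistical weights.

    Parameters
    ----------
    samples
        ``(N, n)`` matrix of configuration variables.  Entries must be finite.
    weights
        Length-``N`` vector of strictly positive statistical weights
        (``p/q`` ratios).  ``None`` means unit weights (unbiased data).
    names
        Optional ``n`` unique variable labels; auto-generated if omitted.
    """

    samples: np.ndarray
    weights: np.ndarray | None = None
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 2:
            raise ValidationError(
                f"samples must be a 2-D matrix, got ndim={samples.ndim}"
            )
        n_samples, n_variables = samples.shape
        if n_samples < 3:
            raise ValidationError(f"need at least 3 samples, got {n_samples}")
        if n_variables < 1:
            raise ValidationError("need at least one variable")
        if not np.all(np.isfinite(samples)):
            bad = np.argwhere(~np.isfinite(samples))[0]
            raise ValidationError(
                f"non-finite sample entry at row {bad[0]}, column {bad[1]}"
            )

        if self.weights is None:
            weights = np.ones(n_samples, dtype=np.float64)
        else:
            weights = np.asarray(self.weights, dtype=np.float64)
            if weights.shape != (n_samples,):
                raise ValidationError(
                    f"weights must have shape ({n_samples},), got {weights.shape}"
                )
            if not np.all(np.isfinite(weights)) or np.any(weights <= 0):
                raise ValidationError(
                    "statistical weights must be strictly positive and finite"
                )

        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "names", _as_names(self.names or None, n_variables))

    # -- basic shape accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_variables(self) -> int:
        return self.samples.shape[1]

    @property
    def is_unbiased(self) -> bool:
        """True when all weights equal one (equilibrium sampling)."""
        return bool(np.all(self.weights == 1.0))

    # -- subsetting ------------------------------------------------------------

    def resolve_subset(self, subset: Iterable[int] | None) -> tuple[int, ...]:
        """Validate and canonicalise a variable-index subset (sorted tuple)."""
        if subset is None:
            return tuple(range(self.n_variables))
        idx = tuple(sorted(int(i) for i in subset))
        if len(idx) == 0:
            raise ValidationError("variable subset must be nonempty")
        if len(set(idx)) != len(idx):
            raise ValidationError(f"duplicate variable indices in subset {idx}")
        if idx[0] < 0 or idx[-1] >= self.n_variables:
            raise ValidationError(
                f"subset {idx} out of range for {self.n_variables} variables"
            )
        return idx

    def subset_matrix(self, subset: Iterable[int] | None = None) -> np.ndarray:
        """Column view of the sample matrix restricted to ``subset``."""
        idx = self.resolve_subset(subset)
        return self.samples[:, idx]

    def subset_names(self, subset: Iterable[int] | None = None) -> tuple[str, ...]:
        idx = self.resolve_subset(subset)
        return tuple(self.names[i] for i in idx)

    def with_weights(self, weights: np.ndarray | None) -> "WeightedDataset":
        """Copy of this data set with different statistical weights."""
        return WeightedDataset(self.samples, weights, self.names)
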