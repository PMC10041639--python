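"""Greedy backward floating search over variable subsets.

The search starts from the complete ``n``-variable representation and
repeatedly removes the variable whose removal yields the minimal spectral
loss against the reference spectrum of the complete representation.  After
each removal, previously discarded variables are conditionally re-added
("floating" re-inclusion): while some excluded variable, added back, gives a
strictly better subset of that size than any seen before, the best such
variable is re-added.  The search is suboptimal by design -- it avoids the
combinatorial explosion of an exhaustive scan -- and deterministic: ties are
broken towards the lowest variable index and subset evaluations are memoised.

The search always continues down to a single variable so that the loss of the
best one-variable subset is available as the normalisation constant alpha
(normalised loss at ``d = 1`` equals one; at ``d = n`` it is zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .data import WeightedDataset
from .errors import ValidationError
from .markov import estimate_scale, reweighted_kernel, transition_matrix
from .spectral import SpectralLossConfig, normalize_trace, spectral_loss, transition_spectrum

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "evaluate_subset",
    "select_variables",
    "plateau_dimension",
]

_STRICT_REL_TOL = 1e-12  # re-addition must improve by more than this (relative)


@dataclass(frozen=True)
class SelectionStep:
    """One action of the floating search."""

    d: int
    retained: tuple[int, ...]
    sigma_raw: float
    action: str  # "start" | "removed" | "re-added"
    variable: int | None = None  # the variable removed or re-added


@dataclass
class SelectionTrace:
    """Full record of a selection run.

    ``steps`` is the chronological walk of the search; ``best_by_size`` maps
    each subset size ``d`` to the best (lowest-raw-loss) subset encountered.
    Losses are reported both raw (the Eq-style eigenvalue discrepancy) and
    normalised so that the ``d = 1`` value equals one.
    """

    steps: list[SelectionStep]
    best_by_size: dict[int, tuple[float, tuple[int, ...]]]
    reference_eigenvalues: np.ndarray
    config: SpectralLossConfig
    names: tuple[str, ...]
    d_target: int
    epsilons: dict[tuple[int, ...], float] = field(default_factory=dict)

    @property
    def n_variables(self) -> int:
        return len(self.names)

    def losses_by_d(self) -> dict[int, float]:
        """Best raw loss per subset size."""
        return {d: loss for d, (loss, _) in sorted(self.best_by_size.items())}

    def normalized_losses_by_d(self) -> dict[int, float]:
        """Best loss per size, divided by the d = 1 loss (sigma_1 == 1)."""
        return normalize_trace(self.losses_by_d())

    def selected(self, d: int | None = None) -> tuple[int, ...]:
        """Best subset of size ``d`` (default: the requested target size)."""
        d = self.d_target if d is None else d
        if d not in self.best_by_size:
            raise ValidationError(f"no subset of size {d} in the trace")
        return self.best_by_size[d][1]

    def selected_names(self, d: int | None = None) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.selected(d))

    def to_dict(self) -> dict:
        from . import __version__

        raw = self.losses_by_d()
        norm = self.normalized_losses_by_d()
        return {
            "version": __version__,
            "d_target": self.d_target,
            "names": list(self.names),
            "config": {
                "num_eigenvalues": self.config.num_eigenvalues,
                "alpha": 1.0 / raw[1],
            },
            "reference_eigenvalues": [float(v) for v in self.reference_eigenvalues],
            "losses": [
                {
                    "d": d,
                    "retained": list(self.best_by_size[d][1]),
                    "retained_names": [self.names[i] for i in self.best_by_size[d][1]],
                    "sigma_raw": raw[d],
                    "sigma": norm[d],
                }
                for d in sorted(raw)
            ],
            "steps": [
                {
                    "d": s.d,
                    "action": s.action,
                    "variable": None if s.variable is None else self.names[s.variable],
                    "retained_names": [self.names[i] for i in s.retained],
                    "sigma_raw": s.sigma_raw,
                }
                for s in self.steps
            ],
            "epsilons": {
                ",".join(self.names[i] for i in k): v for k, v in self.epsilons.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def evaluate_subset(
    dataset: WeightedDataset,
    subset: Iterable[int],
    reference: np.ndarray,
    config: SpectralLossConfig | None = None,
    *,
    _cache: dict | None = None,
    _epsilons: dict | None = None,
) -> float:
    """Raw spectral loss of a variable subspace against a reference spectrum.

    Rebuilds the scale constant, reweighted kernel and transition matrix
    inside the subspace, takes the leading eigenvalues and returns the raw
    eigenvalue discrepancy.  Deterministic; optionally memoised via
    ``_cache`` keyed by the canonical subset.
    """
    if config is None:
        config = SpectralLossConfig()
    idx = dataset.resolve_subset(subset)
    if _cache is not None and idx in _cache:
        return _cache[idx]
    k = min(config.num_eigenvalues, dataset.n_samples)
    eps = estimate_scale(dataset, idx)
    m = transition_matrix(reweighted_kernel(dataset, idx, eps))
    spectrum = transition_spectrum(m, k)
    loss = spectral_loss(reference, spectrum, SpectralLossConfig(k, config.alpha))
    if _cache is not None:
        _cache[idx] = loss
    if _epsilons is not None:
        _epsilons[idx] = eps
    return loss


def reference_spectrum(
    dataset: WeightedDataset, config: SpectralLossConfig | None = None
) -> np.ndarray:
    """Leading eigenvalues of the complete high-dimensional representation."""
    if config is None:
        config = SpectralLossConfig()
    k = min(config.num_eigenvalues, dataset.n_samples)
    m = transition_matrix(reweighted_kernel(dataset))
    return transition_spectrum(m, k)


def select_variables(
    dataset: WeightedDataset,
    d_target: int = 1,
    config: SpectralLossConfig | None = None,
) -> SelectionTrace:
    """Sequential backward floating selection minimising the spectral loss.

    Parameters
    ----------
    dataset
        Weighted data set of ``n >= 2`` configuration variables.
    d_target
        Requested size of the partial representation, ``1 <= d_target < n``.
        The search itself always continues to ``d = 1`` so the normalisation
        constant (one-variable loss) is computed within the same run.
    config
        Spectral-loss configuration (number of eigenvalues ``K``).
    """
    if config is None:
        config = SpectralLossConfig()
    n = dataset.n_variables
    if n < 2:
        raise ValidationError("selection needs at least 2 variables")
    if not 1 <= d_target < n:
        raise ValidationError(f"d_target must be in [1, {n - 1}], got {d_target}")

    cache: dict[tuple[int, ...], float] = {}
    epsilons: dict[tuple[int, ...], float] = {}
    reference = reference_spectrum(dataset, config)

    def ev(idx: tuple[int, ...]) -> float:
        return evaluate_subset(
            dataset, idx, reference, config, _cache=cache, _epsilons=epsilons
        )

    full = tuple(range(n))
    current = full
    current_loss = ev(full)  # exactly 0: same spectrum subtracted from itself
    best: dict[int, tuple[float, tuple[int, ...]]] = {n: (current_loss, full)}
    steps = [SelectionStep(n, full, current_loss, "start")]
    max_evaluations = 10 * n * n
    floating_enabled = True

    def record_best(idx: tuple[int, ...], loss: float) -> None:
        d = len(idx)
        if d not in best or loss < best[d][0]:
            best[d] = (loss, idx)

    while len(current) > 1:
        # (a) remove the variable whose removal gives the minimal loss
        candidates = []
        for v in current:
            idx = tuple(i for i in current if i != v)
            candidates.append((ev(idx), v, idx))
        loss, removed, current = min(candidates, key=lambda t: (t[0], t[1]))
        current_loss = loss
        record_best(current, loss)
        steps.append(SelectionStep(len(current), current, loss, "removed", removed))

        if len(cache) > max_evaluations:
            floating_enabled = False  # guard pathological alternation

        # (b)/(c) re-add excluded variables while a strictly better subset of
        # the enlarged size than any previously recorded one results
        while floating_enabled and len(current) < n - 1:
            excluded = [v for v in full if v not in current]
            add_candidates = []
            for v in excluded:
                idx = tuple(sorted(current + (v,)))
                add_candidates.append((ev(idx), v, idx))
            add_loss, added, enlarged = min(add_candidates, key=lambda t: (t[0], t[1]))
            prev_best = best[len(enlarged)][0]
            if add_loss < prev_best * (1 - _STRICT_REL_TOL) - _STRICT_REL_TOL:
                current = enlarged
                current_loss = add_loss
                record_best(enlarged, add_loss)
                steps.append(
                    SelectionStep(len(current), current, add_loss, "re-added", added)
                )
            else:
                break

    return SelectionTrace(
        steps=steps,
        best_by_size=best,
        reference_eigenvalues=reference,
        config=config,
        names=dataset.names,
        d_target=d_target,
        epsilons=epsilons,
    )


def plateau_dimension(
    trace: SelectionTrace | Mapping[int, float],
    tolerance: float = 0.05,
) -> int:
    """Smallest ``d`` from which the normalised loss stays below tolerance.

    The plateau is required to be contiguous: ``sigma_d' <= tolerance`` for
    every ``d' >= d``.  For the usual monotonically decreasing traces this is
    the first sub-threshold ``d``.  If no ``d`` qualifies the full dimension
    ``n`` is returned and a ``RuntimeWarning`` is emitted.
    """
    if isinstance(trace, SelectionTrace):
        losses = trace.normalized_losses_by_d()
    else:
        losses = normalize_trace(dict(trace))
    ds = sorted(losses)
    if ds != list(range(ds[0], ds[-1] + 1)):
        raise ValidationError(f"trace does not cover a contiguous range of d: {ds}")
    plateau = None
    for d in reversed(ds):
        if losses[d] <= tolerance:
            plateau = d
        else:
            break
    if plateau is None:
        import warnings

        warnings.warn(
            f"no subset size reaches normalised loss <= {tolerance}; "
            "returning the full dimension",
            RuntimeWarning,
            stacklevel=2,
        )
        return ds[-1]
    return plateau
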