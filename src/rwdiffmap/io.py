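"""Reading and writing feature tables, weights helpers and result files.

Supported table formats: delimited text (CSV/TSV with a header row) and
PLUMED COLVAR-style whitespace tables whose first line is
``#! FIELDS name1 name2 ...``.  A designated column may supply statistical
weights directly, or a bias-energy column together with ``kT`` may be
converted through :func:`weights_from_static_bias`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import WeightedDataset
from .errors import ValidationError
from .spectral import SpectralDecomposition

__all__ = [
    "read_feature_table",
    "write_dataset",
    "weights_from_static_bias",
    "write_trace",
    "write_decomposition",
]


def _read_colvar(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#! FIELDS"):
            raise ValidationError(
                f"{path}: line 1: COLVAR files must start with '#! FIELDS name1 ...'"
            )
        names = first.split()[2:]
        if not names:
            raise ValidationError(f"{path}: line 1: no field names in FIELDS header")
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                # '#! SET ...' and other comment lines are ignored
                continue
            tokens = stripped.split()
            if len(tokens) != len(names):
                raise ValidationError(
                    f"{path}: line {lineno}: expected {len(names)} columns, "
                    f"got {len(tokens)}"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=names)


def _read_delimited(path: Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValidationError(f"{path}: non-numeric columns {bad}")
    na_rows = df.index[df.isna().any(axis=1)]
    if len(na_rows):
        # +2: header line and 1-based numbering
        raise ValidationError(
            f"{path}: line {na_rows[0] + 2}: missing or unparsable value"
        )
    return df


def read_feature_table(
    path: str | Path,
    format: str = "csv",
    weight_column: str | None = None,
    bias_column: str | None = None,
    kt: float | None = None,
    exclude: Sequence[str] = (),
) -> WeightedDataset:
    """Load a feature table into a :class:`WeightedDataset`.

    Exactly one of ``weight_column`` (ready-made statistical weights) and
    ``bias_column`` (static bias energies, converted with ``kT``) may be
    given.  Columns named in ``exclude`` (e.g. ``time``) are dropped; no
    column is ever excluded heuristically.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    if weight_column is not None and bias_column is not None:
        raise ValidationError("give at most one of weight_column / bias_column")
    if bias_column is not None and kt is None:
        raise ValidationError("kT is required with a bias column")

    if format == "colvar":
        df = _read_colvar(path)
    elif format in ("csv", "tsv"):
        df = _read_delimited(path, "," if format == "csv" else "\t")
    else:
        raise ValidationError(f"unknown format {format!r} (csv, tsv or colvar)")

    weights = None
    if weight_column is not None:
        if weight_column not in df.columns:
            raise ValidationError(f"weight column {weight_column!r} not in {path}")
        weights = df.pop(weight_column).to_numpy(dtype=np.float64)
        if np.any(weights <= 0):
            bad = int(np.argmax(weights <= 0))
            raise ValidationError(
                f"{path}: line {bad + 2}: nonpositive weight {weights[bad]}"
            )
    elif bias_column is not None:
        if bias_column not in df.columns:
            raise ValidationError(f"bias column {bias_column!r} not in {path}")
        weights = weights_from_static_bias(
            df.pop(bias_column).to_numpy(dtype=np.float64), kt
        )

    for name in exclude:
        if name in df.columns:
            df = df.drop(columns=[name])
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no feature columns left after exclusions")
    return WeightedDataset(
        df.to_numpy(dtype=np.float64), weights, tuple(df.columns)
    )


def write_dataset(
    dataset: WeightedDataset,
    path: str | Path,
    include_weights: bool | None = None,
) -> None:
    """Write a data set as CSV (weights in a ``weight`` column when present)."""
    df = pd.DataFrame(dataset.samples, columns=list(dataset.names))
    if include_weights is None:
        include_weights = not dataset.is_unbiased
    if include_weights:
        df["weight"] = dataset.weights
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def weights_from_static_bias(bias_values: np.ndarray, kt: float) -> np.ndarray:
    """Statistical weights ``w ∝ exp(V / kT)`` from a static bias potential.

    The maximum is subtracted before exponentiation (overflow-safe; the
    resulting global factor is irrelevant to the transition matrix) and the
    weights are normalised to mean one.
    """
    if not kt > 0:
        raise ValidationError(f"kT must be positive, got {kt}")
    v = np.asarray(bias_values, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite bias energies")
    w = np.exp((v - v.max()) / kt)
    return w / w.mean()


def write_trace(trace, path: str | Path, extra: dict | None = None) -> None:
    """Serialise a :class:`~rwdiffmap.selection.SelectionTrace` to JSON."""
    payload = trace.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_decomposition(
    decomposition: SpectralDecomposition,
    eigenvalues_path: str | Path,
    eigenfunctions_path: str | Path | None = None,
) -> None:
    """Write eigenvalues (one per line) and eigenfunctions (one row per sample)."""
    np.savetxt(eigenvalues_path, decomposition.eigenvalues)
    if eigenfunctions_path is not None:
        k = decomposition.right_eigenfunctions.shape[1]
        header = ",".join([f"psi{i}" for i in range(k)] + ["stationary_density"])
        table = np.column_stack(
            [decomposition.right_eigenfunctions, decomposition.stationary_density]
        )
        np.savetxt(
            eigenfunctions_path, table, delimiter=",", header=header, comments=""
        )
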