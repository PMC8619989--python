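"""Discrete sample tables and sparse contingency counting.

A :class:`DiscreteDataset` holds an integer-coded sample matrix (rows are
observations, columns are categorical features) together with per-feature
arities.  It is the single ground-truth source of sample counts: every
counting backend in this package (direct scans, AD-trees, the joint-entropy
cache) must agree exactly with :func:`count_joint` on it.

Contingency tables are sparse mappings with *implicit zeros*: cells with a
zero count are never stored.  This mirrors the AD-tree convention (nodes are
never created for zero counts) and is what the degrees-of-freedom rule needs,
since it counts value levels with positive support per stratum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DiscreteDataset",
    "ContingencyTable",
    "load_dataset",
    "save_dataset",
    "recode_dataframe",
    "count_joint",
    "count_joint_rows",
    "project_counts",
]


class FormatError(ValueError):
    """Raised when an on-disk table cannot be parsed as integer-coded data."""


@dataclass(frozen=True)
class ContingencyTable:
    """Sparse joint counts over an ordered tuple of feature indices.

    ``counts`` maps value tuples (one value per feature, in ``features``
    order) to strictly positive counts; zero cells are implicit.  ``total``
    is the number of rows the table was built from.
    """

    features: tuple[int, ...]
    counts: dict[tuple[int, ...], int]
    total: int

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("contingency tables never store zero/negative cells")
        if self.counts and sum(self.counts.values()) != self.total:
            raise ValueError("cell counts do not sum to total")

    def project(self, keep: Sequence[int]) -> "ContingencyTable":
        return project_counts(self, keep)


class DiscreteDataset:
    """Integer-coded sample matrix with per-feature arity.

    Values in column ``i`` must lie in ``[0, arities[i])``.  Arities may
    exceed the observed maximum: a value can be legal yet absent from a
    finite sample, which matters for degrees-of-freedom bookkeeping.
    """

    def __init__(
        self,
        values: np.ndarray | Sequence[Sequence[int]],
        arities: Sequence[int] | None = None,
        feature_names: Sequence[str] | None = None,
    ) -> None:
        values = np.asarray(values)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("values must be a non-empty 2-D matrix")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(values == values.astype(np.int64)):
                raise FormatError("non-integer cell values")
            values = values.astype(np.int64)
        if values.min() < 0:
            raise ValueError("negative cell values are not valid category codes")
        self.values = np.ascontiguousarray(values, dtype=np.int64)
        n, m = self.values.shape
        observed = self.values.max(axis=0) + 1
        if arities is None:
            arities = observed.tolist()
        else:
            arities = [int(a) for a in arities]
            if len(arities) != m:
                raise ValueError("arities length does not match column count")
            for i, (a, o) in enumerate(zip(arities, observed)):
                if a < o:
                    raise ValueError(
                        f"arity {a} of column {i} below observed maximum {o - 1} + 1"
                    )
        if any(a < 1 for a in arities):
            raise ValueError("arities must be >= 1")
        if feature_names is None:
            feature_names = [f"X{i}" for i in range(m)]
        feature_names = [str(s) for s in feature_names]
        if len(feature_names) != m:
            raise ValueError("feature_names length does not match column count")
        if len(set(feature_names)) != m:
            raise ValueError("duplicate feature names")
        self.arities: list[int] = list(arities)
        self.feature_names: list[str] = feature_names

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(name) from None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DiscreteDataset(N={self.N}, M={self.M})"


def load_dataset(
    path: str | Path,
    delimiter: str | None = None,
    sidecar: str | Path | None = None,
) -> DiscreteDataset:
    """Read an integer-coded delimited table (header row required).

    ``delimiter`` defaults to sniffing between comma and tab.  ``sidecar``
    may point to a JSON file ``{"arities": [...]}`` overriding the arities
    inferred as (max column value + 1); if omitted, ``<path>.arities.json``
    is used when present.
    """
    path = Path(path)
    if delimiter is None:
        first = path.open().readline()
        delimiter = "\t" if "\t" in first else ","
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise FormatError(f"{path}: empty table")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                v = int(str(cell).strip())
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: row {i + 1}, column {col!r}: cell {cell!r} "
                    "is not an integer"
                ) from None
            if v < 0:
                raise ValueError(
                    f"{path}: row {i + 1}, column {col!r}: negative value {v}"
                )
            values[i, j] = v
    arities = None
    if sidecar is None:
        candidate = path.with_name(path.name + ".arities.json")
        if candidate.exists():
            sidecar = candidate
    if sidecar is not None:
        meta = json.loads(Path(sidecar).read_text())
        arities = meta["arities"]
    return DiscreteDataset(values, arities=arities, feature_names=list(df.columns))


def save_dataset(ds: DiscreteDataset, path: str | Path, delimiter: str = ",") -> None:
    """Write the dataset as a delimited text table with a header row."""
    pd.DataFrame(ds.values, columns=ds.feature_names).to_csv(
        path, sep=delimiter, index=False
    )


def recode_dataframe(df: pd.DataFrame) -> tuple[DiscreteDataset, dict[str, list]]:
    """One-shot recoder: map arbitrary categorical columns to integer codes.

    Returns the dataset plus, per column, the list of original category
    levels in code order (code ``k`` means ``levels[k]``).  The main loader
    deliberately does not remap strings, so that stored codes always align
    with arities and AD-tree value indexing.
    """
    values = np.empty(df.shape, dtype=np.int64)
    levels: dict[str, list] = {}
    for j, col in enumerate(df.columns):
        codes, uniques = pd.factorize(df[col], sort=True)
        if (codes < 0).any():
            raise ValueError(f"column {col!r} contains missing values")
        values[:, j] = codes
        levels[str(col)] = list(uniques)
    return DiscreteDataset(values, feature_names=[str(c) for c in df.columns]), levels


def _as_feature_tuple(features: Iterable[int]) -> tuple[int, ...]:
    if isinstance(features, (set, frozenset)):
        feats = tuple(sorted(features))
    else:
        feats = tuple(int(f) for f in features)
    if len(feats) == 0:
        raise ValueError("feature set must be non-empty (use N directly)")
    if len(set(feats)) != len(feats):
        raise ValueError("duplicate feature indices")
    return feats


def count_joint(ds: DiscreteDataset, features: Iterable[int]) -> ContingencyTable:
    """Joint counts of the given features over all rows (zero cells absent).

    Accepts any ordered feature sequence (key tuples follow that order) or an
    unordered set (sorted ascending).
    """
    feats = _as_feature_tuple(features)
    for f in feats:
        if not 0 <= f < ds.M:
            raise IndexError(f"feature index {f} out of range")
    sub = ds.values[:, feats]
    uniq, cnt = np.unique(sub, axis=0, return_counts=True)
    counts = {tuple(int(v) for v in row): int(c) for row, c in zip(uniq, cnt)}
    return ContingencyTable(feats, counts, ds.N)


def count_joint_rows(
    ds: DiscreteDataset, features: Iterable[int], rows: np.ndarray
) -> ContingencyTable:
    """Like :func:`count_joint` but restricted to a row-index subset.

    Used by AD-tree Leaf-Lists, which store row references and count them at
    query time.  ``total`` equals the number of rows given.
    """
    feats = _as_feature_tuple(features)
    rows = np.asarray(rows)
    sub = ds.values[rows][:, feats]
    uniq, cnt = np.unique(sub, axis=0, return_counts=True)
    counts = {tuple(int(v) for v in row): int(c) for row, c in zip(uniq, cnt)}
    return ContingencyTable(feats, counts, int(rows.size))


def project_counts(ct: ContingencyTable, keep: Iterable[int]) -> ContingencyTable:
    """Marginalize a contingency table onto a subset of its features."""
    keep_t = _as_feature_tuple(keep)
    if not set(keep_t) <= set(ct.features):
        raise ValueError(f"keep set {keep_t} is not a subset of {ct.features}")
    pos = [ct.features.index(f) for f in keep_t]
    out: dict[tuple[int, ...], int] = {}
    for key, c in ct.counts.items():
        k = tuple(key[p] for p in pos)
        out[k] = out.get(k, 0) + c
    return ContingencyTable(keep_t, out, ct.total)
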