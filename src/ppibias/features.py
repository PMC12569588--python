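"""Pair-feature construction from per-protein embeddings.

Two per-protein vectors are combined into one pair feature by
concatenation (``AB``), elementwise addition (``A + B``) or elementwise
multiplication (``A ⊙ B``).  Embeddings are consumed as given — no
normalisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from ppibias.data_model import InteractionDataset

COMBINATION_METHODS = ("concat", "add", "multiply")


class MissingEmbeddingError(KeyError):
    """A queried protein has no embedding; the message names the protein."""


class EmbeddingStore:
    """Mapping from protein identifier to a fixed-length real vector."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        self._vectors: dict[str, np.ndarray] = {}
        dim: int | None = None
        for pid, vec in vectors.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"embedding for {pid!r} is not a 1-D vector")
            if dim is None:
                dim = arr.shape[0]
            elif arr.shape[0] != dim:
                raise ValueError(
                    f"embedding for {pid!r} has length {arr.shape[0]}, expected {dim}"
                )
            self._vectors[pid] = arr
        if dim is None:
            raise ValueError("embedding store cannot be empty")
        self._dim = dim

    @property
    def dim(self) -> int:
        return self._dim

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self._vectors)

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, pid: str) -> bool:
        return pid in self._vectors

    def __getitem__(self, pid: str) -> np.ndarray:
        try:
            return self._vectors[pid]
        except KeyError:
            raise MissingEmbeddingError(
                f"no embedding for protein {pid!r}"
            ) from None

    def matrix(self, proteins: Iterable[str]) -> np.ndarray:
        """Row-stack the vectors of ``proteins`` in the given order."""
        return np.stack([self[p] for p in proteins])

    def write(self, path: str | Path, *, sep: str = "\t") -> None:
        """One row per protein: identifier followed by the vector values."""
        with Path(path).open("w") as fh:
            for pid in sorted(self._vectors):
                values = sep.join(repr(float(v)) for v in self._vectors[pid])
                fh.write(f"{pid}{sep}{values}\n")

    @classmethod
    def read(cls, path: str | Path, *, sep: str = "\t") -> "EmbeddingStore":
        vectors: dict[str, np.ndarray] = {}
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split(sep)
                if len(fields) < 2:
                    raise ValueError(f"{path}: line {lineno}: no vector values")
                pid = fields[0]
                if pid in vectors:
                    raise ValueError(f"{path}: line {lineno}: duplicate id {pid!r}")
                vectors[pid] = np.array([float(v) for v in fields[1:]])
        return cls(vectors)


@dataclass(frozen=True)
class PairFeature:
    """A combined pair vector tagged with the method that produced it."""

    values: np.ndarray
    method: str


def combine(a: np.ndarray, b: np.ndarray, method: str) -> PairFeature:
    """Combine two same-length vectors into one pair feature.

    ``concat`` preserves order (first-listed protein first) and has length
    ``2d``; ``add`` and ``multiply`` are elementwise and keep length ``d``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"vector shapes differ: {a.shape} vs {b.shape}")
    if method == "concat":
        values = np.concatenate([a, b])
    elif method == "add":
        values = a + b
    elif method == "multiply":
        values = a * b
    else:
        raise ValueError(
            f"unknown combination method {method!r}; expected one of {COMBINATION_METHODS}"
        )
    return PairFeature(values=values, method=method)


def build_design(
    ds: InteractionDataset,
    store: EmbeddingStore,
    method: str,
    *,
    augment_reverse: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the feature matrix and label vector for a dataset.

    Row ``i`` is the combination of the embeddings of interaction ``i``'s
    endpoints, in interaction order; labels are 1 (positive) / 0 (negative).

    ``augment_reverse`` appends, after all original rows, one reversed-pair
    row (``BA``) per interaction with the same label.  It is off by default:
    reverse-pair augmentation was evaluated and dropped upstream, and it is
    only informative for the asymmetric ``concat`` combination.
    """
    if method not in COMBINATION_METHODS:
        raise ValueError(
            f"unknown combination method {method!r}; expected one of {COMBINATION_METHODS}"
        )
    A = store.matrix(it.protein_a for it in ds)
    B = store.matrix(it.protein_b for it in ds)
    if method == "concat":
        X = np.hstack([A, B])
    elif method == "add":
        X = A + B
    else:
        X = A * B
    y = np.fromiter((it.label for it in ds), dtype=int, count=len(ds))
    if augment_reverse:
        if method == "concat":
            X_rev = np.hstack([B, A])
        elif method == "add":
            X_rev = B + A
        else:
            X_rev = B * A
        X = np.vstack([X, X_rev])
        y = np.concatenate([y, y])
    return X, y
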