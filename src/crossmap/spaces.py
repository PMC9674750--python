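"""Labeled vector spaces with cosine geometry and truncated-SVD reduction.

A :class:`VectorSpace` holds one row vector per label (words of a
distributional-semantic space, or images/prototypes of a visual feature
space).  All similarity computations in the package go through
:func:`cosine` / :func:`nearest_neighbors`; dimensionality reduction of
visual features goes through :func:`svd_reduce`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VectorSpace",
    "NeighborList",
    "SvdReduction",
    "read_word2vec_text",
    "write_word2vec_text",
    "cosine",
    "nearest_neighbors",
    "svd_reduce",
]


class FormatError(ValueError):
    """Raised when a vector-space file violates the word2vec text format."""


@dataclass
class VectorSpace:
    """An ordered set of labeled row vectors with cosine geometry.

    Parameters
    ----------
    labels
        Unique identifiers, one per matrix row, order preserved.
    matrix
        Real ``(n, d)`` array of row vectors (unitless activations).
    """

    labels: list[str]
    matrix: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        if self.matrix.shape[1] < 1:
            raise ValueError("dimension must be >= 1")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels but {self.matrix.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite values")
        self._index = {}
        for i, lab in enumerate(self.labels):
            if lab in self._index:
                raise ValueError(f"duplicate label: {lab!r}")
            self._index[lab] = i

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def vector(self, label: str) -> np.ndarray:
        """Return the row vector for ``label`` (KeyError if absent)."""
        return self.matrix[self._index[label]]

    def index(self, label: str) -> int:
        return self._index[label]

    def subset(self, labels: Iterable[str]) -> "VectorSpace":
        """New space restricted to ``labels``, in the given order."""
        labels = list(labels)
        rows = [self._index[l] for l in labels]
        return VectorSpace(labels, self.matrix[rows].copy())


@dataclass
class NeighborList:
    """Top-``k`` cosine neighbors of ``query``, descending by similarity."""

    query: str
    neighbors: list[tuple[str, float]]

    @property
    def k(self) -> int:
        return len(self.neighbors)

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.neighbors]


@dataclass
class SvdReduction:
    """Truncated-SVD output: reduced rows plus the projection for new vectors.

    ``reduced`` holds :math:`U_k S_k`; ``projection`` is the ``(d, k)``
    matrix of right singular vectors, so a new ``d``-vector ``x`` maps to
    ``x @ projection``.  Singular-vector signs are fixed so the
    largest-magnitude component of each right singular vector is positive,
    making serialized reductions reproducible.
    """

    reduced: np.ndarray
    projection: np.ndarray
    singular_values: np.ndarray

    def __iter__(self):  # allow tuple unpacking (reduced, projection)
        return iter((self.reduced, self.projection))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.projection


def read_word2vec_text(path: str | Path) -> VectorSpace:
    """Read a vector space in word2vec text format.

    The format is strict: a mandatory ``"count dim"`` header line followed
    by exactly ``count`` whitespace-separated ``"word v1 ... vd"`` rows.
    """
    path = Path(path)
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        header = fh.readline()
        parts = header.split()
        if len(parts) != 2:
            raise FormatError(
                f"{path}: header must be 'count dim', got {header.strip()!r}"
            )
        try:
            count, dim = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer header {header.strip()!r}") from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != dim + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {dim} values for "
                    f"{fields[0]!r}, got {len(fields) - 1}"
                )
            labels.append(fields[0])
            rows.append(np.array(fields[1:], dtype=float))
    if len(labels) != count:
        raise FormatError(
            f"{path}: header declares {count} rows but file has {len(labels)}"
        )
    if count == 0:
        raise FormatError(f"{path}: empty space")
    return VectorSpace(labels, np.vstack(rows))


def write_word2vec_text(space: VectorSpace, path: str | Path) -> None:
    """Write ``space`` in word2vec text format (round-trips to ~1e-10)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{len(space)} {space.dim}\n")
        for lab, row in zip(space.labels, space.matrix):
            fh.write(lab + " " + " ".join(f"{v:.12g}" for v in row) + "\n")


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity between two nonzero vectors of equal dimension."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for the zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _unit_rows(matrix: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("space contains a zero vector; cosine is undefined")
    return matrix / norms


def nearest_neighbors(
    space: VectorSpace,
    query: str,
    k: int = 50,
    candidates: Sequence[str] | None = None,
) -> NeighborList:
    """Top-``k`` cosine neighbors of ``query``, excluding the query itself.

    Ties in similarity are broken by lexicographic label order so results
    are deterministic across platforms.  ``candidates`` optionally
    restricts the pool of potential neighbors.
    """
    q = space.vector(query)  # KeyError if absent
    if candidates is None:
        pool = [lab for lab in space.labels if lab != query]
        mat = np.delete(space.matrix, space.index(query), axis=0)
    else:
        pool = [lab for lab in candidates if lab != query]
        if len(set(pool)) != len(pool):
            raise ValueError("candidate labels must be unique")
        mat = np.vstack([space.vector(lab) for lab in pool]) if pool else np.empty((0, space.dim))
    if k > len(pool):
        raise ValueError(f"k={k} exceeds the {len(pool)} available candidates")
    sims = _unit_rows(mat) @ (q / np.linalg.norm(q))
    order = sorted(range(len(pool)), key=lambda i: (-sims[i], pool[i]))[:k]
    return NeighborList(query, [(pool[i], float(sims[i])) for i in order])


def svd_reduce(matrix: np.ndarray, target_dim: int = 300) -> SvdReduction:
    """Truncated SVD of ``matrix`` keeping ``target_dim`` components.

    Returns the reduced rows :math:`U_k S_k` together with the projection
    ``V_k`` used to map new vectors into the same reduced space.
    ``target_dim`` may exceed the numerical rank (trailing components are
    then numerically zero) but not ``min(n, d)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, d = matrix.shape
    if not 1 <= target_dim <= min(n, d):
        raise ValueError(
            f"target_dim={target_dim} must be in [1, min(n, d)={min(n, d)}]"
        )
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    u, s, vt = u[:, :target_dim], s[:target_dim], vt[:target_dim]
    # Sign convention: largest-|.| component of each right singular vector > 0.
    for j in range(target_dim):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    return SvdReduction(u * s, vt.T.copy(), s.copy())
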