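"""Visual feature inventories: per-image feature vectors tagged with labels.

Implements the label/image selection rules used to build the visual side of
the mapping: keep labels with at least ``min_images`` images, cap the number
of images per label by random down-sampling, resolve multi-label image sets
to the highest-frequency label, average images into per-label prototypes,
and sample fixed-size exemplar sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .spaces import VectorSpace

__all__ = [
    "ImageInventory",
    "PrototypeSet",
    "filter_labels",
    "dedupe_multilabel",
    "compute_prototypes",
    "sample_exemplars",
]


@dataclass
class ImageInventory:
    """Feature vectors for individual images, each tagged with a label.

    ``image_ids`` need not be globally unique before multi-label resolution
    (the same image may appear under several labels); ``(image_id, label)``
    pairs are always unique.  ``label_frequency`` maps labels to corpus (or
    norms-table) word-frequency counts, used to resolve contested images.
    """

    image_ids: list[str]
    labels: list[str]
    matrix: np.ndarray
    label_frequency: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image_ids = [str(i) for i in self.image_ids]
        self.labels = [str(l) for l in self.labels]
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.image_ids)
        if len(self.labels) != n or self.matrix.shape[0] != n:
            raise ValueError("image_ids, labels and matrix rows must align")
        if n and not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")
        pairs = set(zip(self.image_ids, self.labels))
        if len(pairs) != n:
            raise ValueError("(image_id, label) pairs must be unique")

    def __len__(self) -> int:
        return len(self.image_ids)

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def unique_labels(self) -> list[str]:
        return sorted(set(self.labels))

    def group_rows(self) -> dict[str, list[int]]:
        """Row indices per label, labels in sorted order (single pass)."""
        groups: dict[str, list[int]] = {}
        for i, lab in enumerate(self.labels):
            groups.setdefault(lab, []).append(i)
        return {lab: groups[lab] for lab in sorted(groups)}

    def rows_for_label(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels, dtype=object) == label)

    def take(self, rows: np.ndarray | list[int]) -> "ImageInventory":
        rows = np.asarray(rows, dtype=int)
        return ImageInventory(
            [self.image_ids[i] for i in rows],
            [self.labels[i] for i in rows],
            self.matrix[rows].copy(),
            dict(self.label_frequency),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f{j + 1:04d}" for j in range(self.dim)]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(0, "image_id", self.image_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, label_frequency: Mapping[str, float] | None = None
    ) -> "ImageInventory":
        feat_cols = [c for c in df.columns if c not in ("image_id", "label")]
        return cls(
            list(df["image_id"]),
            list(df["label"]),
            df[feat_cols].to_numpy(dtype=float),
            dict(label_frequency or {}),
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, label_frequency: Mapping[str, float] | None = None
    ) -> "ImageInventory":
        return cls.from_frame(pd.read_csv(path, sep="\t"), label_frequency)


@dataclass
class PrototypeSet:
    """One mean feature vector per label, with the number of images averaged."""

    space: VectorSpace
    counts: dict[str, int]

    @property
    def labels(self) -> list[str]:
        return self.space.labels


def filter_labels(
    inv: ImageInventory, min_images: int = 100, cap: int = 200, seed: int | None = None
) -> ImageInventory:
    """Drop labels with fewer than ``min_images`` images; down-sample labels
    with more than ``cap`` images uniformly without replacement to ``cap``.

    Down-sampling is reproducible under ``seed``.  An empty result raises a
    warning, not an error.
    """
    if min_images > cap:
        raise ValueError("min_images must be <= cap")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    # sorted label order => deterministic rng consumption order
    for lab, rows in inv.group_rows().items():
        if len(rows) < min_images:
            continue
        if len(rows) > cap:
            rows = rng.choice(rows, size=cap, replace=False)
        keep.extend(sorted(np.asarray(rows).tolist()))
    if not keep:
        warnings.warn("filter_labels produced an empty inventory", stacklevel=2)
    return inv.take(sorted(keep))


def dedupe_multilabel(inv: ImageInventory) -> ImageInventory:
    """Resolve images tagged with several labels to the highest-frequency one.

    Frequency ties are broken lexicographically (the alphabetically earlier
    label wins).  Images tagged with a single label pass through unchanged.
    """
    by_image: dict[str, list[int]] = {}
    for i, img in enumerate(inv.image_ids):
        by_image.setdefault(img, []).append(i)
    keep: list[int] = []
    for img, rows in by_image.items():
        if len(rows) == 1:
            keep.append(rows[0])
            continue
        for i in rows:
            if inv.labels[i] not in inv.label_frequency:
                raise ValueError(
                    f"no frequency entry for contested label {inv.labels[i]!r}"
                )
        # max frequency; ties -> lexicographically smallest label
        keep.append(
            min(rows, key=lambda i: (-inv.label_frequency[inv.labels[i]], inv.labels[i]))
        )
    return inv.take(sorted(keep))


def compute_prototypes(inv: ImageInventory) -> PrototypeSet:
    """Arithmetic-mean prototype vector per label."""
    if len(inv) == 0:
        raise ValueError("cannot compute prototypes of an empty inventory")
    groups = inv.group_rows()
    labels = list(groups)
    protos = np.empty((len(labels), inv.dim))
    counts: dict[str, int] = {}
    for r, (lab, rows) in enumerate(groups.items()):
        protos[r] = inv.matrix[rows].mean(axis=0)
        counts[lab] = len(rows)
    return PrototypeSet(VectorSpace(labels, protos), counts)


def sample_exemplars(inv: ImageInventory, k: int = 20, seed: int | None = None) -> ImageInventory:
    """Uniformly sample exactly ``k`` images per label, without replacement.

    Raises if any label has fewer than ``k`` images (listing all deficient
    labels); reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    deficient = []
    keep: list[int] = []
    for lab, rows in inv.group_rows().items():
        if len(rows) < k:
            deficient.append(lab)
            continue
        chosen = rows if len(rows) == k else rng.choice(rows, size=k, replace=False)
        keep.extend(sorted(np.asarray(chosen).tolist()))
    if deficient:
        raise ValueError(f"labels with fewer than {k} images: {deficient}")
    return inv.take(sorted(keep))
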