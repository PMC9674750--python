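"""Relative position of visually grounded words in the language space.

Given the set of training labels (words that have a visual representation),
these metrics characterise how close a target word sits to visual
experience: how many of its nearest neighbors are training items, the rank
and similarity of the nearest training item, and the mean rank / mean
cosine similarity over *all* training items,

    mean_training_similarity(w) = (1/n) * sum_i cos(w, t_i),

with the t_i ranging over the n visually grounded training labels.  Ranks
are competition ranks (1-based; ties share the minimum rank) in the full
similarity ordering of the lexicon, the target word itself excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spaces import VectorSpace, nearest_neighbors

__all__ = ["NeighborhoodProfile", "visual_neighbor_count", "training_profile", "profile_table"]


@dataclass
class NeighborhoodProfile:
    """Neighborhood metrics of one word relative to the training labels."""

    word: str
    visual_neighbor_count: int
    nearest_training_rank: int
    nearest_training_similarity: float
    mean_training_rank: float
    mean_training_similarity: float


def visual_neighbor_count(
    lang: VectorSpace,
    word: str,
    training_labels: Iterable[str],
    k: int = 50,
) -> int:
    """Number of training labels among the word's k nearest neighbors."""
    training = set(training_labels)
    nn = nearest_neighbors(lang, word, k=k)
    return sum(1 for lab in nn.labels if lab in training)


def _similarities_to_all(lang: VectorSpace, word: str) -> tuple[list[str], np.ndarray]:
    """Cosines from ``word`` to every other label, in label order."""
    q = lang.vector(word)
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(lang.matrix, axis=1)
    if qn == 0.0 or np.any(norms == 0.0):
        raise ValueError("zero vector in space; cosine is undefined")
    sims = (lang.matrix @ q) / (norms * qn)
    others = [i for i, lab in enumerate(lang.labels) if lab != word]
    return [lang.labels[i] for i in others], sims[others]


def training_profile(
    lang: VectorSpace,
    word: str,
    training_labels: Iterable[str],
    k: int = 50,
) -> NeighborhoodProfile:
    """Full neighborhood profile of ``word`` against the training labels.

    The target word, if itself a training label, is excluded (with a
    warning): the metrics are meant for words outside the training set.
    """
    training = set(training_labels)
    if word in training:
        warnings.warn(
            f"{word!r} is itself a training label; excluded from its own profile",
            stacklevel=2,
        )
        training = training - {word}
    if not training:
        raise ValueError("empty training set")
    missing = training - set(lang.labels)
    if missing:
        raise KeyError(f"training labels missing from the space: {sorted(missing)[:10]}")

    labels, sims = _similarities_to_all(lang, word)
    # competition ranks: rank = 1 + number of items strictly more similar
    order = np.argsort(-sims, kind="stable")
    ranks = np.empty(len(labels), dtype=float)
    sorted_sims = sims[order]
    pos = 0
    while pos < len(labels):
        end = pos
        while end < len(labels) and sorted_sims[end] == sorted_sims[pos]:
            end += 1
        ranks[order[pos:end]] = pos + 1  # shared minimum rank
        pos = end

    is_training = np.array([lab in training for lab in labels])
    t_sims = sims[is_training]
    t_ranks = ranks[is_training]
    k_eff = min(k, len(lang) - 1)  # small toy lexicons: count within what exists
    return NeighborhoodProfile(
        word=word,
        visual_neighbor_count=visual_neighbor_count(lang, word, training, k=k_eff),
        nearest_training_rank=int(t_ranks.min()),
        nearest_training_similarity=float(t_sims.max()),
        mean_training_rank=float(t_ranks.mean()),
        mean_training_similarity=float(t_sims.mean()),
    )


def profile_table(
    lang: VectorSpace,
    words: Sequence[str],
    training_labels: Iterable[str],
    k: int = 50,
) -> pd.DataFrame:
    """Profiles for many words as a DataFrame (one row per word)."""
    training = set(training_labels)
    rows = []
    for w in words:
        p = training_profile(lang, w, training, k=k)
        rows.append(
            {
                "word": p.word,
                "visual_neighbor_count": p.visual_neighbor_count,
                "nearest_training_rank": p.nearest_training_rank,
                "nearest_training_similarity": p.nearest_training_similarity,
                "mean_training_rank": p.mean_training_rank,
                "mean_training_similarity": p.mean_training_similarity,
            }
        )
    return pd.DataFrame(rows)
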