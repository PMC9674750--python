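"""Item-selection procedures for the 2AFC experiments.

Two designs are implemented.  The five-condition design crosses a
concreteness median split with the presence of visually grounded words in
the target's immediate semantic neighborhood (far / near / maximum visual
neighbors), 23 items per condition.  The binned design decorrelates
concreteness from mean training-item similarity by sampling a fixed number
of items from each cell of an equal-width 2-D grid over both variables.

Norms tables are plain DataFrames with columns ``word``, ``concreteness``,
``frequency``, ``is_noun`` and optionally ``known_proportion``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spaces import VectorSpace

__all__ = [
    "CONDITIONS",
    "validate_norms",
    "candidate_pool",
    "median_split",
    "build_conditions_exp12",
    "grid_sample_exp3",
    "GridSample",
    "split_lists",
]

CONDITIONS = (
    "abstract/far",
    "abstract/near",
    "concrete/far",
    "concrete/near",
    "concrete/maximum",
)


def validate_norms(norms: pd.DataFrame) -> pd.DataFrame:
    required = {"word", "concreteness", "frequency", "is_noun"}
    missing = required - set(norms.columns)
    if missing:
        raise ValueError(f"norms table missing columns: {sorted(missing)}")
    if norms["word"].duplicated().any():
        dups = norms.loc[norms["word"].duplicated(), "word"].tolist()[:5]
        raise ValueError(f"duplicate words in norms table: {dups}")
    if not np.all(np.isfinite(norms["concreteness"])):
        raise ValueError("non-finite concreteness ratings")
    if (norms["frequency"] < 0).any():
        raise ValueError("negative frequencies")
    return norms


def candidate_pool(
    norms: pd.DataFrame,
    lang: VectorSpace,
    training_labels: Iterable[str],
    freq_min: float = 100,
    freq_max: float = 12_000,
    min_known: float | None = None,
) -> pd.DataFrame:
    """Nouns with frequency strictly inside (freq_min, freq_max), present in
    the language space and outside the training set.  ``min_known``
    optionally screens out unfamiliar words (requires a
    ``known_proportion`` column)."""
    validate_norms(norms)
    training = set(training_labels)
    mask = (
        norms["is_noun"].astype(bool)
        & (norms["frequency"] > freq_min)
        & (norms["frequency"] < freq_max)
        & norms["word"].map(lambda w: w in lang)
        & ~norms["word"].isin(training)
    )
    if min_known is not None:
        if "known_proportion" not in norms.columns:
            raise ValueError("min_known requires a known_proportion column")
        mask &= norms["known_proportion"] >= min_known
    pool = norms.loc[mask].reset_index(drop=True)
    if pool.empty:
        raise ValueError("candidate pool is empty after filtering")
    return pool


def median_split(pool: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split at the median concreteness; ratings at or below the median go
    to the abstract side (documented tie rule)."""
    if len(pool) < 2:
        raise ValueError("median split needs at least 2 words")
    med = float(pool["concreteness"].median())
    abstract = pool[pool["concreteness"] <= med].reset_index(drop=True)
    concrete = pool[pool["concreteness"] > med].reset_index(drop=True)
    return abstract, concrete


def _best_count_subset(counts: np.ndarray, size: int, target: float) -> list[int]:
    """Indices of a ``size``-subset of integer ``counts`` whose sum is as
    close as possible to ``target`` (exact subset-sum dynamic program).

    Counts must be small non-negative integers.  Deterministic: ties in
    achievable sums resolve toward the smaller sum, and the witness subset
    follows first-reached parent states in input order.
    """
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = len(counts)
    if size > n:
        raise ValueError("subset size exceeds pool size")
    smax = int(np.sort(counts)[-size:].sum()) if size else 0
    reach = np.zeros((size + 1, smax + 1), dtype=bool)
    parent = np.full((size + 1, smax + 1), -1, dtype=np.int32)
    reach[0, 0] = True
    for i in range(n):
        c = int(counts[i])
        for j in range(size - 1, -1, -1):
            if c == 0:
                shifted = reach[j]
            else:
                shifted = np.zeros(smax + 1, dtype=bool)
                shifted[c:] = reach[j, : smax + 1 - c]
            new = shifted & ~reach[j + 1]
            if new.any():
                parent[j + 1, new] = i
                reach[j + 1] |= new
    feasible = np.flatnonzero(reach[size])
    if feasible.size == 0:
        raise ValueError("no feasible subset")
    best = int(feasible[np.argmin(np.abs(feasible - target))])
    # backtrack: parent item indices are strictly decreasing along the chain
    chosen: list[int] = []
    j, s = size, best
    while j > 0:
        i = int(parent[j, s])
        chosen.append(i)
        s -= int(counts[i])
        j -= 1
    return sorted(chosen)


def build_conditions_exp12(
    abstract: pd.DataFrame,
    concrete: pd.DataFrame,
    counts: Mapping[str, int] | pd.DataFrame,
    n_per_condition: int = 23,
    seed: int | None = None,
) -> pd.DataFrame:
    """Assemble the five-condition item set (``n_per_condition`` words each).

    abstract/far and concrete/far are random draws from the words with zero
    visual neighbors; abstract/near and concrete/maximum are the words with
    the most visual neighbors on each side; concrete/near is the size-
    ``n_per_condition`` subset of the remaining concrete words whose mean
    visual-neighbor count best matches the abstract/near mean (exact
    integer subset-sum matching).

    ``counts`` maps word -> visual neighbor count (or a profile DataFrame
    with ``word`` and ``visual_neighbor_count`` columns).
    """
    if isinstance(counts, pd.DataFrame):
        counts = dict(zip(counts["word"], counts["visual_neighbor_count"]))
    rng = np.random.default_rng(seed)
    n = n_per_condition

    def _with_counts(df: pd.DataFrame) -> pd.DataFrame:
        missing = [w for w in df["word"] if w not in counts]
        if missing:
            raise KeyError(f"no visual-neighbor count for: {missing[:10]}")
        out = df.copy()
        out["visual_neighbor_count"] = [int(counts[w]) for w in out["word"]]
        return out.sort_values("word", kind="stable").reset_index(drop=True)

    abstract = _with_counts(abstract)
    concrete = _with_counts(concrete)

    def _sample_far(df: pd.DataFrame, name: str) -> pd.DataFrame:
        zero = df[df["visual_neighbor_count"] == 0]
        if len(zero) < n:
            raise ValueError(
                f"condition {name}: only {len(zero)} zero-neighbor candidates, need {n}"
            )
        rows = rng.choice(len(zero), size=n, replace=False)
        return zero.iloc[sorted(rows)]

    def _top(df: pd.DataFrame, name: str) -> pd.DataFrame:
        if len(df) < n:
            raise ValueError(f"condition {name}: only {len(df)} candidates, need {n}")
        return df.sort_values(
            ["visual_neighbor_count", "word"], ascending=[False, True], kind="stable"
        ).head(n)

    a_far = _sample_far(abstract, "abstract/far")
    c_far = _sample_far(concrete, "concrete/far")
    a_near = _top(abstract, "abstract/near")
    c_max = _top(concrete, "concrete/maximum")

    used = set(c_far["word"]) | set(c_max["word"])
    c_pool = concrete[~concrete["word"].isin(used)].reset_index(drop=True)
    if len(c_pool) < n:
        raise ValueError(
            f"condition concrete/near: only {len(c_pool)} candidates, need {n}"
        )
    target = n * float(a_near["visual_neighbor_count"].mean())
    idx = _best_count_subset(c_pool["visual_neighbor_count"].to_numpy(), n, target)
    c_near = c_pool.iloc[idx]

    parts = []
    for cond, df in [
        ("abstract/far", a_far),
        ("abstract/near", a_near),
        ("concrete/far", c_far),
        ("concrete/near", c_near),
        ("concrete/maximum", c_max),
    ]:
        part = df.copy()
        part["condition"] = cond
        parts.append(part)
    items = pd.concat(parts, ignore_index=True)
    if items["word"].duplicated().any():
        raise ValueError("conditions overlap: a word was selected twice")
    return items


@dataclass
class GridSample:
    """Result of the binned decorrelation sampler."""

    items: pd.DataFrame
    r_selected: float
    r_pool: float
    n_bins: int
    per_cell: int


def grid_sample_exp3(
    pool: pd.DataFrame,
    x_col: str = "concreteness",
    y_col: str = "mean_training_similarity",
    n_bins: int = 10,
    per_cell: int = 4,
    window: tuple[tuple[int, int], tuple[int, int]] | None = None,
    seed: int | None = None,
) -> GridSample:
    """Sample items from an equal-width 2-D grid over two covariates.

    The observed range of each variable is cut into ``n_bins`` equal-width
    bins (the maximum value falls in the top bin); from every cell inside
    ``window`` (inclusive ``((x_lo, x_hi), (y_lo, y_hi))`` cell-index
    bounds, default all cells) at most ``per_cell`` items are drawn
    uniformly without replacement — cells with fewer items contribute all
    of them.  The achieved Pearson correlation between the two variables in
    the selected set is reported alongside the pooled correlation.
    """
    if pool.empty:
        raise ValueError("empty pool")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)

    def _bin(values: np.ndarray) -> np.ndarray:
        mn, mx = float(values.min()), float(values.max())
        if mx == mn:
            return np.zeros(len(values), dtype=int)
        idx = np.floor((values - mn) / (mx - mn) * n_bins).astype(int)
        return np.minimum(idx, n_bins - 1)  # max value closes the top bin

    pool = pool.reset_index(drop=True)
    bx = _bin(pool[x_col].to_numpy(dtype=float))
    by = _bin(pool[y_col].to_numpy(dtype=float))

    if window is None:
        (x_lo, x_hi), (y_lo, y_hi) = (0, n_bins - 1), (0, n_bins - 1)
    else:
        (x_lo, x_hi), (y_lo, y_hi) = window

    chosen: list[int] = []
    for cx in range(x_lo, x_hi + 1):
        for cy in range(y_lo, y_hi + 1):
            members = np.flatnonzero((bx == cx) & (by == cy))
            if members.size == 0:
                continue
            if members.size <= per_cell:
                take = members
            else:
                take = rng.choice(members, size=per_cell, replace=False)
            chosen.extend(sorted(take.tolist()))

    items = pool.iloc[sorted(chosen)].reset_index(drop=True)
    items = items.assign(cell_x=bx[sorted(chosen)], cell_y=by[sorted(chosen)])
    r_pool = float(np.corrcoef(pool[x_col], pool[y_col])[0, 1])
    if len(items) >= 2 and items[x_col].std() > 0 and items[y_col].std() > 0:
        r_sel = float(np.corrcoef(items[x_col], items[y_col])[0, 1])
    else:
        r_sel = float("nan")
    return GridSample(items, r_sel, r_pool, n_bins, per_cell)


def split_lists(
    items: pd.DataFrame, n_lists: int, seed: int | None = None
) -> list[pd.DataFrame]:
    """Random partition into ``n_lists`` maximally even lists (sizes differ
    by at most 1), seeded; each list gets a ``list_id`` column."""
    if n_lists < 1:
        raise ValueError("n_lists must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(items))
    base, extra = divmod(len(items), n_lists)
    lists = []
    start = 0
    for i in range(n_lists):
        size = base + (1 if i < extra else 0)
        rows = sorted(perm[start : start + size].tolist())
        start += size
        part = items.iloc[rows].reset_index(drop=True).assign(list_id=i)
        lists.append(part)
    return lists
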