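import itertools

import numpy as np
import pandas as pd
import pytest

from crossmap.item_selection import (
    build_conditions_exp12,
    candidate_pool,
    grid_sample_exp3,
    median_split,
    split_lists,
)
from crossmap.spaces import VectorSpace


def norms_frame(words, conc, freq, noun=True):
    return pd.DataFrame(
        {
            "word": words,
            "concreteness": conc,
            "frequency": freq,
            "is_noun": noun if isinstance(noun, list) else [noun] * len(words),
        }
    )


class TestCandidatePool:
    @pytest.fixture
    def space(self, rng):
        words = [f"w{i}" for i in range(12)]
        return VectorSpace(words, rng.standard_normal((12, 3)))

    def test_boundary_frequencies_are_strict(self, space):
        norms = norms_frame(
            ["w0", "w1", "w2", "w3"],
            [3.0] * 4,
            [100, 101, 11999, 12000],
        )
        pool = candidate_pool(norms, space, [])
        assert set(pool["word"]) == {"w1", "w2"}

    def test_training_labels_excluded(self, space):
        norms = norms_frame(["w0", "w1"], [3.0, 3.0], [500, 500])
        pool = candidate_pool(norms, space, ["w0"])
        assert list(pool["word"]) == ["w1"]

    def test_hand_filtered_toy(self, space):
        words = [f"w{i}" for i in range(10)] + ["absent1", "absent2"]
        norms = norms_frame(
            words,
            [3.0] * 12,
            [50, 150, 200, 12500, 500, 900, 101, 99, 4000, 11000, 500, 600],
            noun=[True, True, False, True, True, True, True, True, True, False, True, True],
        )
        pool = candidate_pool(norms, space, ["w4"])
        # hand filter: in-space nouns, 100 < f < 12000, not training
        assert set(pool["word"]) == {"w1", "w5", "w6", "w8"}

    def test_empty_pool_rejected(self, space):
        norms = norms_frame(["w0"], [3.0], [5])
        with pytest.raises(ValueError, match="empty"):
            candidate_pool(norms, space, [])

    def test_optional_familiarity_screen(self, space):
        norms = norms_frame(["w0", "w1"], [3.0, 3.0], [500, 500])
        norms["known_proportion"] = [0.80, 0.99]
        pool = candidate_pool(norms, space, [], min_known=0.9)
        assert list(pool["word"]) == ["w1"]


class TestMedianSplit:
    def test_even_split(self):
        pool = norms_frame(list("abcd"), [1.0, 2.0, 3.0, 4.0], [500] * 4)
        abstract, concrete = median_split(pool)
        assert set(abstract["word"]) == {"a", "b"}
        assert set(concrete["word"]) == {"c", "d"}

    def test_all_equal_goes_abstract(self):
        pool = norms_frame(list("abc"), [2.5] * 3, [500] * 3)
        abstract, concrete = median_split(pool)
        assert len(abstract) == 3 and len(concrete) == 0

    def test_sizes_match_sort_oracle(self, rng):
        ratings = rng.uniform(1, 5, 101)
        pool = norms_frame([f"w{i}" for i in range(101)], ratings, [500] * 101)
        abstract, concrete = median_split(pool)
        med = np.median(ratings)
        assert len(abstract) == int(np.sum(ratings <= med))
        assert len(concrete) == int(np.sum(ratings > med))
        assert len(abstract) + len(concrete) == 101


def pools_with_counts(rng, n_abstract=60, n_concrete=60, zero_frac=0.5, max_count=10):
    def make(prefix, n):
        words = [f"{prefix}{i:03d}" for i in range(n)]
        conc = rng.uniform(1, 3, n) if prefix == "a" else rng.uniform(3, 5, n)
        counts = {}
        for w in words:
            counts[w] = 0 if rng.random() < zero_frac else int(rng.integers(1, max_count))
        return norms_frame(words, conc, [500] * n), counts

    a_df, a_counts = make("a", n_abstract)
    c_df, c_counts = make("c", n_concrete)
    return a_df, c_df, {**a_counts, **c_counts}


class TestBuildConditionsExp12:
    def test_five_by_n_items(self, rng):
        a, c, counts = pools_with_counts(rng)
        items = build_conditions_exp12(a, c, counts, n_per_condition=10, seed=1)
        assert len(items) == 50
        assert items["condition"].value_counts().eq(10).all()
        assert not items["word"].duplicated().any()

    def test_far_conditions_have_zero_counts(self, rng):
        a, c, counts = pools_with_counts(rng)
        items = build_conditions_exp12(a, c, counts, n_per_condition=10, seed=2)
        far = items[items["condition"].str.endswith("/far")]
        assert (far["visual_neighbor_count"] == 0).all()

    def test_maximum_condition_takes_top_counts(self, rng):
        a, c, counts = pools_with_counts(rng)
        items = build_conditions_exp12(a, c, counts, n_per_condition=5, seed=3)
        cmax = items[items["condition"] == "concrete/maximum"]
        top5 = sorted((counts[w] for w in c["word"]), reverse=True)[:5]
        assert sorted(cmax["visual_neighbor_count"], reverse=True) == top5

    def test_near_matching_is_optimal_vs_exhaustive(self, rng):
        # small pool: compare the matched mean against exhaustive search
        a, c, counts = pools_with_counts(rng, n_abstract=40, n_concrete=40,
                                         zero_frac=0.4, max_count=6)
        n = 4
        items = build_conditions_exp12(a, c, counts, n_per_condition=n, seed=4)
        target = items.loc[
            items["condition"] == "abstract/near", "visual_neighbor_count"
        ].mean()
        got = items.loc[
            items["condition"] == "concrete/near", "visual_neighbor_count"
        ].mean()
        used = set(
            items.loc[items["condition"].isin(["concrete/far", "concrete/maximum"]),
                      "word"]
        )
        pool_counts = [counts[w] for w in c["word"] if w not in used]
        best = min(
            abs(np.mean(combo) - target)
            for combo in itertools.combinations(pool_counts, n)
        )
        assert abs(got - target) <= best + 1e-9

    def test_insufficient_candidates_reported(self, rng):
        a, c, counts = pools_with_counts(rng, n_abstract=5, n_concrete=60)
        with pytest.raises(ValueError, match="abstract"):
            build_conditions_exp12(a, c, counts, n_per_condition=20, seed=0)


class TestGridSampleExp3:
    @staticmethod
    def pool_bivariate(rng, n=800, r=0.53):
        cov = [[1.0, r], [r, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        return pd.DataFrame(
            {
                "word": [f"w{i}" for i in range(n)],
                "concreteness": 3.0 + xy[:, 0],
                "mean_training_similarity": 0.1 + 0.05 * xy[:, 1],
            }
        )

    def test_undersized_cell_fully_taken(self, rng):
        pool = pd.DataFrame(
            {
                "word": ["a", "b", "c"],
                "concreteness": [1.0, 1.1, 5.0],
                "mean_training_similarity": [0.0, 0.01, 0.5],
            }
        )
        out = grid_sample_exp3(pool, n_bins=2, per_cell=4, seed=0)
        assert len(out.items) == 3

    def test_per_cell_cap_respected(self, rng):
        pool = self.pool_bivariate(rng, n=2000)
        out = grid_sample_exp3(pool, n_bins=10, per_cell=4, seed=1)
        cells = out.items.groupby(["cell_x", "cell_y"]).size()
        assert (cells <= 4).all()

    def test_bin_assignment_matches_floor_oracle(self):
        pool = pd.DataFrame(
            {
                "word": list("abcde"),
                "concreteness": [0.0, 0.09, 0.5, 0.99, 1.0],
                "mean_training_similarity": [0.0, 0.2, 0.5, 0.7, 1.0],
            }
        )
        out = grid_sample_exp3(pool, n_bins=10, per_cell=5, seed=0)
        got = dict(zip(out.items["word"], out.items["cell_x"]))
        # floor(x*10) with the max value closed into the top bin
        assert got == {"a": 0, "b": 0, "c": 5, "d": 9, "e": 9}

    def test_decorrelates_in_most_replicates(self, rng):
        # capped sampling over a *central* window of cells (where the grid
        # is densely populated) approximates a uniform fill of a rectangle
        # and so shrinks the correlation; with no window the occupied
        # region is elliptical and uniform sampling preserves r.
        wins = 0
        for seed in range(100):
            pool = self.pool_bivariate(np.random.default_rng(seed), n=600)
            out = grid_sample_exp3(
                pool, n_bins=10, per_cell=4, window=((2, 7), (2, 7)), seed=seed
            )
            if abs(out.r_selected) < abs(out.r_pool):
                wins += 1
        assert wins >= 90

    def test_window_restricts_cells(self, rng):
        pool = self.pool_bivariate(rng, n=1000)
        out = grid_sample_exp3(
            pool, n_bins=10, per_cell=4, window=((2, 7), (2, 7)), seed=2
        )
        assert out.items["cell_x"].between(2, 7).all()
        assert out.items["cell_y"].between(2, 7).all()


class TestSplitLists:
    @staticmethod
    def items_frame(n):
        return pd.DataFrame({"word": [f"w{i}" for i in range(n)]})

    def test_371_into_three_lists(self):
        lists = split_lists(self.items_frame(371), 3, seed=0)
        assert sorted(len(l) for l in lists) == [123, 124, 124]

    def test_exact_division(self):
        lists = split_lists(self.items_frame(9), 3, seed=1)
        assert [len(l) for l in lists] == [3, 3, 3]

    def test_partition_law(self):
        items = self.items_frame(50)
        lists = split_lists(items, 4, seed=2)
        union = pd.concat(lists)["word"]
        assert sorted(union) == sorted(items["word"])
        assert not union.duplicated().any()

    def test_seeded_determinism(self):
        a = split_lists(self.items_frame(20), 3, seed=9)
        b = split_lists(self.items_frame(20), 3, seed=9)
        for x, y in zip(a, b):
            assert list(x["word"]) == list(y["word"])
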