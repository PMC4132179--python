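"""Uncentered Pearson similarity, UPGMA clustering and cluster extraction."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import cosine, squareform

from chiscreen.cluster import (
    Dendrogram,
    UndefinedSimilarityError,
    average_linkage,
    cut_clusters,
    drop_empty_profiles,
    similarity_to_distance,
    two_way_cluster,
    uncentered_pearson,
)
from chiscreen.matrix import WeightedMatrix

from conftest import random_distance_matrix


def brute_force_upgma(dist: np.ndarray):
    """O(n^3) UPGMA oracle: recompute every cluster pair's mean cross-leaf
    distance from the original matrix at each step."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    partitions = [tuple(sorted(tuple(sorted(c)) for c in clusters))]
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best[0]:
                    best = (d, (i, j))
        d, (i, j) = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        partitions.append(tuple(sorted(tuple(sorted(c)) for c in clusters)))
    return heights, partitions


class TestUncenteredPearson:
    def test_self_similarity_is_one(self):
        assert uncentered_pearson([3, 0, 1], [3, 0, 1]) == pytest.approx(1.0)

    def test_orthogonal_profiles(self):
        assert uncentered_pearson([3, 0], [0, 3]) == pytest.approx(0.0)

    def test_hand_computed_overlap(self):
        assert uncentered_pearson([3, 0, 0], [3, 3, 0]) == pytest.approx(
            9 / (3 * np.sqrt(18))
        )

    @given(st.integers(0, 500))
    def test_matches_cosine_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert uncentered_pearson(x, y) == pytest.approx(1 - cosine(x, y), abs=1e-12)

    @given(st.integers(0, 500))
    def test_equals_centered_pearson_on_mean_zero_vectors(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        x -= x.mean()
        y -= y.mean()
        assert uncentered_pearson(x, y) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12
        )

    @given(
        st.floats(0.01, 100.0),
        st.floats(0.01, 100.0),
        st.integers(0, 500),
    )
    def test_scale_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        assert uncentered_pearson(a * x, b * y) == pytest.approx(
            uncentered_pearson(x, y), abs=1e-9
        )

    def test_all_zero_vector_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            uncentered_pearson([0, 0, 0], [1, 2, 3])

    @pytest.mark.parametrize("s, d", [(1.0, 0.0), (0.0, 1.0), (-1.0, 2.0)])
    def test_similarity_to_distance(self, s, d):
        assert similarity_to_distance(s) == pytest.approx(d)


class TestAverageLinkage:
    def test_three_leaf_hand_example(self):
        # d(A,B)=2, d(A,C)=6, d(B,C)=8: merge {A,B} at 2, then C at (6+8)/2
        d = np.array([[0, 2, 6], [2, 0, 8], [6, 8, 0]], dtype=float)
        dend = average_linkage(d, ["A", "B", "C"])
        assert dend.merge_heights == pytest.approx((2.0, 7.0))
        assert dend.merges[0][:2] == (0, 1)

    def test_two_items_merge_at_their_distance(self):
        d = np.array([[0, 0.4], [0.4, 0]])
        dend = average_linkage(d, ["x", "y"])
        assert dend.merge_heights == pytest.approx((0.4,))

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_matches_brute_force_oracle(self, n):
        """Merge heights and every intermediate partition agree with an
        O(n^3) re-averaging oracle on 200 random instances."""
        for seed in range(200):
            rng = np.random.default_rng(1000 * n + seed)
            d = random_distance_matrix(rng, n)
            dend = average_linkage(d, [f"i{k}" for k in range(n)])
            heights, partitions = brute_force_upgma(d)
            assert np.allclose(dend.merge_heights, heights, atol=1e-9)
            for k in range(1, n + 1):
                labels = cut_clusters(dend, k)
                # compare partitions as frozensets of leaf-index sets
                by_label: dict[int, set] = {}
                for idx, leaf in enumerate(dend.ids):
                    by_label.setdefault(labels[leaf], set()).add(idx)
                mine = {frozenset(v) for v in by_label.values()}
                oracle = {frozenset(c) for c in partitions[n - k]}
                assert mine == oracle

    @given(st.integers(0, 300))
    def test_matches_scipy_average_linkage_heights(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        d = random_distance_matrix(rng, n)
        dend = average_linkage(d, [str(i) for i in range(n)])
        z = hierarchy.linkage(squareform(d, checks=False), method="average")
        assert np.allclose(sorted(dend.merge_heights), sorted(z[:, 2]), atol=1e-9)

    @given(st.integers(0, 300))
    def test_merge_heights_monotone(self, seed):
        rng = np.random.default_rng(seed)
        d = random_distance_matrix(rng, int(rng.integers(3, 15)))
        heights = average_linkage(d, [str(i) for i in range(d.shape[0])]).merge_heights
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    @given(st.integers(0, 200))
    def test_leaf_permutation_preserves_heights_and_partitions(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        d = random_distance_matrix(rng, n)
        ids = [f"i{k}" for k in range(n)]
        perm = rng.permutation(n)
        dend = average_linkage(d, ids)
        dend_p = average_linkage(d[np.ix_(perm, perm)], [ids[i] for i in perm])
        assert np.allclose(sorted(dend.merge_heights), sorted(dend_p.merge_heights))
        for k in (2, 3):
            sets_a = {
                frozenset(l for l, lab in cut_clusters(dend, k).items() if lab == c)
                for c in range(1, k + 1)
            }
            sets_b = {
                frozenset(l for l, lab in cut_clusters(dend_p, k).items() if lab == c)
                for c in range(1, k + 1)
            }
            assert sets_a == sets_b

    def test_nan_distances_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="NaN"):
            average_linkage(d, ["a", "b"])


class TestCutClusters:
    def test_trivial_cuts(self):
        d = random_distance_matrix(np.random.default_rng(3), 6)
        dend = average_linkage(d, [f"i{k}" for k in range(6)])
        assert set(cut_clusters(dend, 1).values()) == {1}
        assert sorted(cut_clusters(dend, 6).values()) == [1, 2, 3, 4, 5, 6]

    def test_labels_contiguous_in_leaf_order(self):
        d = random_distance_matrix(np.random.default_rng(4), 8)
        dend = average_linkage(d, [f"i{k}" for k in range(8)])
        labels = cut_clusters(dend, 4)
        seen = []
        for leaf in dend.leaf_order():
            if labels[leaf] not in seen:
                seen.append(labels[leaf])
        assert seen == [1, 2, 3, 4]

    def test_out_of_range_k(self):
        d = random_distance_matrix(np.random.default_rng(5), 4)
        dend = average_linkage(d, list("abcd"))
        for k in (0, 5):
            with pytest.raises(ValueError):
                cut_clusters(dend, k)


def _block_matrix() -> WeightedMatrix:
    """Two clean allele blocks over disjoint gene sets."""
    w = pd.DataFrame(
        [
            [3, 3, 2, 0, 0, 0, 0, 0],
            [3, 2, 3, 0, 0, 0, 0, 0],
            [2, 3, 3, 0, 0, 0, 0, 0],
            [0, 0, 0, 3, 3, 2, 1, 0],
            [0, 0, 0, 2, 3, 3, 1, 0],
            [0, 0, 0, 3, 2, 3, 2, 0],
        ],
        index=[f"a{i}" for i in range(6)],
        columns=[f"g{i}" for i in range(8)],
    )
    return WeightedMatrix(weights=w)


class TestTwoWayCluster:
    def test_block_diagonal_top_split(self):
        with pytest.warns(UserWarning, match="all-zero gene"):
            rows, cols = two_way_cluster(_block_matrix())
        labels = cut_clusters(rows, 2)
        assert {labels[f"a{i}"] for i in range(3)} == {1}
        assert {labels[f"a{i}"] for i in range(3, 6)} == {2}

    def test_transpose_swaps_dendrograms(self):
        m = _block_matrix()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows, cols = two_way_cluster(m)
            rows_t, cols_t = two_way_cluster(WeightedMatrix(weights=m.weights.T))
        assert rows.merges == cols_t.merges and cols.merges == rows_t.merges
        assert rows.ids == cols_t.ids and cols.ids == rows_t.ids

    def test_duplicate_rows_merge_first_at_similarity_one(self):
        w = pd.DataFrame(
            [[3, 1, 0], [3, 1, 0], [0, 2, 3], [1, 0, 3]],
            index=list("abcd"),
            columns=["g1", "g2", "g3"],
        )
        rows, _ = two_way_cluster(WeightedMatrix(weights=w))
        first = rows.merges[0]
        assert {rows.ids[first[0]], rows.ids[first[1]]} == {"a", "b"}
        assert first[2] == pytest.approx(1.0)

    def test_all_zero_profiles_dropped_with_warning(self):
        w = pd.DataFrame(
            [[3, 0, 1], [0, 0, 0], [1, 0, 3]],
            index=list("abc"),
            columns=["g1", "g2", "g3"],
        )
        with pytest.warns(UserWarning, match="all-zero"):
            filtered = drop_empty_profiles(WeightedMatrix(weights=w))
        assert filtered.allele_ids == ("a", "c")
        assert filtered.gene_ids == ("g1", "g3")

    def test_too_few_profiles_raise(self):
        w = pd.DataFrame([[3, 1], [0, 0]], index=["a", "b"], columns=["g1", "g2"])
        with pytest.raises(ValueError):
            two_way_cluster(WeightedMatrix(weights=w))


class TestDendrogramInvariants:
    def test_merge_bookkeeping_validated(self):
        with pytest.raises(ValueError):
            Dendrogram(ids=("a", "b", "c"), merges=((0, 1, 0.5),))
        with pytest.raises(ValueError):
            Dendrogram(ids=("a", "b"), merges=((0, 0, 0.5),))

    def test_leaf_order_covers_all_leaves(self, synthetic_default):
        from chiscreen.matrix import reverse_weights

        _, _, _, matrix, _, _ = synthetic_default
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows, cols = two_way_cluster(drop_empty_profiles(reverse_weights(matrix)))
        assert sorted(rows.leaf_order()) == sorted(rows.ids)
        assert sorted(cols.leaf_order()) == sorted(cols.ids)
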