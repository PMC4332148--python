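import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from proteoplex.clustering import (
    ClusteringError,
    ahc_upgma,
    max_normalize,
    pca_pearson,
    pearson_dissimilarity,
    supervised_cluster,
    upgma,
)


# --- exhaustive oracle ------------------------------------------------------


def upgma_oracle(d: np.ndarray, leaves):
    """Naive UPGMA: clusters as explicit leaf sets, inter-cluster distance
    recomputed from the original matrix at every step (O(n^4))."""
    clusters = {i: frozenset([i]) for i in range(len(leaves))}
    merges = []
    next_id = len(leaves)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                dist = np.mean(
                    [d[i, j] for i in clusters[a] for j in clusters[b]]
                )
                cand = (dist, (a, b))
                if best is None or cand < best:
                    best = cand
        dist, (a, b) = best
        merged = clusters.pop(a) | clusters.pop(b)
        merges.append((a, b, dist, len(merged)))
        clusters[next_id] = merged
        next_id += 1
    return merges


def random_dissimilarity(rng, n):
    x = rng.random((n, n))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


# --- max normalization ------------------------------------------------------


class TestMaxNormalize:
    def test_row_scaled_to_unit_maximum(self):
        values = pd.DataFrame({"s1": [2.0], "s2": [4.0], "s3": [1.0]}, index=["P"])
        norm, excluded = max_normalize(values)
        np.testing.assert_allclose(norm.loc["P"], [0.5, 1.0, 0.25])
        assert excluded == []

    def test_constant_row(self):
        values = pd.DataFrame({"s1": [5.0], "s2": [5.0], "s3": [5.0]}, index=["P"])
        norm, _ = max_normalize(values)
        np.testing.assert_allclose(norm.loc["P"], [1, 1, 1])

    def test_missing_values_preserved(self):
        values = pd.DataFrame({"s1": [2.0], "s2": [np.nan]}, index=["P"])
        norm, _ = max_normalize(values)
        assert norm.loc["P", "s1"] == 1.0
        assert np.isnan(norm.loc["P", "s2"])

    def test_all_missing_row_excluded(self):
        values = pd.DataFrame(
            {"s1": [1.0, np.nan], "s2": [2.0, np.nan]}, index=["P", "Q"]
        )
        norm, excluded = max_normalize(values)
        assert excluded == ["Q"]
        assert list(norm.index) == ["P"]


# --- UPGMA ------------------------------------------------------------------


class TestUpgma:
    def test_merge_sequence_matches_exhaustive_oracle(self, rng):
        for n in (6, 8, 10):
            for _ in range(5):
                d = random_dissimilarity(rng, n)
                leaves = [f"L{i}" for i in range(n)]
                got = upgma(d, leaves).merges
                want = upgma_oracle(d, leaves)
                assert len(got) == len(want)
                for (a, b, h, s), (oa, ob, oh, os) in zip(got, want):
                    assert {a, b} == {oa, ob}
                    assert h == pytest.approx(oh, rel=1e-10)
                    assert s == os

    def test_heights_match_scipy_average_linkage(self, rng):
        d = random_dissimilarity(rng, 9)
        ours = upgma(d, [f"L{i}" for i in range(9)]).to_linkage()
        theirs = hierarchy.linkage(squareform(d), method="average")
        np.testing.assert_allclose(
            np.sort(ours[:, 2]), np.sort(theirs[:, 2]), rtol=1e-10
        )

    def test_heights_monotone_non_decreasing(self, rng):
        for _ in range(10):
            d = random_dissimilarity(rng, 7)
            heights = [m[2] for m in upgma(d, list("abcdefg")).merges]
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_identical_rows_merge_first_at_height_zero(self):
        values = pd.DataFrame(
            {
                "P1": [1.0, 2.0, 3.0],
                "P2": [2.0, 4.0, 6.0],  # r = 1 with P1 -> d = 0
                "P3": [5.0, 1.0, 2.0],
            }
        ).T
        dendro, _ = ahc_upgma(values)
        first = dendro.merges[0]
        assert {dendro.leaves[first[0]], dendro.leaves[first[1]]} == {"P1", "P2"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_have_distance_two(self):
        values = pd.DataFrame({"P1": [1.0, 2.0, 3.0], "P2": [3.0, 2.0, 1.0]}).T
        d, undefined = pearson_dissimilarity(values)
        assert d[0, 1] == pytest.approx(2.0)
        assert undefined == []

    def test_zero_variance_pair_maximal_and_reported(self):
        values = pd.DataFrame({"P1": [1.0, 1.0, 1.0], "P2": [1.0, 2.0, 3.0]}).T
        d, undefined = pearson_dissimilarity(values)
        assert d[0, 1] == 2.0
        assert undefined == [("P1", "P2")]

    def test_deterministic_tie_break(self):
        # three leaves all at equal distance: the smallest index pair wins
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        merges = upgma(d, list("abc")).merges
        assert (merges[0][0], merges[0][1]) == (0, 1)

    def test_newick_and_cut(self):
        d = np.array(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]]
        )
        dendro = upgma(d, ["a", "b", "c"])
        labels = dendro.cut(2)
        assert labels["a"] == labels["b"] != labels["c"]
        newick = dendro.to_newick()
        assert newick.endswith(";") and "a" in newick and "c" in newick


# --- supervised clustering --------------------------------------------------


class TestSupervisedCluster:
    def test_block_matrix_cuts_into_three_groups(self, rng):
        blocks = {}
        for g, cols in enumerate([(0, 1), (2, 3), (4, 5)]):
            for i in range(4):
                row = rng.normal(0.05, 0.02, 6).clip(0, 1)
                row[list(cols)] = rng.normal(0.9, 0.02, 2).clip(0, 1)
                blocks[f"g{g}_p{i}"] = row
        r2 = pd.DataFrame(blocks).T
        result = supervised_cluster(r2)
        labels = result.dendrogram.cut(3)
        for g in range(3):
            group = {labels[f"g{g}_p{i}"] for i in range(4)}
            assert len(group) == 1
        assert len({labels[f"g{g}_p0"] for g in range(3)}) == 3

    def test_duplicated_rows_merge_at_zero_height(self):
        r2 = pd.DataFrame(
            {"ref1": [0.9, 0.9, 0.1], "ref2": [0.1, 0.1, 0.8]},
            index=["dup1", "dup2", "other"],
        )
        result = supervised_cluster(r2)
        first = result.dendrogram.merges[0]
        assert first[2] == pytest.approx(0.0)
        assert {result.dendrogram.leaves[first[0]],
                result.dendrogram.leaves[first[1]]} == {"dup1", "dup2"}

    def test_row_order_covers_all_rows(self, rng):
        r2 = pd.DataFrame(rng.random((5, 3)), index=list("abcde"))
        result = supervised_cluster(r2)
        assert sorted(result.row_order) == list("abcde")
        assert list(result.matrix.index) == result.row_order

    def test_undefined_cells_rejected(self):
        r2 = pd.DataFrame({"ref": [0.1, np.nan]}, index=["a", "b"])
        with pytest.raises(ClusteringError, match="undefined"):
            supervised_cluster(r2)


# --- PCA --------------------------------------------------------------------


class TestPcaPearson:
    def test_explained_variance_sums_to_one(self, rng):
        norm = pd.DataFrame(rng.random((10, 5)))
        result = pca_pearson(norm)
        assert result.explained.sum() == pytest.approx(1.0)

    def test_two_perfectly_correlated_variables(self, rng):
        base = rng.random(12)
        norm = pd.DataFrame({"v1": base, "v2": 3 * base + 1, "v3": rng.random(12)})
        result = pca_pearson(norm)
        load = result.loadings
        # the component carrying v1 also carries v2 with equal weight
        assert abs(load.loc["v1", "PC1"]) == pytest.approx(
            abs(load.loc["v2", "PC1"]), rel=1e-9
        )

    def test_eigenvalues_match_bruteforce_on_4x4_toy(self):
        norm = pd.DataFrame(
            [
                [0.1, 1.0, 0.3, 0.2],
                [0.4, 0.8, 0.9, 0.1],
                [0.9, 0.2, 0.7, 0.6],
                [0.3, 0.5, 0.2, 1.0],
            ],
            columns=list("wxyz"),
        )
        x = norm.to_numpy()
        z = (x - x.mean(axis=0)) / x.std(axis=0)  # population std
        corr = np.corrcoef(x, rowvar=False)  # independent correlation route
        want = np.sort(np.linalg.eigvalsh(corr))[::-1]
        result = pca_pearson(norm)
        got = result.explained.to_numpy() * want.sum()
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)
        # scores reproduce the standardized data in the component basis
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
        np.testing.assert_allclose(recon, z, rtol=1e-9, atol=1e-9)

    def test_scores_invariant_to_variable_rescaling(self, rng):
        norm = pd.DataFrame(rng.random((8, 4)))
        scaled = norm * np.array([3.0, 0.5, 10.0, 1.0]) + np.array([1.0, -2.0, 0.0, 5.0])
        a = pca_pearson(norm)
        b = pca_pearson(scaled)
        np.testing.assert_allclose(
            a.scores.to_numpy(), b.scores.to_numpy(), rtol=1e-8, atol=1e-8
        )

    def test_zero_variance_variable_dropped(self, rng):
        norm = pd.DataFrame(rng.random((6, 4)))
        norm[1] = 7.0
        result = pca_pearson(norm)
        assert result.dropped == [1]
        assert 1 not in result.loadings.index

    def test_too_small_input_rejected(self):
        with pytest.raises(ClusteringError, match="at least 3"):
            pca_pearson(pd.DataFrame(np.ones((2, 5))))
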