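import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from germdiv import (
    DistanceMatrix,
    cophenetic_correlation,
    cophenetic_matrix,
    cut_tree,
    upgma,
)
from germdiv.errors import DataError


def brute_force_upgma_cophenetic(values, labels):
    """Reference UPGMA: re-average raw distances over all member pairs each step.

    Independent of the incremental update used by the implementation.
    """
    n = len(labels)
    clusters = {i: frozenset([i]) for i in range(n)}
    cop = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            members_a, members_b = clusters[a], clusters[b]
            d = np.mean([values[i, j] for i in members_a for j in members_b])
            rank = tuple(sorted((min(labels[i] for i in members_a),
                                 min(labels[i] for i in members_b))))
            if best is None or (d, rank) < (best[0], best[1]):
                best = (d, rank, a, b)
        d, _, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                cop[i, j] = cop[j, i] = d
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return cop


def random_distance(rng, n):
    x = rng.random((n, max(2, n - 1)))
    v = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    return DistanceMatrix([chr(65 + i) for i in range(n)], v, "test", {})


class TestUpgma:
    def test_three_leaf_hand_example(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float),
            "test", {},
        )
        t = upgma(d)
        assert [m[2] for m in t.merges] == [2.0, 8.0]
        cop = cophenetic_matrix(t)
        assert cop.loc("A", "B") == 2.0
        assert cop.loc("A", "C") == 8.0
        assert cop.loc("B", "C") == 8.0
        assert cut_tree(t, 2) == {"A": 0, "B": 0, "C": 1}

    def test_two_leaves(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]), "t", {})
        t = upgma(d)
        assert t.merges == ((0, 1, 3.0),)

    def test_ultrametric_input_reproduced_exactly(self):
        # five-leaf ultrametric built from nested merge heights
        labels = ["A", "B", "C", "D", "E"]
        cop = np.array(
            [
                [0, 1, 4, 4, 9],
                [1, 0, 4, 4, 9],
                [4, 4, 0, 2, 9],
                [4, 4, 2, 0, 9],
                [9, 9, 9, 9, 0],
            ],
            dtype=float,
        )
        d = DistanceMatrix(labels, cop, "ultra", {})
        t = upgma(d)
        assert np.allclose(t.cophenetic(), cop)
        assert cophenetic_correlation(d, t) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(3, 9))
            d = random_distance(rng, n)
            t = upgma(d)
            ref = brute_force_upgma_cophenetic(d.values, d.ids)
            assert np.allclose(t.cophenetic(), ref, atol=1e-9)

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            d = random_distance(rng, n)
            t = upgma(d)
            Z = average(d.condensed())
            assert np.allclose(
                squareform(t.cophenetic()), cophenet(Z), atol=1e-9
            )

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = upgma(random_distance(rng, int(rng.integers(3, 12))))
            heights = [m[2] for m in t.merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_nan_rejected(self):
        v = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(DataError):
            DistanceMatrix(["A", "B"], v, "t", {})


class TestCophenetic:
    def test_ultrametric_three_point_law(self):
        rng = np.random.default_rng(6)
        t = upgma(random_distance(rng, 7))
        cop = t.cophenetic()
        for i, j, k in itertools.combinations(range(7), 3):
            sides = sorted([cop[i, j], cop[i, k], cop[j, k]])
            assert sides[1] == pytest.approx(sides[2])

    def test_matches_independent_pearson(self):
        rng = np.random.default_rng(8)
        d = random_distance(rng, 3)
        t = upgma(d)
        cop = t.cophenetic()
        pairs = [(0, 1), (0, 2), (1, 2)]
        x = np.array([d.values[i, j] for i, j in pairs])
        y = np.array([cop[i, j] for i, j in pairs])
        expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert cophenetic_correlation(d, t) == pytest.approx(expected, abs=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        d = random_distance(rng, 6)
        t = upgma(d)
        perm = rng.permutation(6)
        d2 = DistanceMatrix(
            [d.ids[i] for i in perm], d.values[np.ix_(perm, perm)], "t", {}
        )
        assert cophenetic_correlation(d2, t) == pytest.approx(
            cophenetic_correlation(d, t)
        )


class TestCutTree:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(10)
        t = upgma(random_distance(rng, 6))
        assert set(cut_tree(t, 1).values()) == {0}
        assert sorted(cut_tree(t, 6).values()) == list(range(6))

    def test_out_of_range(self):
        rng = np.random.default_rng(10)
        t = upgma(random_distance(rng, 4))
        with pytest.raises(DataError):
            cut_tree(t, 0)
        with pytest.raises(DataError):
            cut_tree(t, 5)

    def test_partition_invariant_to_input_permutation(self):
        rng = np.random.default_rng(12)
        d = random_distance(rng, 8)
        part1 = cut_tree(upgma(d), 3)
        perm = rng.permutation(8)
        d2 = DistanceMatrix(
            [d.ids[i] for i in perm], d.values[np.ix_(perm, perm)], "t", {}
        )
        part2 = cut_tree(upgma(d2), 3)
        # same partition up to cluster relabeling
        groups1 = {}
        groups2 = {}
        for lab in d.ids:
            groups1.setdefault(part1[lab], set()).add(lab)
            groups2.setdefault(part2[lab], set()).add(lab)
        assert {frozenset(s) for s in groups1.values()} == {
            frozenset(s) for s in groups2.values()
        }
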