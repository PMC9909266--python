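import itertools

import numpy as np
import pytest

from germdiv import Dendrogram, entanglement, matched_leaves, untangle, upgma
from germdiv.distances import DistanceMatrix
from germdiv.errors import LabelMismatchError


def random_tree(rng, n):
    x = rng.random((n, 3))
    v = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    d = DistanceMatrix([chr(65 + i) for i in range(n)], v, "t", {})
    return upgma(d)


def restarted_step2side(t1, t2, n_restarts=10):
    """Best entanglement from step2side run from random rotation starts."""
    best = untangle(t1, t2, method="step2side").entanglement
    for s in range(n_restarts):
        rng = np.random.default_rng(s)
        r1, r2 = t1, t2
        for node in range(t1.n_leaves, t1.root + 1):
            if rng.random() < 0.5:
                r1 = r1.flip(node)
        for node in range(t2.n_leaves, t2.root + 1):
            if rng.random() < 0.5:
                r2 = r2.flip(node)
        best = min(best, untangle(r1, r2, method="step2side").entanglement)
    return best


def all_rotations(t: Dendrogram):
    """Every displayed leaf order reachable by flipping internal nodes."""
    n = t.n_leaves
    for mask in range(2 ** (n - 1)):
        merges = []
        for k, (a, b, h) in enumerate(t.merges):
            merges.append((b, a, h) if (mask >> k) & 1 else (a, b, h))
        yield Dendrogram(t.labels, tuple(merges))


class TestEntanglement:
    def test_identical_orders(self):
        assert entanglement(list("ABCD"), list("ABCD")) == 0.0

    def test_full_reversal_is_worst_case(self):
        for m in (2, 3, 5, 8):
            order = [str(i) for i in range(m)]
            assert entanglement(order, order[::-1]) == pytest.approx(1.0)

    def test_three_leaf_value(self):
        e = entanglement(["A", "B", "C"], ["B", "A", "C"], L=1.5)
        assert e == pytest.approx(2 / (2 * 2**1.5), abs=1e-9)

    def test_symmetry_and_relabeling(self):
        rng = np.random.default_rng(0)
        order1 = [f"x{i}" for i in range(7)]
        order2 = list(rng.permutation(order1))
        assert entanglement(order1, order2) == pytest.approx(
            entanglement(order2, order1)
        )
        rename = {lab: f"y{i}" for i, lab in enumerate(order1)}
        assert entanglement(
            [rename[x] for x in order1], [rename[x] for x in order2]
        ) == pytest.approx(entanglement(order1, order2))

    def test_zero_iff_identical(self):
        rng = np.random.default_rng(1)
        labels = [f"x{i}" for i in range(6)]
        for _ in range(20):
            other = list(rng.permutation(labels))
            e = entanglement(labels, other)
            assert (e == 0.0) == (other == labels)

    def test_label_mismatch_rejected(self):
        with pytest.raises(LabelMismatchError):
            entanglement(["A", "B"], ["A", "C"])


class TestUntangle:
    def test_single_flip_recovered(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            t1 = random_tree(rng, 5)
            node = int(rng.integers(t1.n_leaves, t1.root + 1))
            t2 = t1.flip(node)
            res = untangle(t1, t2, method="step1side")
            assert res.entanglement == pytest.approx(0.0)

    def test_identical_trees_noop(self):
        rng = np.random.default_rng(3)
        t = random_tree(rng, 6)
        res = untangle(t, t, method="step2side")
        assert res.entanglement == 0.0
        assert res.order1 == res.order2 == t.leaf_order()

    @pytest.mark.parametrize("method", ["step1side", "step2side", "random"])
    def test_never_increases(self, method):
        rng = np.random.default_rng(4)
        for _ in range(8):
            t1, t2 = random_tree(rng, 7), random_tree(rng, 7)
            before = entanglement(t1.leaf_order(), t2.leaf_order())
            res = untangle(t1, t2, method=method, seed=0)
            assert res.entanglement <= before + 1e-12

    def test_idempotent_after_convergence(self):
        rng = np.random.default_rng(5)
        t1, t2 = random_tree(rng, 8), random_tree(rng, 8)
        res = untangle(t1, t2, method="step2side")
        again = untangle(res.tree1, res.tree2, method="step2side")
        assert again.entanglement == pytest.approx(res.entanglement)
        assert again.order1 == res.order1 and again.order2 == res.order2

    def test_restarted_step2side_finds_exhaustive_minimum(self):
        """Best-of-restarts greedy matches full 2^(n-1) x 2^(n-1) search, n <= 6."""
        rng = np.random.default_rng(6)
        for _ in range(6):
            n = int(rng.integers(4, 7))
            t1, t2 = random_tree(rng, n), random_tree(rng, n)
            exact = min(
                entanglement(r1.leaf_order(), r2.leaf_order())
                for r1 in all_rotations(t1)
                for r2 in all_rotations(t2)
            )
            best = restarted_step2side(t1, t2)
            assert best == pytest.approx(exact, abs=1e-9)


class TestMatchedLeaves:
    def test_identical_trees_all_matched(self):
        rng = np.random.default_rng(7)
        t = random_tree(rng, 6)
        assert matched_leaves(t, t, 3) == set(t.labels)

    def test_k_one_all_matched(self):
        rng = np.random.default_rng(8)
        t1, t2 = random_tree(rng, 5), random_tree(rng, 5)
        assert matched_leaves(t1, t2, 1) == set(t1.labels)

    def test_partial_agreement(self):
        # trees whose 2-cuts are {A,B|C,D} vs {A,B,C|D}: Hungarian matching
        # pairs {A,B}<->{A,B,C} and {C,D}<->{D}, so A, B and D agree
        t1 = Dendrogram(("A", "B", "C", "D"),
                        ((0, 1, 1.0), (2, 3, 1.5), (4, 5, 4.0)))
        t2 = Dendrogram(("A", "B", "C", "D"),
                        ((0, 1, 1.0), (4, 2, 2.0), (5, 3, 4.0)))
        assert matched_leaves(t1, t2, 2) == {"A", "B", "D"}
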