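"""Tanglegram comparison of two dendrograms over the same genotypes.

A tanglegram draws two trees face to face and connects equal leaves. The
entanglement coefficient measures how crossed the connecting lines are:
with u_l, v_l the 1-based positions of leaf l in the two displayed
orders, and exponent L,

    entanglement = sum_l |u_l - v_l|^L / sum_i |i - (m + 1 - i)|^L,

normalised by the worst case (one order fully reversed), so 0 means the
orders coincide and 1 means maximal disorder. L = 1.5 is the dendextend
default and is used here.

Because a dendrogram's topology fixes only the nesting, not the
left/right order of children, each internal node can be flipped freely.
``untangle`` searches over such rotations:

* ``step1side`` — hold tree 1 fixed; sweep tree 2's internal nodes from
  the root down, accepting a flip only if entanglement strictly
  decreases; repeat sweeps until one passes with no change.
* ``step2side`` — alternate one-sided passes on each tree to convergence.
* ``random`` — seeded random rotation assignments, keeping the best of
  the initial state and all draws.

``matched_leaves`` reports which genotypes keep the same cluster
membership when both trees are cut at k, matching the two partitions by
maximal overlap (Hungarian assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clustering import cut_tree
from .errors import ConfigError, LabelMismatchError
from .tree import Dendrogram

__all__ = ["entanglement", "untangle", "matched_leaves", "TanglegramResult"]


def entanglement(order1, order2, L: float = 1.5) -> float:
    """Normalised leaf-rank discrepancy between two leaf orders."""
    order1, order2 = list(order1), list(order2)
    m = len(order1)
    if m < 2:
        raise LabelMismatchError("need >= 2 leaves")
    if set(order1) != set(order2) or len(set(order1)) != m:
        raise LabelMismatchError("leaf orders are not permutations of one label set")
    pos2 = {lab: i + 1 for i, lab in enumerate(order2)}
    num = sum(abs((i + 1) - pos2[lab]) ** L for i, lab in enumerate(order1))
    den = sum(abs((i + 1) - (m - i)) ** L for i in range(m))
    return num / den


@dataclass
class TanglegramResult:
    entanglement: float
    L: float
    order1: list[str]
    order2: list[str]
    tree1: Dendrogram
    tree2: Dendrogram
    method: str
    #: per-leaf (rank in tree 1, rank in tree 2), 1-based
    leaf_ranks: dict[str, tuple[int, int]] = field(default_factory=dict)
    matched: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "entanglement": self.entanglement,
            "L": self.L,
            "method": self.method,
            "order1": self.order1,
            "order2": self.order2,
            "leaf_ranks": {k: list(v) for k, v in self.leaf_ranks.items()},
            "matched_leaves": sorted(self.matched),
        }


def _check_labels(t1: Dendrogram, t2: Dendrogram) -> None:
    if set(t1.labels) != set(t2.labels):
        raise LabelMismatchError("trees do not share one label set")


def _sweep_one_side(fixed_order, moving: Dendrogram, L: float) -> tuple[Dendrogram, bool]:
    """One root-to-leaf pass of greedy flips; returns (tree, changed)."""
    changed = False
    current = entanglement(fixed_order, moving.leaf_order(), L)
    # root-to-leaf = decreasing height = reversed merge order
    for node in range(moving.root, moving.n_leaves - 1, -1):
        cand = moving.flip(node)
        e = entanglement(fixed_order, cand.leaf_order(), L)
        if e < current:
            moving, current, changed = cand, e, True
    return moving, changed


def _step1side(t1: Dendrogram, t2: Dendrogram, L: float) -> tuple[Dendrogram, Dendrogram]:
    fixed = t1.leaf_order()
    while True:
        t2, changed = _sweep_one_side(fixed, t2, L)
        if not changed:
            return t1, t2


def _step2side(t1: Dendrogram, t2: Dendrogram, L: float) -> tuple[Dendrogram, Dendrogram]:
    while True:
        t1_new, c1 = _sweep_one_side(t2.leaf_order(), t1, L)
        t1 = t1_new
        t2_new, c2 = _sweep_one_side(t1.leaf_order(), t2, L)
        t2 = t2_new
        if not (c1 or c2):
            return t1, t2


def _random_rotation(t: Dendrogram, rng: np.random.Generator) -> Dendrogram:
    merges = []
    for a, b, h in t.merges:
        merges.append((b, a, h) if rng.random() < 0.5 else (a, b, h))
    return Dendrogram(t.labels, tuple(merges))


def untangle(
    t1: Dendrogram,
    t2: Dendrogram,
    method: str = "step2side",
    L: float = 1.5,
    seed: int | None = None,
    n_random: int = 100,
    k: int | None = None,
) -> TanglegramResult:
    """Rotate the trees' internal nodes to minimise entanglement.

    The result's entanglement never exceeds the initial one. When ``k``
    is given the matched-leaf set at that cut is included.
    """
    _check_labels(t1, t2)
    initial = entanglement(t1.leaf_order(), t2.leaf_order(), L)
    if method == "step1side":
        r1, r2 = _step1side(t1, t2, L)
    elif method == "step2side":
        r1, r2 = _step2side(t1, t2, L)
    elif method == "random":
        rng = np.random.default_rng(seed)
        best = (initial, t1, t2)
        for _ in range(n_random):
            c1 = _random_rotation(t1, rng)
            c2 = _random_rotation(t2, rng)
            e = entanglement(c1.leaf_order(), c2.leaf_order(), L)
            if e < best[0]:
                best = (e, c1, c2)
        _, r1, r2 = best
    else:
        raise ConfigError(f"unknown untangle method {method!r}")
    o1, o2 = r1.leaf_order(), r2.leaf_order()
    final = entanglement(o1, o2, L)
    if final > initial + 1e-12:  # greedy methods only ever accept improvements
        r1, r2, o1, o2, final = t1, t2, t1.leaf_order(), t2.leaf_order(), initial
    pos2 = {lab: i + 1 for i, lab in enumerate(o2)}
    ranks = {lab: (i + 1, pos2[lab]) for i, lab in enumerate(o1)}
    matched = matched_leaves(r1, r2, k) if k is not None else set()
    return TanglegramResult(
        entanglement=final,
        L=L,
        order1=o1,
        order2=o2,
        tree1=r1,
        tree2=r2,
        method=method,
        leaf_ranks=ranks,
        matched=matched,
    )


def matched_leaves(t1: Dendrogram, t2: Dendrogram, k: int) -> set[str]:
    """Leaves whose k-cluster membership agrees between the two trees.

    The two partitions' cluster numberings are arbitrary, so clusters are
    first matched by maximising total overlap (Hungarian assignment);
    a leaf is matched when its tree-2 cluster is the one assigned to its
    tree-1 cluster.
    """
    _check_labels(t1, t2)
    c1 = cut_tree(t1, k)
    c2 = cut_tree(t2, k)
    k1 = max(c1.values()) + 1
    k2 = max(c2.values()) + 1
    overlap = np.zeros((k1, k2))
    for lab in t1.labels:
        overlap[c1[lab], c2[lab]] += 1
    rows, cols = linear_sum_assignment(-overlap)
    mapping = dict(zip(rows, cols))
    return {lab for lab in t1.labels if mapping.get(c1[lab]) == c2[lab]}
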