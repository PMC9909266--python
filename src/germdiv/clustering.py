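"""UPGMA hierarchical clustering with cophenetic validation.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly
merges the two clusters with the smallest average pairwise distance; the
distance from the merged cluster to any other is the size-weighted mean
of its parts, so it always equals the plain average over all member
pairs. Merge heights are the raw merge distances (hclust convention),
which keeps cophenetic distances on the input scale.

Determinism: ties on the minimal distance are broken by the
lexicographically smallest pair of cluster keys, a cluster's key being
its lexicographically smallest leaf label; within a merge the cluster
with the smaller key becomes the left child.

The cophenetic correlation coefficient — the Pearson correlation between
the input distances and the tree-implied (cophenetic) distances over all
leaf pairs — measures how faithfully the dendrogram represents the
matrix; r = 1 exactly when the input is already ultrametric.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError, LabelMismatchError, UndefinedCorrelationError
from .distances import DistanceMatrix
from .tree import Dendrogram

__all__ = ["upgma", "cophenetic_matrix", "cophenetic_correlation", "cut_tree"]


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Build the UPGMA dendrogram for a distance matrix."""
    n = d.n
    if n < 2:
        raise DataError("need >= 2 units to cluster")
    if np.isnan(d.values).any():
        raise DataError("distance matrix contains NaN")
    labels = tuple(d.ids)

    # active clusters: id -> (key label, size); distances in a dict
    key = {i: labels[i] for i in range(n)}
    size = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.values[i, j])

    def pair_rank(i: int, j: int):
        a, b = sorted((key[i], key[j]))
        return (a, b)

    merges = []
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), v in dist.items():
            cand = (v, pair_rank(i, j), (i, j))
            if best is None or cand[:2] < best[:2]:
                best = cand
        v, _, (i, j) = best
        left, right = (i, j) if key[i] <= key[j] else (j, i)
        merges.append((left, right, v))
        new = next_id
        next_id += 1
        ni, nj = size[i], size[j]
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(new, k), max(new, k))] = (ni * dik + nj * djk) / (ni + nj)
        del dist[(min(i, j), max(i, j))]
        active.discard(i)
        active.discard(j)
        active.add(new)
        key[new] = min(key[i], key[j])
        size[new] = ni + nj
    return Dendrogram(labels, tuple(merges))


def cophenetic_matrix(t: Dendrogram) -> DistanceMatrix:
    """Tree-implied distances: (i, j) -> height of their lowest common merge."""
    return DistanceMatrix(list(t.labels), t.cophenetic(), "cophenetic", {})


def cophenetic_correlation(d: DistanceMatrix, t: Dendrogram) -> float:
    """Pearson r between input and cophenetic distances over leaf pairs."""
    if set(d.ids) != set(t.labels):
        raise LabelMismatchError("distance matrix and tree label sets differ")
    order = [d.ids.index(lab) for lab in t.labels]
    obs = d.values[np.ix_(order, order)]
    cop = t.cophenetic()
    iu = np.triu_indices(len(t.labels), k=1)
    x, y = obs[iu], cop[iu]
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError(
            "cophenetic correlation undefined for constant distance vectors"
        )
    return float(np.corrcoef(x, y)[0, 1])


def cut_tree(t: Dendrogram, k: int) -> dict[str, int]:
    """Cut into k clusters by removing the k-1 highest merges.

    Returns label -> cluster number; clusters are numbered 0..k-1 by the
    first appearance of one of their leaves in label order.
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise DataError(f"k={k} out of range [1, {n}]")
    parent = list(range(n + len(t.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (a, b, _) in enumerate(t.merges[: n - k]):
        new = n + idx
        parent[find(a)] = new
        parent[find(b)] = new

    assignment: dict[str, int] = {}
    root_number: dict[int, int] = {}
    for i, lab in enumerate(t.labels):
        r = find(i)
        if r not in root_number:
            root_number[r] = len(root_number)
        assignment[lab] = root_number[r]
    return assignment
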