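"""Rooted binary merge trees (dendrograms) with heights and leaf order.

A :class:`Dendrogram` follows the hclust/scipy linkage convention: leaves
are clusters ``0..n-1`` in label order, and the k-th merge creates cluster
``n+k`` from two existing clusters at a given height. Merge heights are
nondecreasing (guaranteed by UPGMA, required here), so the tree is
ultrametric: the cophenetic distance between two leaves is the height of
the lowest merge joining them, and a node drawn at height h sits at
ultrametric depth h/2 from the leaves.

The *displayed* leaf order is the left-to-right traversal order and is
part of the object's state: each internal node stores its children as an
ordered pair, and flipping a node swaps them without changing the
topology. Tanglegram untangling works entirely through such flips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError


@dataclass(frozen=True)
class Dendrogram:
    labels: tuple[str, ...]
    #: (left child id, right child id, height) per merge; new cluster n+k
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise FormatError("a dendrogram needs at least 2 leaves")
        if len(set(self.labels)) != n:
            raise FormatError("duplicate leaf labels")
        if len(self.merges) != n - 1:
            raise FormatError(
                f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}"
            )
        seen: set[int] = set()
        prev_h = 0.0
        for k, (a, b, h) in enumerate(self.merges):
            for c in (a, b):
                if not 0 <= c < n + k:
                    raise FormatError(f"merge {k}: child {c} not yet defined")
                if c in seen:
                    raise FormatError(f"merge {k}: cluster {c} used twice")
                seen.add(c)
            if h < prev_h - 1e-9:
                raise FormatError(
                    f"merge heights decrease at step {k}: {h} < {prev_h}"
                )
            prev_h = max(prev_h, h)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def children(self, node: int) -> tuple[int, int]:
        return self.merges[node - self.n_leaves][:2]

    def height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return self.merges[node - self.n_leaves][2]

    def leaves_under(self, node: int) -> list[int]:
        """Leaf indices below ``node`` in displayed order."""
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                a, b = self.children(v)
                stack.extend((b, a))  # left child explored first
        return out

    def leaf_order(self) -> list[str]:
        """Displayed leaf labels, left to right."""
        return [self.labels[i] for i in self.leaves_under(self.root)]

    def flip(self, node: int) -> "Dendrogram":
        """Return a copy with ``node``'s children swapped (same topology)."""
        if not self.n_leaves <= node <= self.root:
            raise FormatError(f"{node} is not an internal node")
        k = node - self.n_leaves
        a, b, h = self.merges[k]
        merges = list(self.merges)
        merges[k] = (b, a, h)
        return Dendrogram(self.labels, tuple(merges))

    def with_leaf_order_of(self) -> list[int]:
        return self.leaves_under(self.root)

    def cophenetic(self) -> np.ndarray:
        """Full n x n cophenetic distance matrix in label order."""
        n = self.n_leaves
        out = np.zeros((n, n))
        for a, b, h in self.merges:
            left = self.leaves_under(a)
            right = self.leaves_under(b)
            for i in left:
                out[i, right] = h
            for j in right:
                out[j, left] = h
        return out

    def to_linkage(self) -> np.ndarray:
        """Scipy-style linkage matrix (counts in the 4th column)."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        rows = []
        for k, (a, b, h) in enumerate(self.merges):
            sizes[n + k] = sizes[a] + sizes[b]
            rows.append([a, b, h, sizes[n + k]])
        return np.asarray(rows, dtype=float)
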