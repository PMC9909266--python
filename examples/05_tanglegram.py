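"""Tanglegram comparison of marker- and trait-based dendrograms.

Two dendrograms over the same genotypes are compared by entanglement:
the normalised rank discrepancy of their displayed leaf orders (0 =
perfectly aligned, 1 = one order is the reverse of the other). Because
leaf order is free up to flips of internal nodes, the trees are first
untangled (step2side greedy rotation search). Trees from the same panel
share latent group structure, so they untangle much better than trees
from two unrelated panels — compare the two results printed below.
"""

from germdiv import (
    PanelConfig,
    binary_distance,
    entanglement,
    gower_distance,
    simulate_panel,
    untangle,
    upgma,
)

panel = simulate_panel(PanelConfig(seed=11))
t_marker = upgma(binary_distance(panel.band_matrix))
t_trait = upgma(gower_distance(panel.trait_table))

before = entanglement(t_marker.leaf_order(), t_trait.leaf_order())
res = untangle(t_marker, t_trait, method="step2side", k=4)
print(f"same panel:      entanglement {before:.3f} -> {res.entanglement:.3f} "
      f"after untangling; {len(res.matched)}/32 leaves keep their "
      "k=4 cluster across trees")

unrelated = simulate_panel(PanelConfig(seed=99999))
t_other = upgma(gower_distance(unrelated.trait_table))
res2 = untangle(t_marker, t_other, method="step2side", k=4)
print(f"unrelated panel: entanglement -> {res2.entanglement:.3f} "
      f"after untangling; {len(res2.matched)}/32 matched leaves")
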