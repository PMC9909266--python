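"""UPGMA clustering of a germplasm panel with cophenetic validation.

Builds simple-matching distances from the marker layer and Gower
distances from the mixed trait layer, clusters each with UPGMA, and
reports the cophenetic correlation r — the Pearson correlation between
the input distances and the tree-implied distances. r close to 1 means
the dendrogram is a faithful summary of the distance matrix. The marker
tree is also written as a Newick file.
"""

import io

from germdiv import (
    PanelConfig,
    binary_distance,
    cophenetic_correlation,
    cut_tree,
    gower_distance,
    simulate_panel,
    upgma,
    write_newick,
)

panel = simulate_panel(PanelConfig(seed=11))

d_marker = binary_distance(panel.band_matrix, method="simple-matching")
d_trait = gower_distance(panel.trait_table)

for name, d in (("marker", d_marker), ("trait", d_trait)):
    tree = upgma(d)
    r = cophenetic_correlation(d, tree)
    clusters = cut_tree(tree, 4)
    sizes = sorted(list(clusters.values()).count(c)
                   for c in set(clusters.values()))
    print(f"{name:>6} layer: cophenetic r = {r:.3f}, "
          f"cluster sizes at k=4: {sizes}")

buf = io.StringIO()
write_newick(upgma(d_marker), buf)
print("\nMarker tree (Newick, truncated):")
print(buf.getvalue()[:120] + "...")
print("\nThe true simulated groups have 8 genotypes each; sizes close to")
print("[8, 8, 8, 8] mean the cut recovered the latent structure.")
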