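"""PCA of the mixed morphological trait table.

Qualitative traits are ordinal-coded by their declared level order, the
matrix is standardized, and the correlation matrix eigendecomposed.
The Kaiser rule keeps components with eigenvalue > 1 (more variance
than a single variable); the contribution table shows which traits
drive each component.
"""

from germdiv import PanelConfig, pca, select_components, simulate_panel

panel = simulate_panel(PanelConfig(seed=11))
encoded = panel.trait_table.ordinal_encoded()
res = pca(encoded, standardize=True)

k = select_components(res, rule="kaiser")
print(f"{encoded.shape[1]} variables -> {k} components with eigenvalue > 1")
print("eigenvalue  explained%  cumulative%")
for j in range(k):
    print(f"{res.eigenvalues[j]:10.2f}  {res.explained[j]:9.2f}  "
          f"{res.cumulative[j]:10.2f}")

top = res.contributions["PC1"].sort_values(ascending=False).head(5)
print("\nTop trait contributions to PC1 (% of the component):")
print(top.round(2).to_string())
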