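"""Dominant-marker informativeness statistics on a synthetic panel.

Simulates a 32-genotype panel fingerprinted with a SCoT-like 12-primer
set, then computes per-primer polymorphism (PB, %P), gene diversity H,
PIC, effective multiplex ratio E, marker index MI, discriminating power
DP and resolving power RP. High DP (near 1) means the primer's banding
patterns distinguish almost every genotype pair; MI balances per-band
informativeness against the number of polymorphic bands.
"""

from germdiv import PanelConfig, panel_summary, simulate_panel
from germdiv.ref_panels import scot_panel

panel = simulate_panel(PanelConfig(seed=11))
summary = panel_summary(panel.band_matrix)

print("Per-primer statistics (first 5 primers):")
cols = ["n_bands", "polymorphic_bands", "percent_polymorphic",
        "mean_PIC", "E", "MI", "DP", "RP"]
print(summary.per_primer[cols].head().round(3).to_string())

print(f"\nTotal bands: {summary.total_bands}, "
      f"polymorphic: {summary.total_polymorphic}")
print(f"Mean polymorphic bands per primer: "
      f"{summary.mean_polymorphic_per_primer:.1f}")
print(f"Pooled %P: {summary.pooled_percent_polymorphic:.1f}%   "
      f"mean of per-primer %P: {summary.averages['percent_polymorphic']:.1f}%")

print("\nGC content of the canonical SCoT primers:")
for rec in list(scot_panel())[:4]:
    print(f"  {rec.name}: {rec.sequence} -> {rec.gc_percent}%")
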