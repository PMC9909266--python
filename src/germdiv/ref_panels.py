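"""Canonical SRAP and SCoT fingerprinting primer panels.

SRAP (sequence-related amplified polymorphism) uses combinations of
"me" forward primers (CCGG-core) and "em" reverse primers (AATT-core);
SCoT (start codon targeted polymorphism) uses single 18-mers anchored on
the ATG translation-start context. The panels below are the primer sets
used for ornamental germplasm (Cyclamen) fingerprinting, with their
published GC contents (percent, one decimal) for validation of sequence
arithmetic.
"""

from __future__ import annotations

from .tables import PrimerPanel, PrimerRecord

#: (name, 5'->3' sequence, published GC %)
SRAP_FORWARD = [
    ("me1", "TGAGTCCAAACCGGATA", 47.1),
    ("me2", "TGAGTCCAAACCGGAGC", 58.8),
    ("me3", "TGAGTCCAAACCGGAAT", 47.1),
    ("me4", "TGAGTCCAAACCGGACC", 58.8),
    ("me5", "TGAGTCCAAACCGGAAG", 52.9),
    ("me6", "TGAGTCCAAACCGGACA", 52.9),
]

SRAP_REVERSE = [
    ("em1", "GACTGCGTACGAATTAAT", 38.9),
    ("em2", "GACTGCGTACGAATTTGC", 50.0),
    ("em3", "GACTGCGTACGAATTGAC", 50.0),
    ("em4", "GACTGCGTACGAATTTGA", 44.4),
    ("em6", "GACTGCGTACGAATTGCA", 50.0),
    ("ba1", "GTCGAGCTGCCAATTATA", 44.4),
]

SCOT = [
    ("SCoT 1", "CAACAATGGCTACCACCA", 50.0),
    ("SCoT 2", "CAACAATGGCTACCACCC", 55.6),
    ("SCoT 3", "CAACAATGGCTACCACCG", 55.6),
    ("SCoT 4", "CAACAATGGCTACCACCT", 50.0),
    ("SCoT 5", "CAACAATGGCTACCACGA", 50.0),
    ("SCoT 6", "CAACAATGGCTACCACGC", 55.6),
    ("SCoT 7", "CAACAATGGCTACCACGG", 55.6),
    ("SCoT 8", "CAACAATGGCTACCACGT", 50.0),
    ("SCoT 13", "ACGACATGGCGACCATCG", 61.1),
    ("SCoT 16", "ACCATGGCTACCACCGAC", 61.1),
    ("SCoT 30", "CCATGGCTACCACCGGCG", 72.2),
    ("SCoT 33", "CCATGGCTACCACCGCAG", 66.7),
]

#: published band counts for the two marker systems on the 32-genotype panel
SCOT_BAND_COUNTS = {"total": 204, "polymorphic": 169, "primers": 12}
SRAP_BAND_COUNTS = {"total": 349, "polymorphic": 264, "primers": 26}


def srap_panel() -> PrimerPanel:
    """All SRAP forward and reverse primers as one panel."""
    return PrimerPanel(
        [PrimerRecord(n, s, "SRAP forward") for n, s, _ in SRAP_FORWARD]
        + [PrimerRecord(n, s, "SRAP reverse") for n, s, _ in SRAP_REVERSE]
    )


def scot_panel() -> PrimerPanel:
    return PrimerPanel([PrimerRecord(n, s, "SCoT") for n, s, _ in SCOT])


def published_gc() -> dict[str, float]:
    """Primer name -> published GC percent, across all panels."""
    return {n: gc for n, _, gc in SRAP_FORWARD + SRAP_REVERSE + SCOT}
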