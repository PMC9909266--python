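"""Informativeness statistics for dominant (band presence/absence) markers.

For a dominant band with presence frequency p among non-missing genotypes
(the band is "biallelic": present vs absent), the per-band statistics are

* gene diversity        H  = 1 - p^2 - (1-p)^2 = 2p(1-p)          (max 0.5)
* polymorphic info.     PIC = 1 - (p^2 + q^2) - 2 p^2 q^2, q=1-p  (max 0.375)
* band informativeness  Ib = 1 - 2|0.5 - p|                        (max 1)

and per primer (n scored bands, PB polymorphic, N genotypes):

* percent polymorphism  %P = 100 PB / n
* effective multiplex   E  = PB * (PB / n)   (polymorphic fraction form
                             PB/n available via ``e_formula="fraction"``)
* marker index          MI = mean(PIC) * PB
* resolving power       RP = sum of Ib over the primer's bands
* discriminating power  DP = 1 - sum_i p_i (N p_i - 1) / (N - 1), where
  p_i are the relative frequencies of the distinct multi-band genotype
  profiles ("banding patterns") the primer produces. DP is the probability
  that two genotypes drawn without replacement show different patterns.

A band is polymorphic when both states occur among non-missing calls
(strict criterion); an optional 95% criterion additionally requires the
minor state above 5% frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateBandError, InsufficientDataError
from .tables import BandMatrix

__all__ = [
    "band_frequency",
    "gene_diversity_band",
    "pic_band",
    "band_informativeness",
    "is_polymorphic",
    "band_stats",
    "discriminating_power",
    "primer_summary",
    "panel_summary",
    "PrimerStats",
    "PanelSummary",
]


def band_frequency(calls: np.ndarray) -> float:
    """Presence frequency p = (#present) / (#non-missing) for one band."""
    calls = np.asarray(calls, dtype=float)
    mask = ~np.isnan(calls)
    if not mask.any():
        raise DegenerateBandError("band has no non-missing calls")
    return float(calls[mask].sum() / mask.sum())


def gene_diversity_band(p: float) -> float:
    """Two-state gene diversity H = 1 - p^2 - (1-p)^2 = 2p(1-p)."""
    return 2.0 * p * (1.0 - p)


def pic_band(p: float) -> float:
    """Botstein PIC for a biallelic dominant band."""
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def band_informativeness(p: float) -> float:
    """Ib = 1 - 2|0.5 - p|; peaks at p = 0.5, zero for fixed bands."""
    return 1.0 - 2.0 * abs(0.5 - p)


def is_polymorphic(p: float, criterion: str = "strict") -> bool:
    """Strict: both states observed. '95': minor state frequency > 5%."""
    if criterion == "strict":
        return 0.0 < p < 1.0
    if criterion == "95":
        return 0.05 < p < 0.95
    raise ValueError(f"unknown polymorphism criterion {criterion!r}")


def band_stats(m: BandMatrix, criterion: str = "strict") -> pd.DataFrame:
    """Per-band table: frequency, polymorphic flag, H, PIC, Ib."""
    rows = []
    for j, band in enumerate(m.band_ids):
        p = band_frequency(m.calls[:, j])
        rows.append(
            {
                "band": band,
                "primer": m.primer_of_band[band],
                "frequency": p,
                "polymorphic": is_polymorphic(p, criterion),
                "H": gene_diversity_band(p),
                "PIC": pic_band(p),
                "Ib": band_informativeness(p),
            }
        )
    return pd.DataFrame(rows).set_index("band")


def discriminating_power(primer_calls: np.ndarray) -> float:
    """DP of one primer from its genotypes x bands 0/1 sub-matrix.

    Genotypes with any missing call within the primer are excluded and N
    adjusted; at least two complete genotypes are required.
    """
    calls = np.asarray(primer_calls, dtype=float)
    complete = ~np.isnan(calls).any(axis=1)
    calls = calls[complete]
    N = calls.shape[0]
    if N < 2:
        raise InsufficientDataError(
            "discriminating power needs >= 2 genotypes without missing calls"
        )
    patterns: dict[tuple, int] = {}
    for row in calls:
        key = tuple(int(v) for v in row)
        patterns[key] = patterns.get(key, 0) + 1
    acc = 0.0
    for count in patterns.values():
        p_i = count / N
        acc += p_i * (N * p_i - 1.0) / (N - 1.0)
    return 1.0 - acc


@dataclass
class PrimerStats:
    primer: str
    n_bands: int
    polymorphic_bands: int
    percent_polymorphic: float
    mean_H: float
    mean_PIC: float
    E: float
    MI: float
    DP: float
    RP: float


def primer_summary(
    m: BandMatrix,
    primer: str,
    criterion: str = "strict",
    e_formula: str = "multiplex",
    mi_bands: str = "all",
) -> PrimerStats:
    """Summary statistics for one primer's bands.

    ``e_formula``: 'multiplex' -> E = PB*(PB/n); 'fraction' -> E = PB/n.
    ``mi_bands``: average PIC over 'all' scored bands (default) or only
    'polymorphic' ones before multiplying by PB.
    """
    bands = m.bands_of_primer(primer)
    if not bands:
        raise DegenerateBandError(f"primer {primer!r} owns no bands")
    cols = [m.band_ids.index(b) for b in bands]
    ps = [band_frequency(m.calls[:, j]) for j in cols]
    poly = [is_polymorphic(p, criterion) for p in ps]
    n = len(bands)
    pb = int(sum(poly))
    pics = [pic_band(p) for p in ps]
    hs = [gene_diversity_band(p) for p in ps]
    if mi_bands == "polymorphic":
        mi_pic = float(np.mean([pc for pc, f in zip(pics, poly) if f])) if pb else 0.0
    else:
        mi_pic = float(np.mean(pics))
    if e_formula == "multiplex":
        e = pb * (pb / n)
    elif e_formula == "fraction":
        e = pb / n
    else:
        raise ValueError(f"unknown e_formula {e_formula!r}")
    return PrimerStats(
        primer=primer,
        n_bands=n,
        polymorphic_bands=pb,
        percent_polymorphic=100.0 * pb / n,
        mean_H=float(np.mean(hs)),
        mean_PIC=float(np.mean(pics)),
        E=float(e),
        MI=mi_pic * pb,
        DP=discriminating_power(m.primer_calls(primer)),
        RP=float(sum(band_informativeness(p) for p in ps)),
    )


@dataclass
class PanelSummary:
    total_bands: int
    total_polymorphic: int
    per_primer: pd.DataFrame
    #: unweighted means of the per-primer columns
    averages: pd.Series
    #: pooled percent polymorphic = 100 * total_polymorphic / total_bands
    pooled_percent_polymorphic: float
    #: pooled mean polymorphic bands per primer = total_polymorphic / n_primers
    mean_polymorphic_per_primer: float


def panel_summary(
    m: BandMatrix,
    criterion: str = "strict",
    e_formula: str = "multiplex",
    mi_bands: str = "all",
) -> PanelSummary:
    """Whole-panel totals and per-primer averages.

    Percent-polymorphism is reported both as the unweighted mean of the
    per-primer percentages and as the pooled ratio of the totals; field
    summaries often mix the two, so both are labeled explicitly.
    """
    stats = [
        primer_summary(m, p, criterion=criterion, e_formula=e_formula, mi_bands=mi_bands)
        for p in m.primers
    ]
    per_primer = pd.DataFrame([vars(s) for s in stats]).set_index("primer")
    total = int(per_primer["n_bands"].sum())
    total_poly = int(per_primer["polymorphic_bands"].sum())
    return PanelSummary(
        total_bands=total,
        total_polymorphic=total_poly,
        per_primer=per_primer,
        averages=per_primer.mean(),
        pooled_percent_polymorphic=100.0 * total_poly / total,
        mean_polymorphic_per_primer=total_poly / len(stats),
    )
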