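"""Ecological diversity indices over per-genotype profiles.

Each genotype's nonnegative feature vector x (band calls, or min-max
scaled trait/color variables) is normalised to proportions p_i over its
S nonzero entries, and summarised by

* Shannon-Wiener  H' = -sum p_i ln p_i   (nats; max ln S at uniformity)
* Gini-Simpson    lambda = 1 - sum p_i^2 (max 1 - 1/S at uniformity)
* Pielou evenness J = H' / ln S          (defined for S >= 2)

Natural logarithms throughout, matching the vegan R package defaults.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["shannon", "simpson", "pielou", "diversity_table", "minmax_profile"]


def _proportions(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise DataError("abundance vector must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise DataError("empty profile: all abundances zero")
    p = x[x > 0] / total
    # entries can underflow to zero after normalisation; drop them again
    return p[p > 0]


def shannon(x) -> float:
    """Shannon-Wiener index H' in nats."""
    p = _proportions(x)
    return float(-(p * np.log(p)).sum())


def simpson(x) -> float:
    """Gini-Simpson index lambda = 1 - sum p_i^2."""
    p = _proportions(x)
    return float(1.0 - (p * p).sum())


def pielou(x) -> float:
    """Pielou evenness J = H' / ln S; requires >= 2 nonzero categories."""
    p = _proportions(x)
    s = len(p)
    if s < 2:
        raise DataError("evenness undefined for a single nonzero category")
    return float(-(p * np.log(p)).sum() / np.log(s))


def minmax_profile(df: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each column to [0, 1], making mixed data nonnegative.

    Constant columns scale to 0. This is the profile construction used for
    trait and color layers before computing diversity indices.
    """
    out = {}
    for col in df.columns:
        v = df[col].astype(float)
        rng = v.max() - v.min()
        out[col] = (v - v.min()) / rng if rng > 0 else v * 0.0
    return pd.DataFrame(out, index=df.index)


def diversity_table(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype diversity indices plus a min/median/max/average summary.

    Parameters
    ----------
    matrix : DataFrame
        Genotypes (rows) x nonnegative features. All-zero rows are flagged
        with a warning and excluded from the summary block.

    Returns
    -------
    (per_genotype, summary)
        ``per_genotype`` has columns S, shannon, simpson, pielou (pielou is
        NaN when S < 2); ``summary`` has rows min/median/max/average.
    """
    rows = []
    skipped = []
    for g in matrix.index:
        x = matrix.loc[g].to_numpy(dtype=float)
        if np.nansum(x) <= 0:
            skipped.append(g)
            rows.append({"genotype": g, "S": 0, "shannon": np.nan,
                         "simpson": np.nan, "pielou": np.nan})
            continue
        x = np.nan_to_num(x, nan=0.0)
        s = int((x > 0).sum())
        rows.append(
            {
                "genotype": g,
                "S": s,
                "shannon": shannon(x),
                "simpson": simpson(x),
                "pielou": pielou(x) if s >= 2 else np.nan,
            }
        )
    if skipped:
        warnings.warn(
            f"all-zero profiles excluded from summary: {skipped}", stacklevel=2
        )
    per = pd.DataFrame(rows).set_index("genotype")
    ok = per.dropna(subset=["shannon"])
    summary = pd.DataFrame(
        {
            "min": ok[["shannon", "simpson", "pielou"]].min(),
            "median": ok[["shannon", "simpson", "pielou"]].median(),
            "max": ok[["shannon", "simpson", "pielou"]].max(),
            "average": ok[["shannon", "simpson", "pielou"]].mean(),
        }
    ).T
    return per, summary
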