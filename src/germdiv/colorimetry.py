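"""Chroma and hue derivation from CIELab triplets.

CIELab expresses color as lightness L* (0 dark .. 100 light) and two
opponent axes, a* (green negative .. red positive) and b* (blue negative
.. yellow positive). The polar form adds

* chroma  C* = sqrt(a*^2 + b*^2)  — color intensity, distance from grey;
* hue angle H° = atan2(b*, a*) in degrees mapped to [0, 360) — the shade
  (0° red, 90° yellow, 180° green, 270° blue).

The naive single-argument arctan(b*/a*) printed in many protocols is
quadrant-ambiguous and undefined at a* = 0; the two-argument arctangent
is the colorimetric standard and is used throughout. At the achromatic
point a* = b* = 0 hue is undefined and reported as missing.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import AlignmentError, UndefinedHueError
from .tables import ColorTable

__all__ = ["chroma", "hue_angle", "derive_color_features", "color_feature_matrix"]


def chroma(a: float, b: float) -> float:
    """C* = sqrt(a*^2 + b*^2)."""
    return math.hypot(a, b)


def hue_angle(a: float, b: float) -> float:
    """H° = atan2(b*, a*) in degrees, mapped to [0, 360)."""
    if a == 0.0 and b == 0.0:
        raise UndefinedHueError("hue undefined at a*=b*=0 (achromatic)")
    return math.degrees(math.atan2(b, a)) % 360.0


def derive_color_features(table: ColorTable) -> ColorTable:
    """Return a copy of ``table`` with C* and H° columns filled in.

    Achromatic rows (a*=b*=0) get C*=0 and a missing hue, which downstream
    distances handle by pairwise exclusion.
    """
    df = table.data.copy()
    a = df["a"].astype(float).to_numpy()
    b = df["b"].astype(float).to_numpy()
    df["C"] = np.hypot(a, b)
    hue = np.degrees(np.arctan2(b, a)) % 360.0
    hue[(a == 0) & (b == 0)] = np.nan
    df["H"] = hue
    return ColorTable(df)


def color_feature_matrix(table: ColorTable) -> pd.DataFrame:
    """Wide genotype x (organ, channel) feature matrix for distances/PCA.

    Every genotype must be measured on the same organ regions; offenders
    are listed in the error. Columns are named ``organ.channel`` over
    channels L, a, b, C, H.
    """
    derived = derive_color_features(table)
    df = derived.data
    organs = derived.organs
    per_genotype = df.groupby("genotype")["organ"].apply(set)
    expected = set(organs)
    offenders = [g for g, s in per_genotype.items() if s != expected]
    if offenders:
        raise AlignmentError(
            f"organ regions inconsistent across genotypes; offenders: {offenders}"
        )
    wide = df.pivot(index="genotype", columns="organ", values=["L", "a", "b", "C", "H"])
    # order columns organ-major: slip.L, slip.a, ... per organ in table order
    cols = []
    for organ in organs:
        for ch in ("L", "a", "b", "C", "H"):
            cols.append((ch, organ))
    wide = wide[cols]
    wide.columns = [f"{organ}.{ch}" for ch, organ in cols]
    return wide.loc[derived.genotype_ids]
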