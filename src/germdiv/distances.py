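"""Dissimilarity matrices for the three data layers.

* Euclidean distance on (optionally z-scored) numeric matrices — the
  classical choice for quantitative traits and color features;
* Gower dissimilarity for mixed quantitative/qualitative trait tables:
  per-pair mean of range-normalised absolute differences (quantitative)
  and mismatch indicators (qualitative), with pairwise deletion of
  missing features;
* simple-matching and Jaccard distances for binary band matrices;
* Pearson correlation similarity between genotype profiles, with the
  associated 1 - r dissimilarity.

z-scoring uses the population standard deviation (divisor N) so results
are bit-reproducible and documented; constant features are dropped with
a warning rather than producing NaNs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .errors import (
    DataError,
    IncomparablePairError,
    UndefinedCorrelationError,
)
from .tables import QUALITATIVE, QUANTITATIVE, BandMatrix, TraitTable

__all__ = [
    "DistanceMatrix",
    "euclidean_distance",
    "gower_distance",
    "binary_distance",
    "pearson_similarity",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarity matrix with unit labels."""

    ids: list[str]
    values: np.ndarray
    metric: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DataError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if np.isnan(self.values).any():
            raise DataError("distance matrix contains NaN")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise DataError("negative distances")
        # exact symmetry/diagonal for downstream bit-reproducibility
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def _as_frame(matrix, ids=None) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    idx = ids if ids is not None else [f"u{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=idx)


def euclidean_distance(matrix, standardize: bool = True, ids=None) -> DistanceMatrix:
    """Pairwise Euclidean distance, optionally on z-scored features.

    Missing values are a hard error: silent imputation would quietly
    distort every downstream dendrogram, so callers must impute
    explicitly first.
    """
    df = _as_frame(matrix, ids)
    if df.shape[0] < 2:
        raise DataError("need >= 2 units")
    X = df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise DataError(
            "missing values present; impute explicitly before Euclidean distance"
        )
    dropped = []
    if standardize:
        sd = X.std(axis=0)  # population SD (divisor N)
        keep = sd > 0
        if not keep.all():
            dropped = [str(c) for c, k in zip(df.columns, keep) if not k]
            warnings.warn(
                f"constant features dropped under standardization: {dropped}",
                stacklevel=2,
            )
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        if X.shape[1] == 0:
            raise DataError("no non-constant features left to standardize")
    diff = X[:, None, :] - X[None, :, :]
    vals = np.sqrt((diff * diff).sum(axis=2))
    return DistanceMatrix(
        list(df.index),
        vals,
        "euclidean",
        {"standardized": standardize, "dropped_features": dropped},
    )


def gower_distance(traits: TraitTable) -> DistanceMatrix:
    """Gower dissimilarity on a mixed trait table.

    Quantitative features contribute |x - y| / range (range over observed
    non-missing values); qualitative features contribute 0/1 mismatch.
    Features missing in either member of a pair are excluded from both
    numerator and denominator; a pair with no comparable feature is an
    error. Quantitative features with zero range are skipped entirely.
    """
    ids = traits.genotype_ids
    n = len(ids)
    if n < 2:
        raise DataError("need >= 2 genotypes")
    parts = []  # (per-feature dissimilarity matrix, comparability mask)
    for var in traits.values.columns:
        col = traits.values[var]
        if traits.var_types[var] == QUANTITATIVE:
            v = col.to_numpy(dtype=float)
            obs = v[~np.isnan(v)]
            if obs.size == 0:
                continue
            rng = obs.max() - obs.min()
            if rng == 0:
                continue
            d = np.abs(v[:, None] - v[None, :]) / rng
            comp = ~np.isnan(v[:, None]) & ~np.isnan(v[None, :])
        else:
            raw = col.to_numpy(dtype=object)
            present = np.array([not pd.isna(x) for x in raw])
            eq = np.array(
                [[str(a) == str(b) for b in raw] for a in raw], dtype=float
            )
            d = 1.0 - eq
            comp = present[:, None] & present[None, :]
        parts.append((np.where(comp, d, 0.0), comp.astype(float)))
    if not parts:
        raise IncomparablePairError("no comparable features for any pair")
    num = sum(p[0] for p in parts)
    den = sum(p[1] for p in parts)
    if (den == 0).any():
        bad = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))
        if bad.size:
            i, j = bad[0]
            raise IncomparablePairError(
                f"genotypes {ids[i]!r} and {ids[j]!r} share no comparable feature"
            )
    vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(ids, vals, "gower", {"n_features": len(parts)})


def binary_distance(m: BandMatrix, method: str = "simple-matching") -> DistanceMatrix:
    """Simple-matching or Jaccard distance on a binary band matrix.

    Missing calls are excluded pairwise. Simple-matching distance is
    mismatches / compared bands; Jaccard distance is
    1 - (both present) / (either present), with identical all-absent
    profiles assigned distance 0.
    """
    if method not in ("simple-matching", "jaccard"):
        raise ValueError(f"unknown binary distance method {method!r}")
    X = m.calls
    n = m.n_genotypes
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ~np.isnan(X[i]) & ~np.isnan(X[j])
            if not comp.any():
                raise IncomparablePairError(
                    f"genotypes {m.genotype_ids[i]!r} and {m.genotype_ids[j]!r} "
                    "share no non-missing band"
                )
            xi, xj = X[i, comp], X[j, comp]
            if method == "simple-matching":
                d = float((xi != xj).mean())
            else:
                both = float(((xi == 1) & (xj == 1)).sum())
                either = float(((xi == 1) | (xj == 1)).sum())
                d = 0.0 if either == 0 else 1.0 - both / either
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(m.genotype_ids, vals, method, {"n_bands": m.n_bands})


def pearson_similarity(matrix, ids=None) -> tuple[pd.DataFrame, DistanceMatrix]:
    """Pearson correlation between unit profiles and the 1 - r distance.

    Returns the full similarity matrix as a DataFrame together with a
    DistanceMatrix on 1 - r (range [0, 2]). Constant profiles have no
    defined correlation and are reported by name.
    """
    df = _as_frame(matrix, ids)
    if df.shape[1] < 3:
        raise DataError("Pearson similarity needs >= 3 features")
    X = df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise DataError("missing values present; impute before correlation")
    sd = X.std(axis=1)
    flat = [str(u) for u, s in zip(df.index, sd) if s == 0]
    if flat:
        raise UndefinedCorrelationError(
            f"constant profiles have undefined correlation: {flat}"
        )
    r = np.corrcoef(X)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    sim = pd.DataFrame(r, index=df.index, columns=df.index)
    dist = DistanceMatrix(list(df.index), 1.0 - r, "pearson", {})
    return sim, dist
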