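"""Principal component analysis of standardized trait matrices.

PCA is computed by eigendecomposition of the correlation matrix
(``standardize=True``, the default, appropriate for variables on
different scales) or the covariance matrix. Both use the population
convention (divisor N). Scores are the standardized data projected on
the loadings, so scores x loadings' reconstructs the standardized data
exactly when all components are kept.

Sign convention: within each loading column the entry of largest
magnitude is made positive, which fixes the otherwise arbitrary
eigenvector signs for reproducible outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["PCAResult", "pca", "select_components"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    explained: np.ndarray  # percentages, sum to 100
    cumulative: np.ndarray
    loadings: pd.DataFrame  # variables x components, orthonormal columns
    scores: pd.DataFrame  # units x components
    contributions: pd.DataFrame  # percent contribution of each variable per PC
    standardized: bool

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca(matrix, standardize: bool = True, ids=None) -> PCAResult:
    """PCA of a units x variables numeric matrix.

    Constant variables cannot be standardized and are dropped with a
    warning; missing values are a hard error (impute first).
    """
    if isinstance(matrix, pd.DataFrame):
        df = matrix.astype(float)
    else:
        arr = np.asarray(matrix, dtype=float)
        idx = ids if ids is not None else [f"u{i}" for i in range(arr.shape[0])]
        df = pd.DataFrame(arr, index=idx)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise DataError("PCA needs >= 2 units and >= 2 variables")
    X = df.to_numpy()
    if np.isnan(X).any():
        raise DataError("missing values present; impute before PCA")
    sd = X.std(axis=0)
    keep = sd > 0
    if standardize and not keep.all():
        dropped = [str(c) for c, k in zip(df.columns, keep) if not k]
        warnings.warn(f"constant variables dropped: {dropped}", stacklevel=2)
        df = df.loc[:, keep]
        X, sd = X[:, keep], sd[keep]
    Xc = X - X.mean(axis=0)
    Z = Xc / sd if standardize else Xc
    C = (Z.T @ Z) / Z.shape[0]
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry positive per column
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    explained = 100.0 * evals / total
    comp_names = [f"PC{j + 1}" for j in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=df.columns, columns=comp_names)
    scores = pd.DataFrame(Z @ evecs, index=df.index, columns=comp_names)
    contributions = pd.DataFrame(
        100.0 * evecs**2, index=df.columns, columns=comp_names
    )
    return PCAResult(
        eigenvalues=evals,
        explained=explained,
        cumulative=np.cumsum(explained),
        loadings=loadings,
        scores=scores,
        contributions=contributions,
        standardized=standardize,
    )


def select_components(
    result: PCAResult, rule: str = "kaiser", threshold: float = 80.0
) -> int:
    """Number of components to retain.

    ``kaiser`` keeps eigenvalues > 1 (meaningful for correlation-matrix
    PCA, where an eigenvalue of 1 is one variable's worth of variance),
    never returning fewer than 1; ``cumulative`` keeps the smallest count
    whose cumulative explained variance reaches ``threshold`` percent.
    """
    if rule == "kaiser":
        k = int((result.eigenvalues > 1.0).sum())
        if k == 0:
            warnings.warn("no eigenvalue exceeds 1; keeping one component",
                          stacklevel=2)
            return 1
        return k
    if rule == "cumulative":
        reached = np.nonzero(result.cumulative >= threshold - 1e-12)[0]
        return int(reached[0]) + 1 if reached.size else result.n_components
    raise ValueError(f"unknown selection rule {rule!r}")
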