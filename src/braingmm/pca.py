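"""Covariance-based PCA on the mixture feature matrix, plus feature correlation.

The d x d sample covariance C of an n x d feature matrix is
eigendecomposed, C V = V Lambda; eigenvectors are ranked by descending
eigenvalue and the leading n_retained (default 3) form the projection
basis.  Rows are centered by the basis's mean vector before projection
(a ``center=False`` mode projects raw rows for the literal textbook
construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .gmm import FeatureMatrix

__all__ = [
    "PCAModel",
    "ProjectedFeatures",
    "covariance_matrix",
    "fit_pca",
    "project",
    "feature_correlation",
]


def _as_array(Rt) -> np.ndarray:
    if isinstance(Rt, FeatureMatrix):
        return Rt.values
    return np.asarray(Rt, dtype=float)


def covariance_matrix(Rt) -> np.ndarray:
    """Sample covariance (denominator n-1) of the rows of an n x d matrix."""
    X = _as_array(Rt)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for a covariance")
    return np.cov(X, rowvar=False, ddof=1)


@dataclass
class PCAModel:
    """Eigenbasis of a feature covariance matrix.

    eigenvalues are descending; eigenvectors are orthonormal columns with a
    deterministic sign (largest-magnitude entry positive).
    """

    mean_vector: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_retained: int
    cumulative_variance_fraction: float
    center: bool = True

    @property
    def components(self) -> np.ndarray:
        """Retained eigenvector block, d x n_retained."""
        return self.eigenvectors[:, : self.n_retained]

    @classmethod
    def from_feature_matrix(cls, Rt, n_retained: Optional[int] = 3,
                            variance_fraction: Optional[float] = None,
                            center: bool = True) -> "PCAModel":
        X = _as_array(Rt)
        C = covariance_matrix(X)
        return fit_pca(C, n_retained=n_retained, variance_fraction=variance_fraction,
                       mean_vector=X.mean(axis=0), center=center)

    def to_dict(self) -> dict:
        return {
            "mean_vector": self.mean_vector.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "n_retained": int(self.n_retained),
            "cumulative_variance_fraction": float(self.cumulative_variance_fraction),
            "center": bool(self.center),
        }


@dataclass
class ProjectedFeatures:
    rows: np.ndarray
    source_basis: PCAModel

    @property
    def shape(self):
        return self.rows.shape


def fit_pca(
    C,
    n_retained: Optional[int] = 3,
    variance_fraction: Optional[float] = None,
    mean_vector=None,
    center: bool = True,
    sym_tol: float = 1e-8,
) -> PCAModel:
    """Eigendecompose a symmetric covariance matrix.

    Retains either a fixed number of components (default 3) or, if
    ``variance_fraction`` is given, the smallest k whose cumulative
    eigenvalue share reaches that fraction.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be square")
    scale = max(np.abs(C).max(), 1.0)
    if np.abs(C - C.T).max() > sym_tol * scale:
        raise ValueError("covariance matrix is not symmetric")
    d = C.shape[0]
    evals, evecs = np.linalg.eigh(0.5 * (C + C.T))
    order = np.argsort(-evals, kind="stable")
    evals = evals[order]
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(d):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]

    total = evals.sum()
    if variance_fraction is not None:
        cum = np.cumsum(evals) / total if total > 0 else np.ones(d)
        k = int(np.searchsorted(cum, variance_fraction) + 1)
        k = min(k, d)
    else:
        if n_retained is None:
            n_retained = 3
        if not (1 <= n_retained <= d):
            raise ValueError("n_retained must be in [1, d]")
        k = int(n_retained)
    cvf = float(evals[:k].sum() / total) if total > 0 else 1.0
    if mean_vector is None:
        mean_vector = np.zeros(d)
    return PCAModel(
        mean_vector=np.asarray(mean_vector, dtype=float),
        eigenvalues=evals,
        eigenvectors=evecs,
        n_retained=k,
        cumulative_variance_fraction=cvf,
        center=center,
    )


def project(Rt, model: PCAModel) -> ProjectedFeatures:
    """Project rows onto the retained eigenvectors (after mean-centering)."""
    X = _as_array(Rt)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.eigenvectors.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model dimension "
            f"{model.eigenvectors.shape[0]}"
        )
    Xc = X - model.mean_vector if model.center else X
    return ProjectedFeatures(rows=Xc @ model.components, source_basis=model)


def feature_correlation(Rt, feature_names=None) -> pd.DataFrame:
    """Pearson correlation between feature columns.

    Zero-variance columns have no defined correlation; their entries are
    reported as NaN (flagged missing), with the diagonal kept at 1.
    """
    X = _as_array(Rt)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    if feature_names is None and isinstance(Rt, FeatureMatrix):
        feature_names = Rt.feature_names
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    zero_var = X.std(axis=0) == 0
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    np.fill_diagonal(corr, 1.0)
    names = feature_names or [f"f{i + 1}" for i in range(X.shape[1])]
    return pd.DataFrame(corr, index=names, columns=names)
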