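"""Univariate Gaussian mixture fitting and the 9-element intensity feature vector.

The central statistic of the package: the intensity distribution of a
segmented region (tumor or normal brain) is modelled as a K-component
Gaussian mixture

    p(x | lambda) = sum_i w_i N(x; mu_i, v_i),   lambda = {w_i, mu_i, v_i},

fitted by maximum-likelihood EM.  For the default K = 3 the fitted
parameters are concatenated into the feature vector

    R = [w_1..w_3, mu_1..mu_3, v_1..v_3]

(components ordered by ascending mean), and n regions stack into an
n x 3K feature matrix used downstream by PCA and the classifiers.

The model is exposed statsmodels-style: build :class:`IntensityMixtureModel`
from raw intensities or an :class:`~braingmm.segment.IntensityHistogram`,
call ``fit()`` and get an :class:`IntensityMixtureResults` carrying the
estimates, the per-iteration log-likelihood trace and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "GMMParams",
    "IntensityMixtureModel",
    "IntensityMixtureResults",
    "FeatureVector",
    "FeatureMatrix",
    "fit_gmm",
    "build_feature_vector",
    "build_feature_matrix",
]


@dataclass
class GMMParams:
    """Fitted mixture parameters, components sorted by ascending mean.

    weights are unitless and sum to 1; means are gray levels; variances
    are squared gray levels.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float = np.nan
    n_iterations: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not (self.weights.shape == self.means.shape == self.variances.shape):
            raise ValueError("weights, means, variances must have equal length")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights <= 0):
            raise ValueError("mixture weights must be positive")
        if np.any(self.variances < 0):
            raise ValueError("variances must be non-negative")

    @property
    def K(self) -> int:
        return self.weights.size

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        xv = np.atleast_1d(x)
        sig = np.sqrt(self.variances)
        out = np.sum(
            self.weights[:, None] * norm.pdf(xv[None, :], self.means[:, None], sig[:, None]),
            axis=0,
        )
        return float(out[0]) if x.ndim == 0 else out.reshape(x.shape)

    def cdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        sig = np.sqrt(self.variances)
        out = np.sum(
            self.weights[:, None] * norm.cdf(x[None, :], self.means[:, None], sig[:, None]),
            axis=0,
        )
        return out

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "log_likelihood": float(self.log_likelihood),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
        }


def _sort_components(w, mu, v):
    """Ascending mean; ties broken by descending weight."""
    order = np.lexsort((-np.asarray(w), np.asarray(mu)))
    return np.asarray(w)[order], np.asarray(mu)[order], np.asarray(v)[order]


def _as_weighted_samples(data) -> tuple[np.ndarray, np.ndarray]:
    """Return (values, weights).  Histograms become weighted bin centers."""
    # duck-typed so this module does not import segment
    if hasattr(data, "counts") and hasattr(data, "bin_edges"):
        centers = np.asarray(data.centers, dtype=float)
        counts = np.asarray(data.counts, dtype=float)
        keep = counts > 0
        return centers[keep], counts[keep]
    x = np.asarray(data, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no samples provided")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    return x, np.ones_like(x)


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(q, cw, x)


class IntensityMixtureModel:
    """K-component univariate Gaussian mixture for region intensities.

    Parameters
    ----------
    data : array-like of intensities or IntensityHistogram
        Histogram input is treated as weighted samples at bin centers.
    K : int
        Number of mixture components (default 3).
    """

    def __init__(self, data, K: int = 3):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.values, self.sample_weights = _as_weighted_samples(data)
        if self.sample_weights.sum() < K:
            raise ValueError("need at least K samples (or K units of histogram mass)")
        self.K = int(K)

    def _initialize(self, init_policy: str, seed: Optional[int]):
        x, w = self.values, self.sample_weights
        mean = np.average(x, weights=w)
        var = np.average((x - mean) ** 2, weights=w)
        if init_policy == "quantile":
            q = (np.arange(self.K) + 1.0) / (self.K + 1.0)
            mu = _weighted_quantile(x, w, q)
        elif init_policy == "kmeans":
            from sklearn.cluster import KMeans

            km = KMeans(n_clusters=self.K, n_init=1, random_state=seed)
            km.fit(x[:, None], sample_weight=w)
            mu = np.sort(km.cluster_centers_.ravel())
        else:
            raise ValueError(f"unknown init_policy {init_policy!r}")
        weights = np.full(self.K, 1.0 / self.K)
        variances = np.full(self.K, max(var, 1e-12))
        return weights, mu.astype(float), variances

    def fit(
        self,
        init_policy: str = "quantile",
        tol: float = 1e-8,
        max_iter: int = 500,
        variance_floor: Optional[float] = None,
        seed: Optional[int] = None,
    ) -> "IntensityMixtureResults":
        """Maximum-likelihood EM fit.

        ``tol`` is the relative log-likelihood change declaring convergence;
        ``variance_floor`` defaults to 1e-6 x the (weighted) sample variance,
        never below 1e-12, which keeps degenerate components from collapsing.
        """
        x, sw = self.values, self.sample_weights
        mean = np.average(x, weights=sw)
        sample_var = np.average((x - mean) ** 2, weights=sw)
        floor = variance_floor if variance_floor is not None else max(1e-6 * sample_var, 1e-12)

        w, mu, v = self._initialize(init_policy, seed)
        v = np.maximum(v, floor)
        n_eff = sw.sum()
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step in log space
            log_comp = (
                -0.5 * (x[None, :] - mu[:, None]) ** 2 / v[:, None]
                - 0.5 * np.log(2.0 * np.pi * v[:, None])
                + np.log(w[:, None])
            )
            log_px = logsumexp(log_comp, axis=0)
            ll = float(np.sum(sw * log_px))
            trace.append(ll)
            resp = np.exp(log_comp - log_px[None, :])  # K x n
            # M-step, weighted by the per-sample weights
            rk = resp * sw[None, :]
            nk = rk.sum(axis=1)
            nk = np.maximum(nk, 1e-300)
            w = nk / n_eff
            mu = (rk @ x) / nk
            v = (rk @ (x**2)) / nk - mu**2
            v = np.maximum(v, floor)
            if len(trace) >= 2:
                prev = trace[-2]
                denom = max(abs(prev), 1.0)
                if abs(trace[-1] - prev) / denom < tol:
                    converged = True
                    break
        w, mu, v = _sort_components(w, mu, v)
        params = GMMParams(
            weights=w / w.sum(),
            means=mu,
            variances=v,
            log_likelihood=trace[-1],
            n_iterations=it,
            converged=converged,
        )
        return IntensityMixtureResults(self, params, np.asarray(trace))


class IntensityMixtureResults:
    """EM fit results: parameter estimates plus the log-likelihood trace."""

    def __init__(self, model: IntensityMixtureModel, params: GMMParams, loglik_trace: np.ndarray):
        self.model = model
        self.params = params
        self.loglik_trace = loglik_trace

    @property
    def weights(self):
        return self.params.weights

    @property
    def means(self):
        return self.params.means

    @property
    def variances(self):
        return self.params.variances

    def pdf(self, x):
        return self.params.pdf(x)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "weight": self.params.weights,
                "mean": self.params.means,
                "variance": self.params.variances,
                "std": np.sqrt(self.params.variances),
            },
            index=[f"component_{i + 1}" for i in range(self.params.K)],
        )
        df.attrs["log_likelihood"] = self.params.log_likelihood
        df.attrs["n_iterations"] = self.params.n_iterations
        df.attrs["converged"] = self.params.converged
        return df


def fit_gmm(
    data,
    K: int = 3,
    init_policy: str = "quantile",
    tol: float = 1e-8,
    max_iter: int = 500,
    variance_floor: Optional[float] = None,
    seed: Optional[int] = None,
) -> GMMParams:
    """Convenience wrapper: fit and return only the parameters."""
    model = IntensityMixtureModel(data, K=K)
    return model.fit(
        init_policy=init_policy,
        tol=tol,
        max_iter=max_iter,
        variance_floor=variance_floor,
        seed=seed,
    ).params


@dataclass
class FeatureVector:
    """One region's 3K-element feature row: weights, means, variances."""

    values: np.ndarray
    names: list
    label: Optional[str] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.names) != self.values.size:
            raise ValueError("values must be 1-D and match names")


def build_feature_vector(
    params: GMMParams, label: Optional[str] = None, provenance: Optional[dict] = None
) -> FeatureVector:
    """Concatenate [w_1..w_K, mu_1..mu_K, v_1..v_K], components by ascending mean."""
    w, mu, v = _sort_components(params.weights, params.means, params.variances)
    K = params.K
    names = (
        [f"w{i + 1}" for i in range(K)]
        + [f"mu{i + 1}" for i in range(K)]
        + [f"v{i + 1}" for i in range(K)]
    )
    return FeatureVector(
        values=np.concatenate([w, mu, v]),
        names=names,
        label=label,
        provenance=dict(provenance or {}),
    )


@dataclass
class FeatureMatrix:
    """n x d stack of per-region feature vectors with labels and provenance."""

    values: np.ndarray
    feature_names: list
    labels: list
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] < 1:
            raise ValueError("feature matrix needs at least one row")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length mismatch")
        if not self.provenance:
            self.provenance = [{} for _ in range(self.values.shape[0])]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        prov_keys = sorted({k for p in self.provenance for k in p})
        for k in prov_keys:
            df[k] = [p.get(k) for p in self.provenance]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def subset(self, row_mask) -> "FeatureMatrix":
        idx = np.flatnonzero(np.asarray(row_mask))
        return FeatureMatrix(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            labels=[self.labels[i] for i in idx],
            provenance=[self.provenance[i] for i in idx],
        )


def build_feature_matrix(vectors: Sequence[FeatureVector]) -> FeatureMatrix:
    """Stack feature vectors row-wise, preserving input order."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("cannot build a feature matrix from an empty list")
    d = vectors[0].values.size
    for vec in vectors:
        if vec.values.size != d:
            raise ValueError("all feature vectors must have the same length")
    return FeatureMatrix(
        values=np.vstack([vec.values for vec in vectors]),
        feature_names=list(vectors[0].names),
        labels=[vec.label for vec in vectors],
        provenance=[vec.provenance for vec in vectors],
    )
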