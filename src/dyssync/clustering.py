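"""Phenotype discovery: z-scoring, elbow model selection, K-means, PCA.

The 24 dyssynchrony metrics are standardized to z-scores over the entire
cohort (patients and controls together), K-means is fit for a range of k and
the elbow of the inertia curve selects k, and the final partition is
relabeled deterministically so that cluster 1 is the most synchronous
(lowest mean circumferential-strain CCD) and the highest label the most
dyssynchronous.  A 2-component PCA of the z-matrix provides the standard
visualization coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ConstantFeatureError, DegenerateClusteringError, ProjectionError


@dataclass
class StandardizationParams:
    """Per-feature cohort mean and sample SD used for z-scoring."""

    columns: Tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        return (features[list(self.columns)] - self.mean) / self.sd


def standardize(features: pd.DataFrame) -> Tuple[pd.DataFrame, StandardizationParams]:
    """Z-score each feature column (mean 0, sample SD 1) over the full cohort.

    Raises :class:`ConstantFeatureError` naming the first zero-variance
    column; columns are otherwise returned in the input order.
    """
    if len(features) < 2:
        raise ConstantFeatureError("standardization requires at least 2 subjects")
    if features.isna().any().any():
        raise ValueError("missing feature values; standardization expects a complete matrix")
    mean = features.mean(axis=0).to_numpy()
    sd = features.std(axis=0, ddof=1).to_numpy()
    zero = np.nonzero(sd == 0.0)[0]
    if zero.size:
        raise ConstantFeatureError(
            f"constant feature column {features.columns[zero[0]]!r} (SD = 0)"
        )
    params = StandardizationParams(tuple(features.columns), mean, sd)
    return params.transform(features), params


@dataclass
class ElbowResult:
    """Outcome of elbow model selection over a k range."""

    k: int
    inertia_by_k: Dict[int, float]
    curvature_by_k: Dict[int, float]
    no_elbow_warning: bool
    scale: str


def _fit_inertia(Z: np.ndarray, k: int, seed: int, n_init: int) -> float:
    if k == 1:
        centered = Z - Z.mean(axis=0)
        return float((centered**2).sum())
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, tol=1e-6,
                max_iter=300, random_state=seed)
    km.fit(Z)
    return float(km.inertia_)


def elbow_select(
    Z: pd.DataFrame | np.ndarray,
    k_range: Sequence[int] = range(1, 11),
    seed: int = 0,
    n_init: int = 10,
    scale: str = "log",
) -> ElbowResult:
    """Select k at the maximum inflection of the inertia-vs-k curve.

    K-means is fit at each k in ``k_range``; k* is the interior k maximizing
    the discrete second difference of the inertia curve — by default on the
    log scale, which measures where the *relative* inertia gains collapse and
    is invariant to the overall spread of the data (``scale="linear"`` gives
    the raw-inertia curvature).  Ties break toward smaller k.  If no interior
    k has positive curvature (e.g. perfectly linear decay), the smallest
    interior k is returned with ``no_elbow_warning`` set.
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if sorted(ks) != ks or len(set(ks)) != len(ks):
        raise ValueError("k_range must be strictly increasing")
    Zm = np.asarray(Z, dtype=float)
    if Zm.shape[0] <= max(ks):
        raise ValueError("need more subjects than the largest k")
    if scale not in ("log", "linear"):
        raise ValueError("scale must be 'log' or 'linear'")

    inertia = np.array([_fit_inertia(Zm, k, seed, n_init) for k in ks])
    # inertia must be non-increasing in k; retry harder on local-optimum blips
    for i in range(1, len(ks)):
        if inertia[i] > inertia[i - 1] * (1 + 1e-9):
            inertia[i] = min(
                inertia[i], _fit_inertia(Zm, ks[i], seed + 9973, max(n_init * 5, 50))
            )
            if inertia[i] > inertia[i - 1] * (1 + 1e-6):
                raise DegenerateClusteringError(
                    f"inertia increased from k={ks[i-1]} to k={ks[i]}"
                )

    return select_elbow_from_inertia(dict(zip(ks, inertia)), scale=scale)


def select_elbow_from_inertia(
    inertia_by_k: Dict[int, float], scale: str = "log"
) -> ElbowResult:
    """Elbow selection given an already-computed inertia-vs-k curve.

    The elbow is the interior k with maximal discrete second difference of
    the (log-)inertia curve; see :func:`elbow_select`.
    """
    ks = sorted(inertia_by_k)
    if len(ks) < 3:
        raise ValueError("need inertia at >= 3 values of k")
    inertia = np.array([inertia_by_k[k] for k in ks], dtype=float)
    if scale == "log":
        floor = max(inertia[0], 1.0) * 1e-12
        y = np.log(np.maximum(inertia, floor))
    elif scale == "linear":
        y = inertia
    else:
        raise ValueError("scale must be 'log' or 'linear'")
    d2 = y[:-2] - 2.0 * y[1:-1] + y[2:]  # curvature at interior ks
    interior = ks[1:-1]
    no_elbow = bool(d2.max() <= 0.0 or np.allclose(d2, d2[0]))
    if no_elbow:
        warnings.warn("no elbow detected; returning smallest interior k", stacklevel=2)
        k_star = interior[0]
    else:
        k_star = interior[int(np.argmax(d2))]  # argmax: first max -> smaller k
    return ElbowResult(
        k=int(k_star),
        inertia_by_k={k: float(v) for k, v in zip(ks, inertia)},
        curvature_by_k={k: float(v) for k, v in zip(interior, d2)},
        no_elbow_warning=no_elbow,
        scale=scale,
    )


@dataclass
class ClusterModel:
    """A fitted, deterministically relabeled K-means partition."""

    k: int
    seed: int
    labels: np.ndarray  # 1..k per subject, 1 = most synchronous
    centroids: pd.DataFrame  # k x features, in z-space, rows ordered by label
    inertia: float
    order_feature: str
    subject_ids: Tuple[str, ...]
    inertia_by_k: Dict[int, float] = field(default_factory=dict)
    pca_coordinates: Optional[np.ndarray] = None  # n x 2

    def assignments(self) -> pd.Series:
        return pd.Series(self.labels, index=list(self.subject_ids), name="cluster")


def kmeans_fit(
    Z: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 50,
    order_feature: str = "ccd_cs",
) -> ClusterModel:
    """Fit K-means (k-means++ init, 50 restarts, tol 1e-6) on the z-matrix.

    Raw K-means labels are arbitrary, so clusters are renumbered 1..k by
    ascending cluster mean of ``order_feature`` (z-scored circumferential
    CCD by default): cluster 1 is the most synchronous phenotype.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(Z) <= k:
        raise ValueError("need more subjects than clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, tol=1e-6,
                max_iter=300, random_state=seed)
    raw = km.fit_predict(np.asarray(Z, dtype=float))
    if len(np.unique(raw)) < k:
        raise DegenerateClusteringError("empty cluster persisted across restarts")
    if order_feature not in Z.columns:
        raise ValueError(f"order feature {order_feature!r} not among z-columns")
    key = Z[order_feature].to_numpy()
    means = np.array([key[raw == j].mean() for j in range(k)])
    order = np.argsort(means, kind="stable")  # ties: stable by raw label
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    centroids = pd.DataFrame(km.cluster_centers_[order], columns=Z.columns,
                             index=pd.RangeIndex(1, k + 1, name="cluster"))
    return ClusterModel(
        k=k,
        seed=seed,
        labels=relabel[raw],
        centroids=centroids,
        inertia=float(km.inertia_),
        order_feature=order_feature,
        subject_ids=tuple(str(s) for s in Z.index),
    )


def pca_project(Z: pd.DataFrame | np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project the z-matrix onto its top-2 principal components.

    Returns ``(scores (n, 2), explained_variance, components (2, p))``.
    Component 1 explains at least as much variance as component 2, and each
    loading vector is oriented so its coefficient sum is nonnegative.  A
    rank-1 input is allowed (component-2 variance is then 0).
    """
    Zm = np.asarray(Z, dtype=float)
    if Zm.ndim != 2 or Zm.shape[0] < 3:
        raise ProjectionError("PCA projection requires at least 3 subjects")
    if Zm.shape[1] < 2:
        raise ProjectionError("PCA projection requires at least 2 features")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Zm)
    components = pca.components_.copy()
    for i in range(2):
        if components[i].sum() < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    return scores, pca.explained_variance_.copy(), components
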