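"""Cognitive profile discovery: k-means on scaled patient z-scores.

Patients' normative z-scores are median-imputed, standardized per feature,
and clustered with Lloyd's k-means over a range of k. Model selection uses
the within-cluster sum of squares (WCSS) curve: the automated elbow
suggestion is the k maximizing the second difference of the curve, and the
final k can be pinned by the analyst (the conventional workflow combines
the elbow with visual inspection of cluster overlap in PCA space, which a
program cannot do). Cluster labels are stabilized by decreasing cluster
size with a lexicographic centroid tie-break, so identical inputs and
seeds always yield identical reports.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "CognitiveProfiler",
    "scale_features",
    "fit_kmeans",
    "profile_summary",
    "pca_projection",
]


def scale_features(z: pd.DataFrame, patients=None) -> pd.DataFrame:
    """Median-impute then standardize each feature column (mean 0, SD 1, ddof=1).

    Zero-variance columns cannot be scaled and are dropped with a warning.
    """
    z = z.z if hasattr(z, "z") else z
    if patients is not None:
        z = z.loc[list(patients)]
    filled = z.apply(lambda col: col.fillna(col.median()))
    if filled.isna().any().any():
        all_nan = [c for c in filled.columns if filled[c].isna().all()]
        raise ValueError(f"features with no observed values: {all_nan}")
    sd = filled.std(ddof=1)
    dead = sd[(sd == 0) | sd.isna()].index.tolist()
    if dead:
        msg = f"dropping zero-variance features before scaling: {dead}"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        filled = filled.drop(columns=dead)
        sd = sd.drop(index=dead)
    return (filled - filled.mean()) / sd


class CognitiveProfiler(BaseEstimator, ClusterMixin):
    """K-means patient profiling with WCSS/elbow model selection.

    Parameters
    ----------
    k : final number of clusters; ``None`` accepts the elbow suggestion.
    k_range : contiguous range of k values scanned for the WCSS curve.
    n_init : k-means restarts per k (best-of-n kept).
    seed : base random seed for all restarts.
    tol : Lloyd convergence tolerance on centroid movement.
    scale : standardize input columns first (set False if pre-scaled).

    Attributes (after fit)
    ----------------------
    labels_ : stable cluster ids (1-based, decreasing cluster size).
    centroids_ : k x features centroid matrix in the scaled space.
    wcss_curve_ : dict k' -> WCSS of the best-of-n_init solution.
    elbow_k_ : automated elbow suggestion (max second difference of WCSS).
    k_ : the k actually used (``k`` or the elbow suggestion).
    """

    def __init__(self, k: int | None = None, k_range=(1, 2, 3, 4, 5, 6, 7, 8),
                 n_init: int = 25, seed: int = 0, tol: float = 1e-6,
                 scale: bool = True):
        self.k = k
        self.k_range = k_range
        self.n_init = n_init
        self.seed = seed
        self.tol = tol
        self.scale = scale

    def fit(self, X: pd.DataFrame, y=None) -> "CognitiveProfiler":
        X = X.z if hasattr(X, "z") else X
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        scaled = scale_features(X) if self.scale else X.astype(float)
        n = scaled.shape[0]
        ks = sorted(int(k) for k in self.k_range)
        if ks[0] < 1 or ks[-1] > n:
            raise ValueError(f"k_range must lie within [1, {n}]")
        models: dict[int, KMeans] = {}
        wcss: dict[int, float] = {}
        for k in ks:
            km = KMeans(n_clusters=k, n_init=self.n_init, tol=self.tol,
                        algorithm="lloyd", random_state=self.seed % (2**32))
            km.fit(scaled.to_numpy())
            models[k] = km
            wcss[k] = float(km.inertia_)
        self.wcss_curve_ = wcss
        self.elbow_k_ = _elbow(wcss)
        if self.k is not None:
            if self.k not in models:
                raise ValueError(f"k={self.k} not in scanned k_range {ks}")
            self.k_ = int(self.k)
        else:
            self.k_ = self.elbow_k_
        km = models[self.k_]
        order = _stable_order(km.labels_, km.cluster_centers_)
        relabel = {old: new + 1 for new, old in enumerate(order)}
        self.labels_ = pd.Series([relabel[l] for l in km.labels_],
                                 index=scaled.index, name="profile")
        self.centroids_ = pd.DataFrame(km.cluster_centers_[order],
                                       index=range(1, self.k_ + 1),
                                       columns=scaled.columns)
        self.scaled_ = scaled
        self.feature_names_in_ = np.asarray(scaled.columns, dtype=object)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_.to_numpy()

    def profile_summary(self, z: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
        """Mean raw z per (cluster, feature) plus cluster sizes.

        Clusters are reported in decreasing-size order under their stable
        1-based labels.
        """
        if not hasattr(self, "labels_"):
            raise ValueError("CognitiveProfiler is not fitted")
        z = z.z if hasattr(z, "z") else z
        z = z.loc[self.labels_.index]
        means = z.groupby(self.labels_).mean()
        sizes = self.labels_.value_counts().sort_index()
        means.index.name = "profile"
        sizes.index.name = "profile"
        return means, sizes


def _elbow(wcss: dict[int, float]) -> int:
    """k maximizing the second difference of the WCSS curve.

    Interior points only; degenerate scans (fewer than 3 k values) fall
    back to the largest drop / smallest k.
    """
    ks = sorted(wcss)
    if len(ks) < 3:
        return ks[0] if len(ks) == 1 else max(ks, key=lambda k: -wcss[k])
    second = {k: wcss[ks[i - 1]] - 2 * wcss[k] + wcss[ks[i + 1]]
              for i, k in enumerate(ks) if 0 < i < len(ks) - 1}
    return max(second, key=lambda k: (second[k], -k))


def _stable_order(labels: np.ndarray, centers: np.ndarray) -> list[int]:
    """Cluster index order: decreasing size, then lexicographic centroid."""
    sizes = np.bincount(labels, minlength=centers.shape[0])
    return sorted(range(centers.shape[0]),
                  key=lambda i: (-sizes[i], tuple(np.round(centers[i], 12))))


def fit_kmeans(scaled: pd.DataFrame, k_range=(1, 2, 3, 4, 5, 6, 7, 8),
               seed: int = 0, n_init: int = 25, k: int | None = None) -> CognitiveProfiler:
    """Scan k over ``k_range`` on an already-scaled matrix; see CognitiveProfiler."""
    return CognitiveProfiler(k=k, k_range=k_range, n_init=n_init, seed=seed,
                             scale=False).fit(scaled)


def profile_summary(model: CognitiveProfiler, z: pd.DataFrame):
    return model.profile_summary(z)


def pca_projection(scaled: pd.DataFrame, n_components: int = 2):
    """PCA coordinates (for cluster-overlap plots) and explained-variance shares."""
    scaled = pd.DataFrame(scaled)
    if scaled.shape[1] < 2:
        raise ValueError("need at least 2 features for a projection")
    n_components = min(n_components, scaled.shape[0], scaled.shape[1])
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(scaled.to_numpy(float))
    coords = pd.DataFrame(coords, index=scaled.index,
                          columns=[f"PC{i + 1}" for i in range(n_components)])
    return coords, pca.explained_variance_ratio_.copy()
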