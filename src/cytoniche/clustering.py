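"""Hybrid density/spectral phenotype clustering on t-SNE embeddings.

Designed for very large cell sets where spectral clustering alone is
infeasible: DBSCAN first isolates density-coherent clusters; the dominant
("big") cluster is re-clustered by spectral clustering on a 1-in-10
subsample; finally a 5-nearest-neighbour classifier trained on all
labelled points (small DBSCAN clusters + labelled subsample) extends the
labels to every cell, so the final labelling is total.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN, SpectralClustering
from sklearn.manifold import TSNE
from sklearn.neighbors import KNeighborsClassifier

from .lineage import normalize_for_display, zscore_cluster_means
from .model import ConfigurationError, EXPR_PREFIX

__all__ = [
    "TSNE_MARKERS",
    "select_features",
    "tsne_embed",
    "HybridDensitySpectralClustering",
    "cluster_heatmap",
]

#: functional/lineage markers used for the monocyte–macrophage embedding
TSNE_MARKERS = (
    "CD14", "CD16", "CD68", "CD163", "P2Y12", "CC3", "Ki67",
    "CD40", "CD206", "HIF1a", "MMP9", "MPO", "OX40L", "pSTAT3",
)


def select_features(cells: pd.DataFrame, markers: Sequence[str]) -> np.ndarray:
    """Per-cell raw mean-expression matrix restricted to ``markers``.

    Column order follows the marker list; a missing marker raises a
    configuration error naming it.  No transform is applied here — display
    normalization happens only at plotting time.
    """
    missing = [m for m in markers if EXPR_PREFIX + m not in cells.columns]
    if missing:
        raise ConfigurationError(f"markers absent from cell table: {missing}")
    return cells[[EXPR_PREFIX + m for m in markers]].to_numpy(dtype=float)


def tsne_embed(features: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE with default perplexity; deterministic given ``seed``."""
    features = np.asarray(features, dtype=float)
    if len(features) < 3 * perplexity:
        raise ValueError(
            f"{len(features)} cells is too few for perplexity {perplexity} "
            "(need at least 3x)"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(features)


class HybridDensitySpectralClustering(BaseEstimator, ClusterMixin):
    """DBSCAN → spectral-on-subsample → kNN label completion.

    Parameters
    ----------
    eps : float, default 3.0
        DBSCAN neighbourhood radius, in units of the clustered space
        (the 2-D embedding by default).
    min_samples : int, default 30
        DBSCAN core-point threshold.
    n_spectral_clusters : int or "auto", default "auto"
        Clusters for the spectral re-clustering of the big group; "auto"
        uses an eigengap heuristic on the subsample's kNN graph.
    subsample_rate : int, default 10
        The big group is subsampled 1-in-``subsample_rate`` (uniform,
        without replacement, seeded) before spectral clustering.
    knn_k : int, default 5
        Neighbours for the final label-completion classifier.
    spectral_neighbors : int, default 15
        kNN-graph size for the spectral affinity.
    min_big_fraction : float, default None
        If set, every DBSCAN cluster holding at least this fraction of the
        points joins the "big" group; by default only the largest cluster
        is "big" and all other clusters are kept as final small clusters.
    random_state : int, default 0

    Attributes
    ----------
    labels_ : ndarray
        Final 0-based cluster label per point (total: no noise labels).
    dbscan_labels_ : ndarray
        Raw DBSCAN labels (-1 = noise) before re-clustering.
    """

    def __init__(
        self,
        eps: float = 3.0,
        min_samples: int = 30,
        n_spectral_clusters="auto",
        subsample_rate: int = 10,
        knn_k: int = 5,
        spectral_neighbors: int = 15,
        min_big_fraction: float | None = None,
        random_state: int = 0,
    ):
        self.eps = eps
        self.min_samples = min_samples
        self.n_spectral_clusters = n_spectral_clusters
        self.subsample_rate = subsample_rate
        self.knn_k = knn_k
        self.spectral_neighbors = spectral_neighbors
        self.min_big_fraction = min_big_fraction
        self.random_state = random_state

    # -- helpers -----------------------------------------------------

    def _eigengap(self, X: np.ndarray, max_k: int = 10) -> int:
        """Eigengap heuristic on the normalized Laplacian of a kNN graph."""
        from scipy.sparse import csgraph
        from sklearn.neighbors import kneighbors_graph

        k = min(self.spectral_neighbors, len(X) - 1)
        A = kneighbors_graph(X, n_neighbors=k, mode="connectivity")
        A = 0.5 * (A + A.T)
        lap = csgraph.laplacian(A, normed=True)
        vals = np.sort(np.linalg.eigvalsh(lap.toarray()))[: max_k + 1]
        gaps = np.diff(vals)
        return int(np.argmax(gaps) + 1)

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if len(X) < self.min_samples:
            raise ValueError(
                f"{len(X)} points is fewer than min_samples={self.min_samples}"
            )
        rng = np.random.default_rng(self.random_state)
        db = DBSCAN(eps=self.eps, min_samples=self.min_samples).fit(X)
        self.dbscan_labels_ = db.labels_.copy()
        clusters, sizes = np.unique(db.labels_[db.labels_ >= 0], return_counts=True)

        if len(clusters) == 0:
            warnings.warn("DBSCAN found no clusters; single-cluster fallback", stacklevel=2)
            self.labels_ = np.zeros(len(X), dtype=np.int64)
            self._train_knn(X, self.labels_, np.ones(len(X), dtype=bool))
            return self

        if self.min_big_fraction is not None:
            big_ids = set(clusters[sizes >= self.min_big_fraction * len(X)])
            if not big_ids:
                big_ids = {clusters[np.argmax(sizes)]}
        else:
            big_ids = {clusters[np.argmax(sizes)]}
        small_ids = [c for c in clusters if c not in big_ids]

        labels = np.full(len(X), -1, dtype=np.int64)
        for new, c in enumerate(small_ids):
            labels[db.labels_ == c] = new
        next_label = len(small_ids)

        big_mask = np.isin(db.labels_, list(big_ids))
        big_idx = np.nonzero(big_mask)[0]
        n_sub = max(len(big_idx) // self.subsample_rate, 1)
        sub_idx = np.sort(rng.choice(big_idx, size=n_sub, replace=False))

        if self.n_spectral_clusters == "auto":
            n_spec = self._eigengap(X[sub_idx]) if len(sub_idx) > 2 else 1
        else:
            n_spec = int(self.n_spectral_clusters)
        n_spec = min(n_spec, len(sub_idx))
        if n_spec <= 1:
            labels[sub_idx] = next_label
        else:
            spec = SpectralClustering(
                n_clusters=n_spec,
                affinity="nearest_neighbors",
                n_neighbors=min(self.spectral_neighbors, len(sub_idx) - 1),
                assign_labels="kmeans",
                random_state=self.random_state,
            )
            labels[sub_idx] = spec.fit_predict(X[sub_idx]) + next_label
        self.n_spectral_clusters_ = n_spec

        labelled = labels >= 0
        self._train_knn(X, labels, labelled)
        # training points keep their labels; kNN fills in the rest, so the
        # completion step is idempotent on an already fully labelled set
        out = labels.copy()
        if (~labelled).any():
            out[~labelled] = self._knn.predict(X[~labelled])
        self.labels_ = out
        return self

    def _train_knn(self, X, labels, labelled_mask):
        k = min(self.knn_k, int(labelled_mask.sum()))
        self._knn = KNeighborsClassifier(n_neighbors=k)
        self._knn.fit(X[labelled_mask], labels[labelled_mask])

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Label new points with the fitted kNN completion classifier."""
        return self._knn.predict(np.asarray(X, dtype=float))


def cluster_heatmap(
    cells: pd.DataFrame,
    labels: Sequence,
    markers: Sequence[str],
    pct: float = 95.0,
) -> pd.DataFrame:
    """Z-scored cluster means of display-normalized expression.

    Each marker is normalized to its ``pct``-th percentile (clipped to
    [0, 1]), averaged within clusters, then z-scored across clusters.
    With a single cluster the raw normalized means are returned with a
    warning (a z-score across one row is undefined).
    """
    X = select_features(cells, markers)
    norm = np.column_stack([normalize_for_display(X[:, j], pct) for j in range(X.shape[1])])
    df = pd.DataFrame(norm, columns=list(markers))
    df["_cluster"] = np.asarray(labels)
    means = df.groupby("_cluster").mean()
    if len(means) < 2:
        warnings.warn("single cluster; returning raw normalized means", stacklevel=2)
        return means
    return zscore_cluster_means(means)
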