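"""Cellular-neighbourhood (CN) discovery from N-nearest-neighbour windows.

Each cell's *window* is the frequency vector of cell types among its N
nearest cells (the index cell excluded).  Windows pooled over the
discovery images are clustered with mini-batch k-means; every cell is then
assigned the CN of its window.  Per-image CN prevalence is normalized to
sum to 100% and cohorts are stratified by the z-score (or median) of a
CN's patient-level prevalence.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import MiniBatchKMeans

from ._utils import check_finite_coords

__all__ = [
    "neighbour_windows",
    "CellularNeighbourhoods",
    "cn_prevalence",
    "patient_prevalence",
    "stratify_by_cn",
    "voronoi_render",
]


def neighbour_windows(
    cells: pd.DataFrame,
    n_neighbors: int = 10,
    type_alphabet: Sequence | None = None,
    type_column: str = "lineage",
    include_self: bool = False,
) -> pd.DataFrame:
    """Type-frequency windows over the N nearest cells, per cell of one image.

    Distances are Euclidean between centroids; exact ties at the N-th
    neighbour are broken by row order (deterministic).  Images with at most
    N cells use all other cells (flagged in the ``window_n`` column).
    Returns a DataFrame aligned with ``cells`` whose columns are the type
    alphabet (frequencies summing to 1) plus ``window_n``.
    """
    x = cells["centroid_x_um"].to_numpy(dtype=float)
    y = cells["centroid_y_um"].to_numpy(dtype=float)
    check_finite_coords(x, y)
    types = cells[type_column].to_numpy()
    if type_alphabet is None:
        type_alphabet = sorted(set(types))
    alphabet = list(type_alphabet)
    t_index = {t: i for i, t in enumerate(alphabet)}
    codes = np.array([t_index[t] for t in types], dtype=np.int64)

    n = len(cells)
    extra = 0 if include_self else 1
    k_eff = min(n_neighbors, n - extra)
    if k_eff < n_neighbors:
        warnings.warn(
            f"image has {n} cells; windows use {k_eff} neighbours instead of {n_neighbors}",
            stacklevel=2,
        )
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    # one extra neighbour so exact ties at the cutoff can be re-ordered
    k_query = min(n, k_eff + extra + 1)
    dist, idx = tree.query(pts, k=k_query)
    if k_query == 1:
        dist, idx = dist[:, None], idx[:, None]
    # stable per-row order: distance first, then row index for exact ties
    order = np.lexsort((idx, dist), axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    if not include_self:
        # drop the index cell itself; with duplicated coordinates the self
        # index may not be among the returned k — drop the last entry then
        keep = idx != np.arange(n)[:, None]
        no_self = keep.all(axis=1)
        keep[no_self, -1] = False
        idx = idx[keep].reshape(n, -1)
    sel = idx[:, :k_eff]
    counts = np.zeros((n, len(alphabet)), dtype=np.float64)
    np.add.at(counts, (np.repeat(np.arange(n), k_eff), codes[sel].ravel()), 1.0)
    freq = counts / max(k_eff, 1)
    out = pd.DataFrame(freq, columns=alphabet, index=cells.index)
    out["window_n"] = k_eff
    return out


class CellularNeighbourhoods(BaseEstimator, ClusterMixin):
    """Mini-batch k-means over pooled neighbour windows.

    Parameters
    ----------
    n_neighbors : int, default 10
        Window size N (nearest cells per index cell).
    n_clusters : int, default 9
        Number of cellular neighbourhoods K.
    batch_size : int, default 100
        Mini-batch size (the larger 1024 default suits bigger cohorts).
    random_state : int, default 0
        Seed for k-means++ initialization and batching.
    include_self : bool, default False
        Whether the index cell counts inside its own window.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_types)
        Fitted centroids in type-frequency space.
    labels_ : ndarray
        1-based CN label per fitted cell.
    type_alphabet_ : list
        Column order of the frequency space.
    """

    def __init__(
        self,
        n_neighbors: int = 10,
        n_clusters: int = 9,
        batch_size: int = 100,
        random_state: int = 0,
        include_self: bool = False,
        type_column: str = "lineage",
    ):
        self.n_neighbors = n_neighbors
        self.n_clusters = n_clusters
        self.batch_size = batch_size
        self.random_state = random_state
        self.include_self = include_self
        self.type_column = type_column

    def _windows(self, cells: pd.DataFrame, alphabet=None) -> pd.DataFrame:
        parts = []
        for _, grp in cells.groupby("image_id", sort=True):
            parts.append(
                neighbour_windows(
                    grp,
                    n_neighbors=self.n_neighbors,
                    type_alphabet=alphabet,
                    type_column=self.type_column,
                    include_self=self.include_self,
                )
            )
        return pd.concat(parts).loc[cells.index]

    def fit(self, cells: pd.DataFrame, y=None):
        """Fit on the discovery cell table (pool windows over its images)."""
        alphabet = sorted(set(cells[self.type_column]))
        windows = self._windows(cells, alphabet)
        X = windows[alphabet].to_numpy()
        if self.n_clusters > len(X):
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds {len(X)} windows"
            )
        km = MiniBatchKMeans(
            n_clusters=self.n_clusters,
            batch_size=self.batch_size,
            random_state=self.random_state,
            n_init=3,
        )
        self.labels_ = km.fit_predict(X) + 1
        self.cluster_centers_ = km.cluster_centers_
        self.type_alphabet_ = alphabet
        self._kmeans = km
        return self

    def fit_predict(self, cells: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(cells).labels_

    def predict(self, cells: pd.DataFrame) -> np.ndarray:
        """Assign CN labels (1-based) to any cell table's windows."""
        windows = self._windows(cells, self.type_alphabet_)
        X = windows[self.type_alphabet_].to_numpy()
        return self._kmeans.predict(X) + 1


def cn_prevalence(cells: pd.DataFrame, n_clusters: int, label_column: str = "cn_label") -> pd.DataFrame:
    """Per-image CN prevalence in percent (rows sum to exactly 100)."""
    tab = pd.crosstab(cells["image_id"], cells[label_column])
    tab = tab.reindex(columns=range(1, n_clusters + 1), fill_value=0)
    prev = tab.div(tab.sum(axis=1), axis=0) * 100.0
    prev.columns = [f"CN{c}" for c in prev.columns]
    return prev


def patient_prevalence(prevalence: pd.DataFrame, image_to_patient: pd.Series) -> pd.DataFrame:
    """Average per-image prevalence within patients (duplicate cores)."""
    pid = prevalence.index.map(image_to_patient)
    if pid.isna().any():
        missing = prevalence.index[pid.isna()].tolist()
        raise KeyError(f"images without patient mapping: {missing}")
    out = prevalence.groupby(pid).mean()
    out.index.name = "patient_id"
    return out


def stratify_by_cn(
    prevalence: pd.DataFrame, cn: int | str, split: str = "zscore"
) -> tuple[list, list]:
    """Split patients into high/low groups on one CN's prevalence.

    ``split="zscore"``: high = z >= 0 (i.e. at or above the mean);
    ``split="median"``: high = value >= median.  Returns
    ``(high_ids, low_ids)``; a degenerate constant feature yields a single
    (high) group with a warning.
    """
    col = cn if isinstance(cn, str) else f"CN{cn}"
    values = prevalence[col].astype(float)
    if split == "zscore":
        sd = values.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            warnings.warn("constant prevalence; all patients in one group", stacklevel=2)
            return list(values.index), []
        z = (values - values.mean()) / sd
        high = z >= 0
    elif split == "median":
        high = values >= values.median()
    else:
        raise ValueError(f"split must be 'zscore' or 'median', got {split!r}")
    return list(values.index[high]), list(values.index[~high])


def voronoi_render(
    cells: pd.DataFrame,
    labels: Sequence,
    shape_um: tuple[float, float] | None = None,
    ax=None,
    cmap: str = "tab10",
):
    """Render per-cell CN labels as a Voronoi tessellation of centroids.

    Regions are clipped to the image bounds; degenerate (e.g. collinear)
    inputs fall back to a small deterministic jitter with a warning.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib import colormaps
    from scipy.spatial import QhullError, Voronoi

    x = cells["centroid_x_um"].to_numpy(dtype=float)
    y = cells["centroid_y_um"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 cells for a Voronoi rendering")
    labels = np.asarray(labels)
    pts = np.column_stack([x, y])
    try:
        vor = Voronoi(pts)
    except QhullError:
        warnings.warn("degenerate centroid geometry; jittering points", stacklevel=2)
        rng = np.random.default_rng(0)
        vor = Voronoi(pts + rng.normal(scale=1e-3, size=pts.shape))

    if shape_um is None:
        shape_um = (float(y.max() - y.min() + 1), float(x.max() - x.min() + 1))
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    cm = colormaps[cmap]
    uniq = sorted(set(labels.tolist()))
    colour = {lab: cm(i % cm.N) for i, lab in enumerate(uniq)}
    span = float(np.ptp(pts, axis=0).max()) + 1.0
    for poly, lab in zip(_finite_voronoi_polygons(vor, radius=2 * span), labels):
        ax.fill(poly[:, 0], poly[:, 1], color=colour[lab], linewidth=0.2, edgecolor="white")
    ax.set_xlim(x.min(), x.min() + shape_um[1])
    ax.set_ylim(y.min(), y.min() + shape_um[0])
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def _finite_voronoi_polygons(vor, radius: float):
    """Reconstruct finite polygons from a 2-D Voronoi diagram.

    Open regions are closed by extending their infinite ridges ``radius``
    away before clipping; standard construction over ridge midpoints.
    """
    centre = vor.points.mean(axis=0)
    polygons = []
    all_ridges: dict[int, list] = {}
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        all_ridges.setdefault(p1, []).append((p2, v1, v2))
        all_ridges.setdefault(p2, []).append((p1, v1, v2))
    for p1, region_idx in enumerate(vor.point_region):
        vertices = vor.regions[region_idx]
        if all(v >= 0 for v in vertices):
            polygons.append(vor.vertices[vertices])
            continue
        ridges = all_ridges.get(p1, [])
        new_region = [v for v in vertices if v >= 0]
        pts = [vor.vertices[v] for v in new_region]
        for p2, v1, v2 in ridges:
            if v2 < 0:
                v1, v2 = v2, v1
            if v1 >= 0:
                continue
            t = vor.points[p2] - vor.points[p1]
            t = t / np.linalg.norm(t)
            normal = np.array([-t[1], t[0]])
            midpoint = vor.points[[p1, p2]].mean(axis=0)
            direction = np.sign(np.dot(midpoint - centre, normal)) * normal
            pts.append(vor.vertices[v2] + direction * radius)
        pts = np.asarray(pts)
        angle = np.arctan2(pts[:, 1] - pts[:, 1].mean(), pts[:, 0] - pts[:, 0].mean())
        polygons.append(pts[np.argsort(angle)])
    return polygons
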