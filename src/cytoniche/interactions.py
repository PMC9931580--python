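"""Pairwise cell–cell interaction and avoidance permutation tests.

Two cells interact when their centroids are within a fixed radius
(default 6 µm).  For an ordered type pair (A, B) the statistic is the mean
number of B-neighbours per A-cell; the null is built by shuffling the
phenotype labels over all cells of the image with positions (and hence the
neighbour graph) fixed.  One-tailed p-values use the add-one estimator
``(1 + #{null >= observed}) / (n_perm + 1)`` so they are never zero; a pair
is called "interact" or "avoid" at p < 0.01 and results read row-to-column
(A rows, B columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._utils import check_finite_coords

__all__ = [
    "NeighbourGraph",
    "build_graph",
    "permutation_test",
    "permutation_test_all",
    "cohort_heatmap",
    "conditional_contrast",
    "density_category",
    "density_display_values",
]


@dataclass
class NeighbourGraph:
    """Fixed-radius undirected adjacency over one image's cells."""

    image_id: str
    cell_ids: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    radius_um: float
    edges: np.ndarray  # (E, 2) indices into cell_ids, i < j

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def neighbour_counts(self, member: np.ndarray) -> np.ndarray:
        """Per-cell count of neighbours belonging to a boolean subset."""
        counts = np.zeros(self.n_cells, dtype=np.int64)
        if len(self.edges):
            u, v = self.edges[:, 0], self.edges[:, 1]
            np.add.at(counts, u, member[v].astype(np.int64))
            np.add.at(counts, v, member[u].astype(np.int64))
        return counts


def build_graph(
    cells: pd.DataFrame, radius_um: float = 6.0, image_id: str | None = None
) -> NeighbourGraph:
    """Exact fixed-radius neighbour graph from a one-image cell table."""
    if len(cells) < 1:
        raise ValueError("need at least one cell")
    x = cells["centroid_x_um"].to_numpy(dtype=float)
    y = cells["centroid_y_um"].to_numpy(dtype=float)
    check_finite_coords(x, y)
    if image_id is None:
        ids = cells["image_id"].unique() if "image_id" in cells.columns else ["image"]
        if len(ids) > 1:
            raise ValueError("build_graph expects cells from a single image")
        image_id = str(ids[0])
    tree = cKDTree(np.column_stack([x, y]))
    pairs = tree.query_pairs(r=radius_um, output_type="ndarray")
    if len(pairs) == 0:
        pairs = np.empty((0, 2), dtype=np.int64)
    return NeighbourGraph(
        image_id=image_id,
        cell_ids=cells["cell_id"].to_numpy() if "cell_id" in cells.columns else np.arange(len(cells)),
        x_um=x,
        y_um=y,
        radius_um=float(radius_um),
        edges=pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))],
    )


def _directed_counts(codes_u: np.ndarray, codes_v: np.ndarray, n_types: int) -> np.ndarray:
    """Directed type-pair contact counts from edge endpoint type codes."""
    both = np.concatenate([codes_u * n_types + codes_v, codes_v * n_types + codes_u])
    return np.bincount(both, minlength=n_types * n_types).reshape(n_types, n_types)


def permutation_test_all(
    graph: NeighbourGraph,
    labels: Sequence,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    types: Sequence | None = None,
) -> pd.DataFrame:
    """Permutation tests for every ordered type pair of one image.

    ``labels`` aligns with ``graph.cell_ids``.  Pairs for which either type
    is absent from the image are recorded with ``call == "excluded"`` and
    NaN p-values.  Deterministic given ``seed`` (the image's own seed
    should be derived from a master seed and the image id).
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_cells:
        raise ValueError("labels length does not match graph")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is very low for p<{alpha}", stacklevel=2)
    if types is None:
        types = sorted(set(labels))
    types = list(types)
    t_index = {t: i for i, t in enumerate(types)}
    codes = np.array([t_index[l] for l in labels], dtype=np.int64)
    n_types = len(types)
    n_of = np.bincount(codes, minlength=n_types)

    edges = graph.edges
    obs = _directed_counts(codes[edges[:, 0]], codes[edges[:, 1]], n_types) if len(edges) else np.zeros((n_types, n_types), dtype=np.int64)

    rng = np.random.default_rng(seed)
    ge = np.zeros((n_types, n_types), dtype=np.int64)  # null >= observed
    le = np.zeros((n_types, n_types), dtype=np.int64)  # null <= observed
    null_sum = np.zeros((n_types, n_types), dtype=np.float64)
    null_sq = np.zeros((n_types, n_types), dtype=np.float64)

    if len(edges):
        u, v = edges[:, 0], edges[:, 1]
        chunk = max(1, min(n_perm, 4_000_000 // max(len(edges), 1)))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perm = np.repeat(codes[None, :], m, axis=0)
            perm = rng.permuted(perm, axis=1)
            cu, cv = perm[:, u], perm[:, v]
            flat = np.concatenate([cu * n_types + cv, cv * n_types + cu], axis=1)
            flat += (np.arange(m) * n_types * n_types)[:, None]
            counts = np.bincount(flat.ravel(), minlength=m * n_types * n_types)
            counts = counts.reshape(m, n_types, n_types)
            ge += (counts >= obs[None]).sum(axis=0)
            le += (counts <= obs[None]).sum(axis=0)
            null_sum += counts.sum(axis=0)
            null_sq += (counts.astype(np.float64) ** 2).sum(axis=0)
            done += m
    else:
        # no edges: every permutation count is 0 == observed
        ge[:] = n_perm
        le[:] = n_perm

    rows = []
    for a in range(n_types):
        for b in range(n_types):
            n_a, n_b = int(n_of[a]), int(n_of[b])
            base = {
                "image_id": graph.image_id,
                "type_a": types[a],
                "type_b": types[b],
                "n_a": n_a,
                "n_b": n_b,
                "n_perm": n_perm,
            }
            if n_a == 0 or n_b == 0:
                rows.append(
                    base
                    | {
                        "observed": np.nan,
                        "null_mean": np.nan,
                        "null_sd": np.nan,
                        "p_interact": np.nan,
                        "p_avoid": np.nan,
                        "call": "excluded",
                    }
                )
                continue
            p_int = (1 + ge[a, b]) / (n_perm + 1)
            p_avd = (1 + le[a, b]) / (n_perm + 1)
            mean_c = null_sum[a, b] / n_perm
            var_c = max(null_sq[a, b] / n_perm - mean_c**2, 0.0)
            call = "ns"
            if p_int < alpha:
                call = "interact"
            elif p_avd < alpha:
                call = "avoid"
            rows.append(
                base
                | {
                    "observed": obs[a, b] / n_a,
                    "null_mean": mean_c / n_a,
                    "null_sd": np.sqrt(var_c) / n_a,
                    "p_interact": p_int,
                    "p_avoid": p_avd,
                    "call": call,
                }
            )
    return pd.DataFrame(rows)


def permutation_test(
    graph: NeighbourGraph,
    labels: Sequence,
    pair: tuple,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> pd.Series:
    """Single ordered-pair permutation test (row of the all-pairs result)."""
    res = permutation_test_all(graph, labels, n_perm=n_perm, alpha=alpha, seed=seed)
    row = res[(res["type_a"] == pair[0]) & (res["type_b"] == pair[1])]
    if row.empty:
        raise KeyError(f"pair {pair} not present in labels")
    return row.iloc[0]


def cohort_heatmap(results: pd.DataFrame) -> pd.DataFrame:
    """Interaction–avoidance score per ordered pair over a cohort.

    Entry (A, B) = fraction of eligible images called interact minus the
    fraction called avoid, in [-1, 1]; rows are A (read row-to-column).
    """
    eligible = results[results["call"] != "excluded"]
    def _score(grp: pd.DataFrame) -> float:
        return (grp["call"] == "interact").mean() - (grp["call"] == "avoid").mean()

    scores = eligible.groupby(["type_a", "type_b"]).apply(_score, include_groups=False)
    return scores.unstack("type_b")


def conditional_contrast(
    cells: pd.DataFrame,
    graph: NeighbourGraph,
    focal_type: str,
    partner_type: str,
    statistic,
    type_column: str = "lineage",
) -> tuple[np.ndarray, np.ndarray] | None:
    """Split focal cells by contact with a partner type and score each cell.

    A focal cell is "interacting" iff it has at least one partner-type
    neighbour in the graph, else "avoiding".  ``statistic`` is either a
    marker name (per-cell mean expression) or a tuple ``("ratio", num,
    den)`` computed as ``expr_num / (expr_den + eps)`` with eps the
    smallest positive denominator mean in the image (fallback 1e-3).
    Returns ``(interacting_values, avoiding_values)``, or None when either
    sample is empty (the image is excluded from the contrast).
    """
    lab = cells[type_column].to_numpy()
    is_focal = lab == focal_type
    if not is_focal.any():
        return None
    partner_neigh = graph.neighbour_counts(lab == partner_type)
    interacting = is_focal & (partner_neigh > 0)
    avoiding = is_focal & (partner_neigh == 0)
    if not interacting.any() or not avoiding.any():
        return None

    if isinstance(statistic, tuple) and statistic[0] == "ratio":
        _, num, den = statistic
        num_v = cells[f"expr_{num}"].to_numpy(dtype=float)
        den_v = cells[f"expr_{den}"].to_numpy(dtype=float)
        pos = den_v[den_v > 0]
        eps = pos.min() if len(pos) else 1e-3
        values = num_v / (den_v + eps)
    else:
        values = cells[f"expr_{statistic}"].to_numpy(dtype=float)
    return values[interacting], values[avoiding]


def density_category(n_flagged: int, area_mm2: float) -> str:
    """Categorize a per-image density: none / low (1–5 per mm²) / high (>=6)."""
    if area_mm2 <= 0:
        raise ValueError("image area must be positive")
    if n_flagged < 0:
        raise ValueError("negative count")
    rate = n_flagged / area_mm2
    if rate == 0:
        return "none"
    if rate <= 5:
        return "low"
    return "high"


def density_display_values(counts: np.ndarray) -> np.ndarray:
    """Log-scale display convention: images with 0 cells plotted at 1."""
    counts = np.asarray(counts, dtype=float)
    return np.where(counts == 0, 1.0, counts)
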