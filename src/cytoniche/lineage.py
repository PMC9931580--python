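"""Pixel-majority lineage assignment and per-cell expression summaries.

Every pixel of a cell gets a binary presence vector over the curated
lineage-marker masks; summing presence over the cell's pixels gives the
cell's majority vector M.  A lineage's score is the maximum count among its
defining markers, the best-scoring lineage wins, ties go to the higher
rank-priority (earlier) lineage, and an all-zero M is "Undefined".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    EXPR_PREFIX,
    UNDEFINED,
    ChannelStack,
    ConfigurationError,
    GeometryError,
    LineageHierarchy,
    MaskSet,
    SegmentationMask,
)

__all__ = [
    "majority_vectors",
    "assign_lineages",
    "summarize_expression",
    "build_cell_table",
    "SubtypeRule",
    "DEFAULT_SUBTYPE_RULES",
    "apply_subtype_rules",
    "normalize_for_display",
    "zscore_cluster_means",
]


def majority_vectors(
    seg: SegmentationMask, maskset: MaskSet, markers: Sequence[str]
) -> pd.DataFrame:
    """Count, per cell and per marker, the cell's pixels inside the mask.

    Returns a DataFrame indexed by cell_id with one integer column per
    marker plus ``area_px``; exact integer counts.
    """
    labels = seg.labels
    for m in markers:
        if maskset[m].shape != labels.shape:
            raise GeometryError(
                f"mask {m!r} shape {maskset[m].shape} != segmentation {labels.shape}"
            )
    n = int(labels.max())
    cell_ids = seg.cell_ids
    data = {}
    for m in markers:
        counts = np.bincount(labels[maskset[m]], minlength=n + 1)
        data[m] = counts[cell_ids]
    areas = np.bincount(labels.ravel(), minlength=n + 1)[cell_ids]
    out = pd.DataFrame(data, index=pd.Index(cell_ids, name="cell_id"))
    out["area_px"] = areas
    return out


def assign_lineages(
    majority: pd.DataFrame, hierarchy: LineageHierarchy
) -> pd.Series:
    """Assign each cell the lineage with the maximal majority-vector score.

    A lineage's score is the max over its defining markers; the earliest
    hierarchy entry wins ties; all-zero cells are "Undefined".
    """
    marker_cols = [c for c in majority.columns if c != "area_px"]
    missing = hierarchy.all_markers - set(marker_cols)
    if missing:
        raise ConfigurationError(
            f"hierarchy markers without majority-vector columns: {sorted(missing)}"
        )
    scores = np.zeros((len(majority), len(hierarchy)), dtype=np.int64)
    for j, (_, defn) in enumerate(hierarchy.lineages):
        cols = sorted(defn)
        scores[:, j] = majority[cols].to_numpy().max(axis=1)
    # argmax returns the first maximum -> columns are in rank-priority order
    winner = np.argmax(scores, axis=1)
    best = scores[np.arange(len(majority)), winner]
    names = np.array(hierarchy.names, dtype=object)
    assigned = names[winner]
    assigned[best == 0] = UNDEFINED
    return pd.Series(assigned, index=majority.index, name="lineage")


def summarize_expression(seg: SegmentationMask, stack: ChannelStack) -> pd.DataFrame:
    """Per-cell mean raw pixel value for every channel.

    Raw measurements only — no transform is applied before analysis.
    Returns a DataFrame indexed by cell_id with ``expr_<marker>`` columns,
    plus centroids (pixel units; x = column, y = row) and ``area_px``.
    """
    labels = seg.labels
    if labels.shape != stack.shape:
        raise GeometryError(
            f"segmentation {labels.shape} does not match stack {stack.shape}"
        )
    n = int(labels.max())
    cell_ids = seg.cell_ids
    flat = labels.ravel()
    areas_all = np.bincount(flat, minlength=n + 1)
    areas = areas_all[cell_ids]
    data = {}
    for name, channel in zip(stack.channel_names, stack.pixels):
        sums = np.bincount(flat, weights=channel.ravel().astype(float), minlength=n + 1)
        data[EXPR_PREFIX + name] = sums[cell_ids] / areas
    rows, cols = np.indices(labels.shape)
    cy = np.bincount(flat, weights=rows.ravel(), minlength=n + 1)[cell_ids] / areas
    cx = np.bincount(flat, weights=cols.ravel(), minlength=n + 1)[cell_ids] / areas
    out = pd.DataFrame(data, index=pd.Index(cell_ids, name="cell_id"))
    out.insert(0, "centroid_x_um", cx * stack.pixel_size_um)
    out.insert(1, "centroid_y_um", cy * stack.pixel_size_um)
    out.insert(2, "area_px", areas)
    return out


def build_cell_table(
    stack: ChannelStack,
    seg: SegmentationMask,
    maskset: MaskSet,
    hierarchy: LineageHierarchy,
    subtype_rules: "Sequence[SubtypeRule] | None" = None,
) -> pd.DataFrame:
    """Full per-image phenotyping: expression, lineage, subtype flags."""
    lineage_markers = sorted(hierarchy.all_markers)
    extra = [m for m in maskset.masks if m not in lineage_markers]
    mv = majority_vectors(seg, maskset, lineage_markers + extra)
    expr = summarize_expression(seg, stack)
    lin = assign_lineages(mv[lineage_markers + ["area_px"]], hierarchy)
    df = expr.copy()
    df["lineage"] = lin
    df["image_id"] = stack.image_id
    df = df.reset_index()
    if subtype_rules is None:
        subtype_rules = []
    flags = apply_subtype_rules(
        df["lineage"], mv.reset_index(drop=True), subtype_rules
    )
    df["sub_flags"] = flags
    return df


# ------------------------------------------------------------- subtypes


@dataclass(frozen=True)
class SubtypeRule:
    """Marker-positivity rule scoped to a set of lineages.

    A cell is positive for ``marker`` when its majority-vector count is at
    least ``positivity_fraction`` of its pixel area (default 0.25 — robust
    to mask speckle while catching partial membrane staining).  Positive
    cells get ``flag_if_positive``; negative cells get ``flag_if_negative``
    (either may be None).
    """

    marker: str
    lineages: frozenset
    flag_if_positive: str | None = None
    flag_if_negative: str | None = None
    positivity_fraction: float = 0.25


#: microglia vs monocyte-derived macrophage by P2Y12, M1/M2-like by CD163,
#: and the MPO-positive flag, scoped to the macrophage/monocyte compartment
DEFAULT_SUBTYPE_RULES = (
    SubtypeRule("P2Y12", frozenset({"macrophage"}), "microglia", "MDM"),
    SubtypeRule("CD163", frozenset({"macrophage", "monocyte"}), "M2-like", "M1-like"),
    SubtypeRule("MPO", frozenset({"macrophage", "monocyte"}), "MPO_pos", None),
)


def apply_subtype_rules(
    lineages: pd.Series,
    majority: pd.DataFrame,
    rules: Sequence[SubtypeRule],
) -> list:
    """Evaluate positivity rules per cell; returns a list of frozensets."""
    for rule in rules:
        if rule.marker not in majority.columns:
            raise ConfigurationError(
                f"subtype rule references unknown marker {rule.marker!r}"
            )
    areas = majority["area_px"].to_numpy()
    flags = [set() for _ in range(len(lineages))]
    lin = lineages.to_numpy()
    for rule in rules:
        counts = majority[rule.marker].to_numpy()
        in_scope = np.isin(lin, list(rule.lineages))
        positive = counts >= rule.positivity_fraction * areas
        for i in np.nonzero(in_scope)[0]:
            flag = rule.flag_if_positive if positive[i] else rule.flag_if_negative
            if flag is not None:
                flags[i].add(flag)
    return [frozenset(f) for f in flags]


# -------------------------------------------------------------- display


def normalize_for_display(values: np.ndarray, pct: float = 95.0) -> np.ndarray:
    """Divide by the ``pct``-th percentile and clip to [0, 1] (display only)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty values")
    denom = np.percentile(values, pct)
    if denom <= 0:
        warnings.warn("percentile is zero; returning zeros", stacklevel=2)
        return np.zeros_like(values)
    return np.clip(values / denom, 0.0, 1.0)


def zscore_cluster_means(means: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score cluster means across clusters (rows = clusters)."""
    centred = means - means.mean(axis=0)
    sd = means.std(axis=0, ddof=ddof)
    out = centred.div(sd.replace(0.0, np.nan), axis=1)
    return out.fillna(0.0)
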