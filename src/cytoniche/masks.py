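"""Per-marker binary mask curation.

Raw antibody channels are turned into curated foreground masks by a
six-step recipe: (1) 3×3 median filtering, (2) 1-D k-means quantization of
pixel intensities into 6 groups, (3) selecting the brightest L groups as
foreground, (4) removing small connected blobs, (5) optionally intersecting
with a local-mean adaptive-threshold mask, with an optional percentile
contrast-enhancement pre-step (6) for weakly stained channels.

Conventions that the recipe leaves open and that are fixed here:

* "up to a particular level" counts from the *brightest* group down —
  antibody signal is bright-positive.  Group centres are stored in
  ascending order so the opposite convention is a one-line change.
* the adaptive threshold is the local mean over a square window of side
  ``2*floor(min(H, W)/16) + 1``, scaled by sensitivity ``s`` as
  ``T = (1.5 - s) * local_mean`` (s = 0.5 is the neutral point; larger s
  admits more foreground).
* step-5 amalgamation is intersection by default (it is a refinement
  step); union is available via ``combine="union"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import measure
from sklearn.cluster import KMeans

from .model import MarkerSpec

__all__ = [
    "LevelRaster",
    "median_filter_3x3",
    "quantize_levels",
    "select_foreground",
    "remove_small_blobs",
    "adaptive_refine",
    "enhance_contrast",
    "curate_mask",
]

#: cap on pixels used to fit the 1-D k-means; assignment is always exact
_KMEANS_FIT_CAP = 200_000


@dataclass
class LevelRaster:
    """Per-pixel intensity-group raster (values ``1..n_levels``).

    ``group_centres`` are sorted ascending, so level ``n_levels`` is the
    brightest group.
    """

    levels: np.ndarray
    group_centres: np.ndarray
    centre_order: str = "ascending"
    image_id: str = ""
    marker: str = ""

    @property
    def n_levels(self) -> int:
        return len(self.group_centres)


def median_filter_3x3(channel: np.ndarray) -> np.ndarray:
    """3×3 median filter with edge replication at the borders."""
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty raster")
    return ndi.median_filter(channel, size=3, mode="nearest")


def quantize_levels(channel: np.ndarray, k: int = 6, seed: int = 0) -> LevelRaster:
    """Cluster pixel intensities into ``k`` ordered groups by 1-D k-means.

    Groups are relabelled 1..k in ascending centre intensity.  If the
    channel has fewer distinct values than ``k``, each value becomes its
    own group (degenerate path, warned).  With more than 200k pixels the
    centres are fitted on an evenly strided subsample of the sorted values;
    every pixel is then assigned exactly to its nearest centre (a 1-D
    nearest-centre assignment via sorted mid-point boundaries).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    channel = np.asarray(channel, dtype=float)
    flat = channel.ravel()
    distinct = np.unique(flat)
    if distinct.size <= k:
        if distinct.size < k:
            warnings.warn(
                f"only {distinct.size} distinct intensities for k={k}; "
                "one group per distinct value",
                stacklevel=2,
            )
        centres = distinct
        levels = np.searchsorted(distinct, channel) + 1
        return LevelRaster(levels=levels.astype(np.int16), group_centres=centres)

    values = np.sort(flat)
    if values.size > _KMEANS_FIT_CAP:
        idx = np.linspace(0, values.size - 1, _KMEANS_FIT_CAP).astype(np.int64)
        values = values[idx]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(values.reshape(-1, 1))
    centres = np.sort(km.cluster_centers_.ravel())
    boundaries = (centres[:-1] + centres[1:]) / 2.0
    levels = np.searchsorted(boundaries, channel) + 1
    return LevelRaster(levels=levels.astype(np.int16), group_centres=centres)


def select_foreground(level_raster: LevelRaster, level: int) -> np.ndarray:
    """Foreground = union of the ``level`` brightest intensity groups."""
    k = level_raster.n_levels
    if not 1 <= level <= 6:
        raise ValueError(f"foreground level must be in [1, 6], got {level}")
    # fewer groups than requested (degenerate quantization) -> all foreground
    cut = max(k - level, 0)
    return level_raster.levels > cut


def remove_small_blobs(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected components with area < ``min_area`` px²."""
    mask = np.asarray(mask, dtype=bool)
    if min_area <= 1:
        return mask.copy()
    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return sizes[labels] >= min_area


def _local_mean(channel: np.ndarray, window: int) -> np.ndarray:
    return ndi.uniform_filter(channel.astype(float), size=window, mode="nearest")


def adaptive_refine(
    channel: np.ndarray,
    mask: np.ndarray,
    sensitivity: float = 0.4,
    combine: str = "intersection",
) -> np.ndarray:
    """Combine ``mask`` with a local-mean adaptive-threshold mask.

    A pixel is adaptively foreground iff its value exceeds
    ``(1.5 - sensitivity)`` times the local mean over a square window of
    side ``2*floor(min(H, W)/16) + 1``.  The default combination is
    intersection, so the result is a subset of the input mask.
    """
    channel = np.asarray(channel, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if channel.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    window = 2 * (min(channel.shape) // 16) + 1
    adaptive = channel > (1.5 - sensitivity) * _local_mean(channel, window)
    if combine == "intersection":
        return mask & adaptive
    if combine == "union":
        return mask | adaptive
    raise ValueError(f"combine must be 'intersection' or 'union', got {combine!r}")


def enhance_contrast(channel: np.ndarray, low_pct: float, high_pct: float) -> np.ndarray:
    """Saturate the intensity tails and rescale back to the original range.

    Values below the ``low_pct`` percentile and above the ``high_pct``
    percentile are clipped, then linearly mapped back onto the channel's
    original [min, max] range.  Monotone; constant channels are returned
    unchanged with a warning.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    channel = np.asarray(channel, dtype=float)
    lo, hi = np.percentile(channel, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn("constant (or near-constant) channel; enhancement skipped", stacklevel=2)
        return channel.copy()
    clipped = np.clip(channel, lo, hi)
    cmin, cmax = channel.min(), channel.max()
    return (clipped - lo) / (hi - lo) * (cmax - cmin) + cmin


def curate_mask(
    channel: np.ndarray,
    params: MarkerSpec,
    seed: int = 0,
    sensitivity: float = 0.4,
    log: dict | None = None,
) -> np.ndarray:
    """Run the full curation recipe for one channel.

    Order: optional contrast enhancement, median filter, 6-level
    quantization, brightest-``foreground_level`` selection, small-blob
    removal, optional adaptive refinement.  Deterministic given ``seed``.
    If ``log`` is a dict it receives per-step foreground pixel counts.
    """
    work = np.asarray(channel, dtype=float)
    if np.ptp(work) == 0:
        # constant channel: a single intensity group carries no signal
        warnings.warn("constant channel; empty mask", stacklevel=2)
        return np.zeros(work.shape, dtype=bool)
    if params.enhance:
        work = enhance_contrast(work, params.enhance_low_pct, params.enhance_high_pct)
    work = median_filter_3x3(work)
    levels = quantize_levels(work, k=6, seed=seed)
    mask = select_foreground(levels, params.foreground_level)
    if log is not None:
        log["after_select"] = int(mask.sum())
    mask = remove_small_blobs(mask, params.min_blob_area)
    if log is not None:
        log["after_blob_removal"] = int(mask.sum())
    if params.refine:
        mask = adaptive_refine(work, mask, sensitivity=sensitivity)
        if log is not None:
            log["after_refine"] = int(mask.sum())
    return mask


def curate_maskset(stack, panel, seed: int = 0):
    """Curate masks for every marker of a panel over one channel stack."""
    from .model import MaskSet

    masks = {}
    for spec in panel.markers:
        masks[spec.name] = curate_mask(stack.channel(spec.name), spec, seed=seed)
    return MaskSet(image_id=stack.image_id, masks=masks)
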