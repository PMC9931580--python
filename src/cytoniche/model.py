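"""Core data model for multiplexed-imaging spatial analysis.

The pipeline operates on four kinds of objects:

* :class:`ChannelStack` — one multichannel raster per tissue core (one
  channel per metal-tagged antibody), at a known pixel size (1 µm/px for
  imaging mass cytometry).
* :class:`SegmentationMask` — an integer label raster from an upstream cell
  segmenter (0 = background, k > 0 = cell k).
* :class:`MaskSet` — per-marker curated binary foreground rasters produced
  by :mod:`cytoniche.masks`.
* the *cell table* — a :class:`pandas.DataFrame` with one row per cell
  (centroid, area, mean expression per channel, lineage, flags, labels).
  Column conventions are in :data:`CELL_TABLE_COLUMNS`.

Marker panels and lineage hierarchies are plain configuration objects so
they can round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Panel / hierarchy / rule configuration is inconsistent."""


class SchemaError(ValueError):
    """A delimited-text table is missing mandatory columns."""


class GeometryError(ValueError):
    """Pixel/coordinate data is inconsistent with the raster geometry."""


#: mandatory cell-table columns (expression columns are ``expr_<marker>``)
CELL_TABLE_COLUMNS = (
    "cell_id",
    "image_id",
    "centroid_x_um",
    "centroid_y_um",
    "area_px",
)

#: lineage value for cells whose majority vector is all-zero
UNDEFINED = "Undefined"

EXPR_PREFIX = "expr_"


@dataclass(frozen=True)
class MarkerSpec:
    """Per-marker curation parameters.

    Parameters
    ----------
    name : str
        Marker (antibody) name; must be unique within the panel.
    role : {"lineage", "functional"}
        Lineage markers drive phenotyping; functional markers are only
        summarized per cell.
    foreground_level : int
        How many of the 6 intensity groups (brightest first) count as
        foreground when curating this marker's mask; in ``[1, 6]``.
    min_blob_area : int
        Connected components smaller than this (px²) are removed.
    refine : bool
        Apply the adaptive-binarization refinement step.
    enhance : bool
        Apply percentile contrast enhancement before curation.
    enhance_low_pct, enhance_high_pct : float
        Saturation percentiles for the enhancement step.
    """

    name: str
    role: str = "lineage"
    foreground_level: int = 3
    min_blob_area: int = 4
    refine: bool = False
    enhance: bool = False
    enhance_low_pct: float = 1.0
    enhance_high_pct: float = 99.0

    def __post_init__(self):
        if self.role not in ("lineage", "functional"):
            raise ConfigurationError(
                f"marker {self.name!r}: role must be 'lineage' or 'functional', got {self.role!r}"
            )
        if not 1 <= int(self.foreground_level) <= 6:
            raise ConfigurationError(
                f"marker {self.name!r}: foreground_level must be in [1, 6], got {self.foreground_level}"
            )


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered antibody panel; channel order in every stack follows it."""

    markers: tuple[MarkerSpec, ...]

    def __post_init__(self):
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate marker names in panel: {dupes}")
        if not self.lineage_markers:
            raise ConfigurationError("panel must contain at least one lineage marker")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def lineage_markers(self) -> list[str]:
        return [m.name for m in self.markers if m.role == "lineage"]

    @property
    def functional_markers(self) -> list[str]:
        return [m.name for m in self.markers if m.role == "functional"]

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, name: str) -> MarkerSpec:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)


@dataclass
class ChannelStack:
    """One core image: channels × height × width, non-negative intensities."""

    image_id: str
    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float = 1.0
    tissue_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise GeometryError("pixels must be 3-D (channel, height, width)")
        if self.pixels.shape[0] != len(self.channel_names):
            raise ConfigurationError(
                f"{self.pixels.shape[0]} pages but {len(self.channel_names)} channel names"
            )
        if self.pixels.shape[1] < 1 or self.pixels.shape[2] < 1:
            raise GeometryError("empty raster")
        if np.any(self.pixels < 0):
            raise ValueError("negative intensities in channel stack")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(f"channel {name!r} not in stack {self.image_id!r}") from None
        return self.pixels[idx]

    @property
    def area_mm2(self) -> float:
        h, w = self.shape
        return h * w * (self.pixel_size_um / 1000.0) ** 2


@dataclass
class SegmentationMask:
    """Integer cell-label raster aligned to a :class:`ChannelStack`."""

    image_id: str
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise GeometryError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise GeometryError("label mask must be integer-typed")
        if self.labels.min() < 0:
            raise GeometryError("negative labels in segmentation mask")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)


@dataclass
class MaskSet:
    """Curated binary foreground rasters, one per panel marker."""

    image_id: str
    masks: dict[str, np.ndarray]

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GeometryError(f"mask shapes disagree: {shapes}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    def __getitem__(self, marker: str) -> np.ndarray:
        return self.masks[marker]

    def __contains__(self, marker: str) -> bool:
        return marker in self.masks


@dataclass(frozen=True)
class LineageHierarchy:
    """Rank-priority list of lineages and their defining lineage markers.

    Order is the tie-break priority: index 0 wins ties.  A lineage's score
    for a cell is the maximum of its defining markers' majority-vector
    counts, so multi-marker lineages do not double-count co-stains.
    """

    lineages: tuple[tuple[str, frozenset], ...]

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, Sequence[str]]]) -> "LineageHierarchy":
        return cls(tuple((name, frozenset(markers)) for name, markers in pairs))

    def __post_init__(self):
        names = [n for n, _ in self.lineages]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate lineage names in hierarchy")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.lineages]

    @property
    def all_markers(self) -> set:
        out: set = set()
        for _, mk in self.lineages:
            out |= set(mk)
        return out

    def validate_against(self, panel: MarkerPanel) -> None:
        missing = self.all_markers - set(panel.lineage_markers)
        if missing:
            raise ConfigurationError(
                f"hierarchy markers not in panel lineage markers: {sorted(missing)}"
            )

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient survival record; one record per patient."""

    patient_id: str
    overall_survival_days: float
    event: bool  # True = death observed, False = censored at last follow-up
    group_labels: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self):
        if not self.overall_survival_days > 0:
            raise ValueError(
                f"patient {self.patient_id!r}: survival time must be > 0, "
                f"got {self.overall_survival_days}"
            )


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check mandatory columns and basic invariants of a cell table."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing mandatory columns: {missing}")
    expr = [c for c in df.columns if c.startswith(EXPR_PREFIX)]
    if expr and (df[expr].to_numpy(dtype=float) < 0).any():
        raise ValueError("negative mean expression values in cell table")
    return df


def expr_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(EXPR_PREFIX)]
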