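"""Reading and writing external formats.

Images travel as multi-page TIFF (one page per channel) with channel names
recorded in the ImageDescription tag as JSON; segmentation masks as
single-page integer TIFF; cell and clinical tables as headered CSV; panels
and lineage hierarchies as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import (
    ChannelStack,
    ClinicalRecord,
    ConfigurationError,
    LineageHierarchy,
    MarkerPanel,
    MarkerSpec,
    SchemaError,
    SegmentationMask,
    validate_cell_table,
)

__all__ = [
    "read_channel_stack",
    "write_channel_stack",
    "read_segmentation",
    "write_segmentation",
    "read_cell_table",
    "write_cell_table",
    "read_panel",
    "write_panel",
    "read_hierarchy",
    "write_hierarchy",
    "read_clinical",
    "write_clinical",
    "attach_clinical",
    "patient_average",
]

_DESC_KEY = "cytoniche"


# ---------------------------------------------------------------- images


def write_channel_stack(stack: ChannelStack, path) -> None:
    """Write a multi-page TIFF, one page per channel, names in the description."""
    desc = json.dumps(
        {
            _DESC_KEY: {
                "image_id": stack.image_id,
                "channel_names": list(stack.channel_names),
                "pixel_size_um": stack.pixel_size_um,
                "tissue_meta": stack.tissue_meta,
            }
        }
    )
    tifffile.imwrite(
        str(path),
        stack.pixels,
        description=desc,
        metadata=None,
        photometric="minisblack",
    )


def read_channel_stack(
    path,
    panel: MarkerPanel,
    *,
    assume_panel_order: bool = False,
) -> ChannelStack:
    """Read a multichannel TIFF and align channels to the panel order.

    Channel names are taken from the TIFF description when present and the
    pages are reordered to match the panel.  Nameless files are accepted
    only with ``assume_panel_order=True`` (a silent order mismatch is the
    dominant failure mode for these panels, so the opt-in is explicit).
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        pixels = tf.asarray()
        desc = tf.pages[0].description or ""
    if pixels.ndim == 2:
        pixels = pixels[None]
    meta = {}
    try:
        meta = json.loads(desc).get(_DESC_KEY, {})
    except (json.JSONDecodeError, AttributeError):
        meta = {}

    names = meta.get("channel_names")
    if names is not None:
        missing = [m for m in panel.names if m not in names]
        if missing:
            raise ConfigurationError(
                f"{path.name}: channels missing for panel markers {missing}"
            )
        order = [names.index(m) for m in panel.names]
        pixels = pixels[order]
    else:
        if pixels.shape[0] != len(panel):
            raise ConfigurationError(
                f"{path.name}: {pixels.shape[0]} unnamed pages for a "
                f"{len(panel)}-marker panel (markers: {panel.names})"
            )
        if not assume_panel_order:
            raise ConfigurationError(
                f"{path.name}: no channel names in TIFF metadata; pass "
                "assume_panel_order=True to map pages to the panel by position"
            )
    return ChannelStack(
        image_id=meta.get("image_id", path.stem),
        pixels=pixels,
        channel_names=list(panel.names),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        tissue_meta=meta.get("tissue_meta", {}),
    )


def write_segmentation(seg: SegmentationMask, path) -> None:
    tifffile.imwrite(
        str(path),
        seg.labels.astype(np.int32),
        description=json.dumps({_DESC_KEY: {"image_id": seg.image_id}}),
        metadata=None,
    )


def read_segmentation(path) -> SegmentationMask:
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        labels = tf.asarray()
        desc = tf.pages[0].description or ""
    try:
        image_id = json.loads(desc)[_DESC_KEY]["image_id"]
    except (json.JSONDecodeError, KeyError, TypeError):
        image_id = path.stem
    return SegmentationMask(image_id=image_id, labels=np.asarray(labels).astype(np.int64))


# ---------------------------------------------------------------- tables

_LIST_SEP = ";"


def write_cell_table(df: pd.DataFrame, path) -> None:
    """Write a cell table as CSV; set-valued ``sub_flags`` joined with ';'."""
    out = df.copy()
    if "sub_flags" in out.columns:
        out["sub_flags"] = [
            _LIST_SEP.join(sorted(v)) if isinstance(v, (set, frozenset, list, tuple)) else (v or "")
            for v in out["sub_flags"]
        ]
    out.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_cell_table(df)
    if "sub_flags" in df.columns:
        df["sub_flags"] = [
            frozenset(str(v).split(_LIST_SEP)) if isinstance(v, str) and v else frozenset()
            for v in df["sub_flags"].fillna("")
        ]
    return df


# ---------------------------------------------------------------- configs


def write_panel(panel: MarkerPanel, path) -> None:
    data = {
        "markers": [
            {
                "name": m.name,
                "role": m.role,
                "foreground_level": m.foreground_level,
                "min_blob_area": m.min_blob_area,
                "refine": m.refine,
                "enhance": m.enhance,
                "enhance_low_pct": m.enhance_low_pct,
                "enhance_high_pct": m.enhance_high_pct,
            }
            for m in panel.markers
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_panel(path) -> MarkerPanel:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "markers" not in data:
        raise SchemaError(f"{path}: panel config must have a top-level 'markers' list")
    return MarkerPanel(tuple(MarkerSpec(**m) for m in data["markers"]))


def write_hierarchy(hierarchy: LineageHierarchy, path) -> None:
    data = {"lineages": [{"name": n, "markers": sorted(mk)} for n, mk in hierarchy.lineages]}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_hierarchy(path) -> LineageHierarchy:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "lineages" not in data:
        raise SchemaError(f"{path}: hierarchy config must have a top-level 'lineages' list")
    return LineageHierarchy.from_pairs(
        [(d["name"], d["markers"]) for d in data["lineages"]]
    )


def write_clinical(records: Iterable[ClinicalRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "overall_survival_days": r.overall_survival_days,
            "event": int(r.event),
        }
        row.update(r.group_labels)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clinical(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    needed = {"patient_id", "overall_survival_days", "event"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: clinical table missing columns {sorted(missing)}")
    extra = [c for c in df.columns if c not in needed]
    out = []
    for _, row in df.iterrows():
        out.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                overall_survival_days=float(row["overall_survival_days"]),
                event=bool(int(row["event"])),
                group_labels={c: row[c] for c in extra},
            )
        )
    return out


# --------------------------------------------------------- clinical join


def attach_clinical(
    per_image: pd.DataFrame, clinical: Sequence[ClinicalRecord]
) -> pd.DataFrame:
    """Join per-image features with clinical records.

    ``per_image`` must carry ``image_id`` and ``patient_id`` columns; every
    patient_id must have a clinical record.  Returns the joined frame (one
    row per image); use :func:`patient_average` before any survival use so
    each patient contributes a single value.
    """
    if "patient_id" not in per_image.columns:
        raise SchemaError("per-image table must carry a patient_id column")
    clin_df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in clinical],
            "overall_survival_days": [r.overall_survival_days for r in clinical],
            "event": [r.event for r in clinical],
        }
    )
    for r in clinical:
        for k, v in r.group_labels.items():
            clin_df.loc[clin_df["patient_id"] == r.patient_id, k] = v
    unmatched = sorted(
        set(per_image["patient_id"].astype(str)) - set(clin_df["patient_id"].astype(str))
    )
    if unmatched:
        raise KeyError(f"patient_ids without clinical records: {unmatched}")
    merged = per_image.copy()
    merged["patient_id"] = merged["patient_id"].astype(str)
    return merged.merge(clin_df, on="patient_id", how="left", validate="many_to_one")


def patient_average(joined: pd.DataFrame, feature_cols: Sequence[str]) -> pd.DataFrame:
    """Average per-image features within each patient.

    Duplicate cores from the same tumour are averaged so each patient has a
    single value in any survival analysis; survival columns are carried
    through unchanged (they are constant within a patient).
    """
    keep = [c for c in ("overall_survival_days", "event") if c in joined.columns]
    agg = {c: "mean" for c in feature_cols}
    agg.update({c: "first" for c in keep})
    return joined.groupby("patient_id", as_index=False).agg(agg)
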