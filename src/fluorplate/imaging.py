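"""Fluorescence image stacks: I/O, leaf-section segmentation, ROI means.

A measurement session produces one pair of frames per saturating pulse —
the steady-state frame (F or F') captured just before the pulse and the
maximal frame (Fm or Fm') captured during it.  This module reads such
stacks (multi-page TIFF + sidecar pulse-metadata CSV), segments the
individual leaf sections from the dark-adapted Fm frame, assigns grid
sample IDs, and reduces each (section, pulse) to mean fluorescence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "FrameStack",
    "ROISet",
    "FormatError",
    "read_dataset",
    "segment_plate",
    "assign_sample_ids",
    "extract_pulse_records",
    "PULSE_METADATA_COLUMNS",
]

PULSE_METADATA_COLUMNS = ["pulse_index", "time_s", "ppfd", "f_page", "fm_page", "label"]

FRAMES_FILENAME = "frames.tif"
PULSES_FILENAME = "pulses.csv"


class FormatError(ValueError):
    """Raised when a dataset on disk is missing pieces or inconsistent."""


@dataclass
class FrameStack:
    """Pulse-indexed fluorescence frames plus per-pulse metadata.

    Attributes
    ----------
    frames : ndarray, shape (n_pulses, 2, height, width)
        Axis 1 holds the two frame roles: index 0 the steady-state frame
        (F/F'), index 1 the maximal frame (Fm/Fm').  Counts, >= 0.
    metadata : DataFrame
        One row per pulse: ``pulse_index, time_s, ppfd, label`` (and the
        TIFF page indices ``f_page, fm_page`` when read from disk).
    """

    frames: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[1] != 2:
            raise ValueError(
                f"frames must have shape (n_pulses, 2, h, w), got {self.frames.shape}"
            )
        if np.any(self.frames < 0):
            raise ValueError("fluorescence counts must be >= 0")
        if len(self.metadata) != self.frames.shape[0]:
            raise ValueError(
                f"metadata rows ({len(self.metadata)}) != pulse count "
                f"({self.frames.shape[0]})"
            )
        n_dark = int((self.metadata["label"] == "dark").sum())
        if n_dark != 1:
            raise ValueError(f"expected exactly one 'dark' pulse, found {n_dark}")

    @property
    def n_pulses(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[2], self.frames.shape[3]

    def dark_pulse_index(self) -> int:
        return int(self.metadata.index[self.metadata["label"] == "dark"][0])

    def fm_dark_frame(self) -> np.ndarray:
        """The dark-adapted Fm frame (highest-contrast segmentation target)."""
        return self.frames[self.dark_pulse_index(), 1]


@dataclass
class ROISet:
    """Labelled leaf-section regions on the plate.

    ``label_map`` assigns each pixel an integer label (0 = background,
    1..n contiguous).  ``table`` has one row per label: ``label,
    sample_id, centroid_row, centroid_col, area_px``.
    """

    label_map: np.ndarray
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        labels = np.unique(self.label_map)
        labels = labels[labels > 0]
        expected = np.arange(1, len(labels) + 1)
        if not np.array_equal(labels, expected):
            raise ValueError("ROI labels must be contiguous from 1")
        if len(self.table) != len(labels):
            raise ValueError("ROI table rows must match label count")

    @property
    def n_rois(self) -> int:
        return len(self.table)

    def write(self, directory: str | Path) -> None:
        """Write the label map (16-bit TIFF) and per-ROI CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(directory / "roi_labels.tif",
                         self.label_map.astype(np.uint16))
        self.table.to_csv(directory / "rois.csv", index=False)


def read_dataset(directory: str | Path) -> FrameStack:
    """Read a pulse-indexed TIFF/CSV dataset from ``directory``.

    The page -> (pulse, role) mapping is taken from the ``f_page`` and
    ``fm_page`` columns of the metadata, never from page-order
    assumptions.  Pages the metadata does not reference are ignored with
    a warning.
    """
    directory = Path(directory)
    tif_path = directory / FRAMES_FILENAME
    csv_path = directory / PULSES_FILENAME
    for p in (tif_path, csv_path):
        if not p.exists():
            raise FormatError(f"dataset file missing: {p}")
    meta = pd.read_csv(csv_path)
    missing = set(PULSE_METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise FormatError(f"{csv_path}: missing metadata columns {sorted(missing)}")
    pages = tifffile.imread(tif_path)
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    meta = meta.sort_values("pulse_index").reset_index(drop=True)
    frames = np.empty((len(meta), 2) + pages.shape[1:], dtype=pages.dtype)
    referenced: set[int] = set()
    for i, row in meta.iterrows():
        for role, col in enumerate(("f_page", "fm_page")):
            page = int(row[col])
            if not 0 <= page < n_pages:
                raise FormatError(
                    f"pulse {int(row['pulse_index'])}: {col}={page} not in "
                    f"TIFF with {n_pages} pages"
                )
            frames[i, role] = pages[page]
            referenced.add(page)
    unused = n_pages - len(referenced)
    if unused:
        warnings.warn(
            f"{tif_path}: {unused} TIFF page(s) not referenced by metadata; ignored",
            RuntimeWarning,
            stacklevel=2,
        )
    return FrameStack(frames=frames, metadata=meta)


def segment_plate(
    fm_dark_frame: np.ndarray,
    min_area: int = 64,
    threshold_method: str = "otsu",
    threshold: float | None = None,
) -> ROISet:
    """Segment leaf sections from the dark-adapted Fm frame.

    Foreground is thresholded (Otsu by default, or a fixed value),
    hole-filled, and split into 8-connected components; components below
    ``min_area`` pixels are discarded.  Returns an empty ROISet with a
    warning if nothing survives.
    """
    frame = np.asarray(fm_dark_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("fm_dark_frame must be 2-D")
    if threshold_method == "otsu":
        thresh = threshold_otsu(frame)
    elif threshold_method == "fixed":
        if threshold is None:
            raise ValueError("fixed threshold_method requires a threshold value")
        thresh = float(threshold)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    mask = frame > thresh
    mask = ndimage.binary_fill_holes(mask)
    labelled = cc_label(mask, connectivity=2)
    rows = []
    for prop in regionprops(labelled):
        if prop.area < min_area:
            labelled[labelled == prop.label] = 0
            continue
        rows.append(
            {
                "label": prop.label,
                "centroid_row": prop.centroid[0],
                "centroid_col": prop.centroid[1],
                "area_px": int(prop.area),
            }
        )
    if not rows:
        warnings.warn(
            "segmentation found no components above min_area",
            RuntimeWarning,
            stacklevel=2,
        )
        return ROISet(label_map=np.zeros_like(labelled), table=pd.DataFrame(
            columns=["label", "sample_id", "centroid_row", "centroid_col", "area_px"]
        ))
    # relabel contiguous 1..n, ordered by original label
    table = pd.DataFrame(rows).sort_values("label").reset_index(drop=True)
    relabel = np.zeros(labelled.max() + 1, dtype=labelled.dtype)
    for new, old in enumerate(table["label"], start=1):
        relabel[old] = new
    labelled = relabel[labelled]
    table["label"] = np.arange(1, len(table) + 1)
    table["sample_id"] = table["label"]
    table = table[["label", "sample_id", "centroid_row", "centroid_col", "area_px"]]
    return ROISet(label_map=labelled, table=table)


def assign_sample_ids(rois: ROISet, n_rows: int, n_cols: int) -> ROISet:
    """Assign sample IDs in reading order on an ``n_rows`` x ``n_cols`` grid.

    The frame height is divided into ``n_rows`` equal bands; ROIs are
    sorted by the band their centroid falls in, then by centroid column
    (ties: smaller row, then smaller column).  IDs run 1..n row-major.
    """
    if rois.n_rois > n_rows * n_cols:
        raise ValueError(
            f"{rois.n_rois} ROIs exceed the {n_rows}x{n_cols} grid; "
            "consider increasing min_area"
        )
    if rois.n_rois == 0:
        return rois
    height = rois.label_map.shape[0]
    band_height = height / n_rows
    table = rois.table.copy()
    table["_band"] = np.minimum(
        (table["centroid_row"] // band_height).astype(int), n_rows - 1
    )
    order = table.sort_values(
        ["_band", "centroid_col", "centroid_row"], kind="mergesort"
    ).index
    table.loc[order, "sample_id"] = np.arange(1, len(table) + 1)
    table = table.drop(columns="_band")
    return ROISet(label_map=rois.label_map, table=table)


def extract_pulse_records(stack: FrameStack, rois: ROISet) -> pd.DataFrame:
    """ROI-mean fluorescence per (sample, pulse).

    Returns a tidy table with columns ``sample_id, time_s, ppfd, label,
    f_mean, fm_mean, flags``.  Rows where the maximal frame mean falls
    below the steady-state mean are flagged ``fm_lt_f`` rather than
    dropped or clamped.
    """
    if rois.label_map.shape != stack.shape:
        raise ValueError(
            f"ROI map shape {rois.label_map.shape} != frame shape {stack.shape}"
        )
    labels = rois.table["label"].to_numpy()
    sample_ids = rois.table["sample_id"].to_numpy()
    rows = []
    for i, meta in stack.metadata.iterrows():
        f_means = ndimage.mean(stack.frames[i, 0], labels=rois.label_map, index=labels)
        fm_means = ndimage.mean(stack.frames[i, 1], labels=rois.label_map, index=labels)
        for sid, f_m, fm_m in zip(sample_ids, f_means, fm_means):
            rows.append(
                {
                    "sample_id": int(sid),
                    "time_s": float(meta["time_s"]),
                    "ppfd": float(meta["ppfd"]),
                    "label": str(meta["label"]),
                    "f_mean": float(f_m),
                    "fm_mean": float(fm_m),
                    "flags": "fm_lt_f" if fm_m < f_m else "",
                }
            )
    return pd.DataFrame(rows).sort_values(["sample_id", "time_s"]).reset_index(drop=True)
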