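"""On-disk artifacts: label masks, multichannel images, feature tables, configs.

Conventions fixed here and relied on everywhere else:

* coordinates are 0-based, row-major, ``(row, col)`` ordered;
* label masks are single-plane 32-bit integer TIFFs, background = 0, and
  label values are never remapped on the way in or out;
* multichannel images are stored channel-first (CYX), one TIFF page per
  channel;
* feature tables are CSV with columns
  ``cell_id, <marker...>, area, centroid_row, centroid_col``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, ValidationError


@dataclass
class LabelMask:
    """2D integer image assigning each pixel a cell ID (0 = background)."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(f"label mask must be 2D, got {self.pixels.ndim}D")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValidationError(f"label mask must be integer, got {self.pixels.dtype}")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValidationError("label mask contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def labels(self) -> np.ndarray:
        """Sorted unique nonzero cell IDs present in the mask."""
        lab = np.unique(self.pixels)
        return lab[lab > 0]

    def n_cells(self) -> int:
        return self.labels().size

    def copy(self) -> "LabelMask":
        return LabelMask(self.pixels.copy())


@dataclass
class MultichannelImage:
    """Channel-first (C, rows, cols) stack of marker intensities."""

    pixels: np.ndarray
    channel_names: list[str]
    nucleus_channel: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.channel_names = list(self.channel_names)
        if self.pixels.ndim != 3:
            raise ValidationError("multichannel image must be 3D (channels, rows, cols)")
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValidationError(
                f"{self.pixels.shape[0]} pages but {len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if self.nucleus_channel not in self.channel_names:
            raise ValidationError(f"nucleus channel {self.nucleus_channel!r} not in panel")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[self.channel_names.index(name)]

    @property
    def marker_names(self) -> list[str]:
        """All channels except the nucleus channel."""
        return [c for c in self.channel_names if c != self.nucleus_channel]


@dataclass
class StudyConfig:
    """Configuration of a full perturbation study (levels x replicates)."""

    levels: list[float] = field(default_factory=lambda: [100.0, 90.0, 80.0, 70.0])
    replicates: int = 5
    master_seed: int = 0
    knn_sizes: list[int] = field(default_factory=lambda: [15, 50, 100])
    kmeans_range: list[int] = field(default_factory=lambda: [3, 10, 30])
    leiden_knn: list[int] = field(default_factory=lambda: [15, 50])
    preprocessing: list[str] = field(default_factory=lambda: ["raw", "log1p"])
    qc_min_area: int = 10
    qc_max_area_factor: float = 5.0
    calibration_replicates: int = 3
    area_tolerance: float = 0.1

    def __post_init__(self):
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for lv in self.levels:
            if not 0 < lv <= 100:
                raise ValidationError(f"target F1 level {lv} outside (0, 100]")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def read_label_mask(path) -> LabelMask:
    """Read a single-plane integer TIFF as a label mask, values untouched."""
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise FormatError(f"{path}: expected single-plane TIFF, got {len(tf.pages)} pages")
        arr = tf.asarray()
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: label mask pixels must be integer, got {arr.dtype}")
    if arr.ndim != 2:
        raise FormatError(f"{path}: label mask must be a single 2D plane, got {arr.shape}")
    return LabelMask(arr)


def write_label_mask(mask: LabelMask, path) -> None:
    tifffile.imwrite(path, mask.pixels.astype(np.int32, copy=False))


def read_multichannel_image(path, channel_names, nucleus_channel) -> MultichannelImage:
    """Read a multi-page TIFF with one page per named channel."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(channel_names):
        raise FormatError(
            f"{path}: {arr.shape[0]} pages but {len(channel_names)} channel names"
        )
    return MultichannelImage(arr, list(channel_names), nucleus_channel)


def write_multichannel_image(image: MultichannelImage, path) -> None:
    tifffile.imwrite(path, np.asarray(image.pixels))


def write_feature_table(table, path) -> None:
    """Write a feature table as CSV (full float precision)."""
    df = table.to_frame()
    if df.index.duplicated().any():
        raise ValidationError("feature table has duplicate cell IDs")
    df.to_csv(path, index=True, index_label="cell_id", float_format="%.17g")


def read_feature_table(path):
    from .features import FeatureTable

    df = pd.read_csv(path, index_col="cell_id")
    markers = [c for c in df.columns if c not in ("area", "centroid_row", "centroid_col")]
    return FeatureTable(df, markers=markers)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
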