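"""Reading/writing scintigrams, lesion masks, and dataset manifests.

Scintigrams are 2-D arrays of nonnegative radiotracer counts (16-bit range,
never 0-255 display intensities). The canonical on-disk format is 16-bit
grayscale TIFF; 16-bit grayscale PNG is accepted too. Masks are stored as
8-bit PNG with {0, 255} and binarized to {0, 1} on read.

The manifest is a CSV with columns ``patient_id,view,image_path,mask_path,
split``. Each examination yields an anterior and a posterior image; the two
views of one patient always travel together through a train/test split so
that near-duplicate anatomy never leaks across the split boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, FormatError, PairingError

__all__ = [
    "Scintigram", "LesionMask", "DatasetManifest",
    "read_scintigram", "write_scintigram", "read_mask", "write_mask",
    "split_by_patient",
]

MANIFEST_COLUMNS = ["patient_id", "view", "image_path", "mask_path", "split"]
VIEWS = ("anterior", "posterior")
SPLITS = ("train", "test", "unassigned")


@dataclass
class Scintigram:
    """A planar bone-scan image: nonnegative integer counts per pixel."""

    pixels: np.ndarray
    pixel_pitch_mm: float = 2.26

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"scintigram must be 2-D, got ndim={px.ndim}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise FormatError(f"scintigram smaller than 8x8: {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise FormatError(f"scintigram pixels must be integer counts, got {px.dtype}")
        if px.min() < 0:
            raise FormatError("scintigram contains negative counts")
        if px.max() > np.iinfo(np.uint16).max:
            raise FormatError("scintigram counts exceed the 16-bit range")
        self.pixels = px.astype(np.uint16)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LesionMask:
    """Binary gold-standard lesion mask, same shape as its scintigram."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"mask must be 2-D, got ndim={px.ndim}")
        vals = np.unique(px)
        if not np.isin(vals, (0, 1)).all():
            raise FormatError(f"mask values must be binary, found {vals[:5]}")
        self.pixels = px.astype(np.uint8)

    def check_pair(self, image: Scintigram) -> None:
        if self.pixels.shape != image.pixels.shape:
            raise PairingError(
                f"mask shape {self.pixels.shape} != image shape {image.pixels.shape}")


def read_scintigram(path: str | Path, pixel_pitch_mm: float = 2.26) -> Scintigram:
    """Read a 16-bit single-channel raster; counts are returned unmodified."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel raster, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: expected integer pixel type, got {arr.dtype}")
    return Scintigram(arr, pixel_pitch_mm)


def write_scintigram(path: str | Path, image: Scintigram) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)


def read_mask(path: str | Path, pair: Scintigram | None = None) -> LesionMask:
    """Read a single-channel raster; any pixel > 0 maps to foreground."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel mask, got shape {arr.shape}")
    mask = LesionMask((arr > 0).astype(np.uint8))
    if pair is not None:
        mask.check_pair(pair)
    return mask


def write_mask(path: str | Path, mask: LesionMask) -> None:
    iio.imwrite(Path(path), (mask.pixels * np.uint8(255)))


@dataclass
class DatasetManifest:
    """Table of (patient, view, paths, split) records."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=MANIFEST_COLUMNS))

    def __post_init__(self):
        df = self.records
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        bad_views = set(df["view"]) - set(VIEWS)
        if bad_views:
            raise FormatError(f"unknown views in manifest: {sorted(bad_views)}")
        bad_splits = set(df["split"]) - set(SPLITS)
        if bad_splits:
            raise FormatError(f"unknown splits in manifest: {sorted(bad_splits)}")
        per_patient = df.groupby("patient_id")["split"].nunique()
        leaky = per_patient[per_patient > 1]
        if len(leaky):
            raise PairingError(
                f"patients with records in multiple splits: {list(leaky.index)[:5]}")
        self.records = df.reset_index(drop=True)

    @property
    def patients(self) -> list[str]:
        return sorted(self.records["patient_id"].unique())

    def subset(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split].reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        return cls(pd.read_csv(Path(path), dtype=str))


def split_by_patient(manifest: DatasetManifest, train_fraction: float,
                     seed: int) -> DatasetManifest:
    """Assign whole patients to train/test; both views stay together.

    Patients (not images) are shuffled with ``seed`` and the first
    ``round(train_fraction * n_patients)`` go to the training split. The
    same (manifest, fraction, seed) triple always yields the same split.
    """
    df = manifest.records
    if not (df["split"] == "unassigned").all():
        raise ConfigurationError("split_by_patient requires all records unassigned")
    patients = sorted(df["patient_id"].unique())
    if len(patients) < 2:
        raise ConfigurationError("need at least 2 distinct patients to split")
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError(f"train_fraction must be in (0,1), got {train_fraction}")
    n_train = int(round(train_fraction * len(patients)))
    if n_train == 0 or n_train == len(patients):
        raise ConfigurationError(
            f"train_fraction {train_fraction} leaves an empty split "
            f"({n_train}/{len(patients)} train patients)")
    order = np.random.default_rng(seed).permutation(len(patients))
    train_set = {patients[i] for i in order[:n_train]}
    out = df.copy()
    out["split"] = np.where(out["patient_id"].isin(train_set), "train", "test")
    return DatasetManifest(out)
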