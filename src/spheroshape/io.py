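"""Image and table input/output.

Owns all format and unit conventions of the pipeline:

* pixel coordinates: x = column index, y = row index, origin at the
  top-left pixel center;
* intensities are read without rescaling; RGB collapses to Rec. 601 luma;
* areas are always reported in px² and additionally in µm² when a physical
  pixel size (µm/pixel) is supplied — the pipeline never guesses a scale;
* tabular output is UTF-8 CSV with '.' decimals at full repr precision.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Rec. 601 luma weights used to collapse RGB input to a single channel.
_LUMA_601 = np.array([0.299, 0.587, 0.114])

MIN_IMAGE_SIDE_PX = 64

COUNT_COLUMNS = ["condition_label", "well_id", "field_id", "migrated_cell_count"]


@dataclass
class GrayImage:
    """Single-channel intensity raster with an optional physical scale.

    Parameters
    ----------
    pixels : ndarray
        2-D non-negative intensity grid, row-major (``pixels[y, x]``).
    pixel_size_um : float, optional
        Physical pixel size in µm/pixel; strictly positive when present.
    source_id : str
        Free-text provenance label (file name, synthetic spec, ...).
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"expected a 2-D grid, got shape {px.shape}")
        if px.shape[0] < MIN_IMAGE_SIDE_PX or px.shape[1] < MIN_IMAGE_SIDE_PX:
            raise ValidationError(
                f"image {px.shape[0]}x{px.shape[1]} is smaller than the "
                f"{MIN_IMAGE_SIDE_PX}x{MIN_IMAGE_SIDE_PX} minimum"
            )
        if not np.all(np.isfinite(px.astype(np.float64, copy=False))):
            raise ValidationError("image contains non-finite intensities")
        if px.min() < 0:
            raise ValidationError("image contains negative intensities")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValidationError(
                f"pixel_size_um must be strictly positive, got {self.pixel_size_um}"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CountTable:
    """Migrated-cell counts of a transwell invasion assay.

    One row per counted microscope field:
    ``(condition_label, well_id, field_id, migrated_cell_count)``.
    By convention three fields are counted per well; other field counts are
    accepted when ``fields_per_well`` is set accordingly (or ``None`` to
    disable the check).
    """

    frame: pd.DataFrame
    fields_per_well: int | None = 3

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"count table is missing column(s): {missing}")
        counts = df["migrated_cell_count"]
        for i, v in counts.items():
            if pd.isna(v) or float(v) != int(v):
                raise ValidationError(
                    f"row {i}: migrated_cell_count {v!r} is not an integer"
                )
            if int(v) < 0:
                raise ValidationError(f"row {i}: migrated_cell_count {v!r} is negative")
        df = df.copy()
        df["migrated_cell_count"] = counts.astype(np.int64)
        if self.fields_per_well is not None:
            per_well = df.groupby(["condition_label", "well_id"]).size()
            bad = per_well[per_well != self.fields_per_well]
            if len(bad):
                key = bad.index[0]
                raise ValidationError(
                    f"well {key} has {bad.iloc[0]} field rows, expected "
                    f"{self.fields_per_well} (set fields_per_well to override)"
                )
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)


def read_image(path: str | os.PathLike, pixel_size_um: float | None = None) -> GrayImage:
    """Read a TIFF or PNG micrograph as a :class:`GrayImage`.

    8/16-bit single-channel rasters are read verbatim; RGB(A) input is
    collapsed to luminance with Rec. 601 weights. Intensities are never
    rescaled.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"cannot read image: no such file: {path}")
    try:
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            arr = tifffile.imread(path)
        else:
            from PIL import Image

            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:  # decoding failure, truncated file, ...
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise IOError(f"cannot read image {path}: no image data (truncated file?)")
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValidationError(f"{path}: unsupported channel count {arr.shape[2]}")
        arr = arr.astype(np.float64) @ _LUMA_601
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"{path}: not a 2-D image (shape {arr.shape})")
    return GrayImage(arr, pixel_size_um=pixel_size_um, source_id=os.path.basename(path))


METRICS_COLUMNS = [
    "source_id",
    "R",
    "chi",
    "n_sectors",
    "n_valid_sectors",
    "area_px",
    "area_um2",
    "satellite_count",
]


def metrics_frame(records) -> pd.DataFrame:
    """Assemble ShapeMetrics records into a tidy one-row-per-spheroid frame."""
    records = list(records)
    if not records:
        raise ValidationError("no metrics records to write")
    rows = []
    for rec in records:
        d = dataclasses.asdict(rec)
        rows.append({c: d.get(c) for c in METRICS_COLUMNS})
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics(records, path: str | os.PathLike) -> None:
    """Write per-spheroid metrics as CSV, one row per record, in input order.

    ``area_um2`` is left empty when no physical scale was available.
    Floats are written at full repr precision so a round trip is lossless.
    """
    df = metrics_frame(records)
    try:
        df.to_csv(path, index=False, float_format=None)
    except OSError as exc:
        raise IOError(f"cannot write metrics to {path}: {exc}") from exc


def read_counts(path: str | os.PathLike, fields_per_well: int | None = 3) -> CountTable:
    """Read a transwell migrated-cell count table from CSV."""
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise IOError(f"cannot read counts from {path}: {exc}") from exc
    return CountTable(df, fields_per_well=fields_per_well)
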