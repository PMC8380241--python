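"""Multipage-TIFF + CSV-manifest dataset reader/writer.

One 16-bit grayscale TIFF per cell: page 1 = nuclear fluorescence,
page 2 = brightfield. The manifest carries the label, provenance and
gating features with a fixed column set.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from mnflow.ingest.records import CellMeta, CellRecord, GatingFeatures
from mnflow.taxonomy import class_name, parse_class

MANIFEST_COLUMNS = (
    "file",
    "label",
    "lab",
    "compound",
    "concentration",
    "replicate",
    "area_um2",
    "aspect_ratio",
    "gradient_rms",
)


class DatasetFormatError(ValueError):
    """Malformed dataset: bad TIFF page count, missing file or bad label."""


def write_dataset(
    records: Sequence[CellRecord], path: str | os.PathLike, manifest_name: str = "manifest.csv"
) -> Path:
    """Write records as per-cell two-page TIFFs plus a CSV manifest.

    Returns the manifest path. Images must be standardised (64x64x2 uint16).
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    width = max(6, len(str(len(records))))
    for i, rec in enumerate(records):
        rec.validate()
        fname = f"cell_{i:0{width}d}.tif"
        pages = np.ascontiguousarray(np.moveaxis(rec.image, -1, 0))  # (2, 64, 64)
        tifffile.imwrite(root / fname, pages, photometric="minisblack")
        f = rec.features
        rows.append(
            {
                "file": fname,
                "label": class_name(rec.label) if rec.label is not None else "",
                "lab": rec.meta.lab,
                "compound": rec.meta.compound,
                "concentration": rec.meta.concentration,
                "replicate": rec.meta.replicate,
                "area_um2": f.brightfield_area if f else np.nan,
                "aspect_ratio": f.aspect_ratio if f else np.nan,
                "gradient_rms": f.gradient_rms if f else np.nan,
            }
        )
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    mpath = root / manifest_name
    manifest.to_csv(mpath, index=False)
    return mpath


def read_dataset(manifest_path: str | os.PathLike) -> list[CellRecord]:
    """Read a dataset back from its CSV manifest.

    Raises DatasetFormatError on a missing image file, a TIFF whose page
    count is not 2, or a label outside the nine-class taxonomy (the error
    names the offending manifest row).
    """
    mpath = Path(manifest_path)
    if not mpath.exists():
        raise DatasetFormatError(f"manifest not found: {mpath}")
    df = pd.read_csv(mpath, keep_default_na=False, na_values=[])
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetFormatError(f"manifest missing columns: {sorted(missing)}")
    root = mpath.parent
    records: list[CellRecord] = []
    for i, row in df.iterrows():
        fpath = root / str(row["file"])
        if not fpath.exists():
            raise DatasetFormatError(f"row {i}: image file not found: {fpath}")
        pages = tifffile.imread(fpath)
        if pages.ndim != 3 or pages.shape[0] != 2:
            npages = 1 if pages.ndim == 2 else pages.shape[0]
            raise DatasetFormatError(
                f"row {i}: expected a 2-page TIFF, got {npages} page(s) in {fpath}"
            )
        image = np.moveaxis(pages, 0, -1).astype(np.uint16)
        label_str = str(row["label"]).strip()
        if label_str:
            try:
                label = parse_class(label_str)
            except ValueError as e:
                raise DatasetFormatError(f"row {i}: {e}") from e
        else:
            label = None
        feats = None
        try:
            area = float(row["area_um2"])
            ar = float(row["aspect_ratio"])
            grms = float(row["gradient_rms"])
            if np.isfinite(area) and np.isfinite(ar):
                feats = GatingFeatures(area, ar, grms)
        except (TypeError, ValueError):
            feats = None
        meta = CellMeta(
            lab=str(row["lab"]),
            compound=str(row["compound"]),
            concentration=float(row["concentration"]) if str(row["concentration"]) else 0.0,
            replicate=int(row["replicate"]) if str(row["replicate"]) else 0,
            source=str(fpath),
        )
        records.append(CellRecord(image=image, features=feats, meta=meta, label=label))
    return records
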