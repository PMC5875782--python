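"""File formats: 16-bit PNG images, JSON ROI vertex lists, cohort CSV tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .simulate import COHORT_COLUMNS, validate_cohort

__all__ = [
    "write_image_png",
    "read_image_png",
    "read_image_dicom",
    "write_roi_json",
    "read_roi_json",
    "write_cohort_csv",
    "read_cohort_csv",
]


def write_image_png(image: np.ndarray, path) -> None:
    """Write a 2D gray-value array as 16-bit grayscale PNG."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("image must be 2D")
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("gray values must fit in 16 bits")
    Image.fromarray(arr.astype(np.uint16)).save(str(path))


def read_image_png(path) -> np.ndarray:
    with Image.open(str(path)) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel grayscale image")
    return arr.astype(np.uint16)


def read_image_dicom(path, to_stored: bool = True) -> np.ndarray:
    """Read a single-frame DICOM slice as stored gray values.

    Applies RescaleSlope/RescaleIntercept to obtain HU, then (with
    ``to_stored``) offsets by +1024 to the unsigned stored convention used
    throughout this package.  Requires pydicom.
    """
    import pydicom  # optional dependency

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    stored = hu + 1024.0 if to_stored else hu
    return np.clip(np.round(stored), 0, 65535).astype(np.uint16)


def write_roi_json(vertices, path) -> None:
    """Write ROI vertices as a JSON list ``[[x, y], ...]`` (0-based pixels)."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ValueError("vertices must be an (n, 2) array")
    Path(path).write_text(json.dumps([[float(x), float(y)] for x, y in verts]) + "\n")


def read_roi_json(path) -> np.ndarray:
    verts = np.asarray(json.loads(Path(path).read_text()), dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError(f"{path}: ROI must be a list of >= 3 [x, y] vertices")
    return verts


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table; feature columns (if present) follow the core schema."""
    validate_cohort(cohort)
    extra = [c for c in cohort.columns if c not in COHORT_COLUMNS]
    cohort[COHORT_COLUMNS + extra].to_csv(path, index=False)


def read_cohort_csv(path, aliases: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    ``aliases`` maps column names found in the file to the canonical schema
    names (useful for tables exported from spreadsheets with different
    headers).  Pair integrity is validated on read; errors name the offending
    column, patient or pair.
    """
    df = pd.read_csv(path)
    if aliases:
        df = df.rename(columns=dict(aliases))
    validate_cohort(df)
    return df
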