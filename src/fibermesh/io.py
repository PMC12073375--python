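"""Image reading/writing, pixel-scale calibration, and metrics persistence.

SEM vendors embed a scale bar rather than per-pixel metadata, so the
calibration here is explicit: either the user supplies um/px directly, or
they read the bar length off the image in pixels and give the labelled
physical length.  Automatic bar detection is deliberately not attempted.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ImageIOError, ValidationError

__all__ = [
    "Calibration",
    "calibrate",
    "load_image",
    "save_image",
    "write_metrics",
    "read_metrics",
    "FIBER_STATS_COLUMNS",
]

#: Fixed column order of the fiber-statistics CSV schema.
FIBER_STATS_COLUMNS = [
    "sample_id",
    "n",
    "mean_um",
    "sd_um",
    "median_um",
    "positively_skewed",
    "n_excluded",
    "min_n_warning",
]


@dataclass(frozen=True)
class Calibration:
    """Physical pixel scale of an image.

    source records whether the scale was given directly ("explicit") or
    derived from a measured scale bar ("scale_bar").
    """

    um_per_px: float
    source: str = "explicit"

    def __post_init__(self):
        if not (self.um_per_px > 0 and math.isfinite(self.um_per_px)):
            raise ValidationError("um_per_px must be positive and finite")


def calibrate(bar_length_px: float, bar_label_um: float) -> Calibration:
    """Calibration from an embedded scale bar: um_per_px = label / length."""
    if not bar_length_px > 0:
        raise ValidationError("bar_length_px must be positive")
    if not bar_label_um > 0:
        raise ValidationError("bar_label_um must be positive")
    return Calibration(um_per_px=bar_label_um / bar_length_px, source="scale_bar")


def load_image(path) -> tuple[np.ndarray, dict]:
    """Load an 8/16-bit grayscale (or RGB-as-gray) image, normalized to [0,1].

    RGB inputs are reduced by channel mean — SEM micrographs are grayscale
    stored in RGB containers.  Returns (float array, metadata dict).
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"could not read image {path}: file does not exist")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise ImageIOError(f"could not read image {path}: {exc}") from exc
    meta = {"path": str(path), "dtype": str(arr.dtype), "shape": tuple(arr.shape)}
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ImageIOError(f"could not read image {path}: expected 2-D grayscale")
    return arr, meta


def save_image(image: np.ndarray, path, bit_depth: int = 16) -> None:
    """Write a [0,1] float image as 8- or 16-bit grayscale TIFF or PNG."""
    if bit_depth not in (8, 16):
        raise ValidationError("bit_depth must be 8 or 16")
    path = Path(path)
    scale = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    arr = np.round(np.clip(image, 0.0, 1.0) * scale).astype(dtype)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, arr)
        else:
            iio.imwrite(path, arr)
    except Exception as exc:
        raise ImageIOError(f"could not write image {path}: {exc}") from exc


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    try:
        tmp.write_text(text)
        os.replace(tmp, path)
    except OSError as exc:
        raise ImageIOError(f"could not write {path}: {exc}") from exc


def write_metrics(records: list[dict], path, columns: list[str] | None = None) -> None:
    """Write records as CSV (fixed column order) plus a JSON mirror.

    Floats round-trip at full precision.  An empty record set with explicit
    columns yields a header-only CSV.  The JSON mirror sits next to the CSV
    with the same stem.
    """
    path = Path(path)
    if columns is None:
        if records:
            columns = list(records[0].keys())
        else:
            columns = FIBER_STATS_COLUMNS
    df = pd.DataFrame.from_records(records, columns=columns)
    _atomic_write_text(path, df.to_csv(index=False))
    _atomic_write_text(
        path.with_suffix(".json"), json.dumps(records, sort_keys=True, default=_jsonable)
    )


def _jsonable(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_metrics(path) -> list[dict]:
    """Read back a metrics CSV written by :func:`write_metrics`."""
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"could not read metrics {path}: file does not exist")
    df = pd.read_csv(path)
    return df.to_dict(orient="records")
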