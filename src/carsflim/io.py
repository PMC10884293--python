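"""Readers and writers for the pipeline's on-disk formats.

Conventions (shared across all modules): arrays are row-major, 0-based,
indexed (row, col); label images use 0 for background.  A hypercube is
a multi-page TIFF with one page per wavenumber plus a JSON sidecar
(`<stem>.axis.json`) holding the wavenumber axis and optional
metadata; FLIM channels are 32-bit float multi-page TIFFs; label masks
are 16-bit integer TIFFs; tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .carsfit import FEATURE_NAMES, FeatureImage, Hypercube
from .exceptions import InvalidArgumentError

__all__ = [
    "read_feature_image",
    "read_hypercube",
    "read_labels",
    "read_table",
    "write_feature_image",
    "write_hypercube",
    "write_labels",
    "write_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".axis.json")


def write_hypercube(path, cube: Hypercube, metadata: dict | None = None) -> None:
    """Write a hypercube as a multi-page TIFF (one page per wavenumber)
    with an axis sidecar JSON next to it."""
    path = Path(path)
    pages = np.moveaxis(cube.data.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    payload = {"axis": cube.axis.tolist()}
    if metadata:
        payload["metadata"] = metadata
    _sidecar(path).write_text(json.dumps(payload))


def read_hypercube(path) -> Hypercube:
    path = Path(path)
    pages = tifffile.imread(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise InvalidArgumentError(f"missing axis sidecar {sidecar}")
    axis = np.asarray(json.loads(sidecar.read_text())["axis"], dtype=float)
    if pages.ndim != 3:
        raise InvalidArgumentError(f"expected a multi-page TIFF, got shape {pages.shape}")
    if pages.shape[0] != axis.size:
        raise InvalidArgumentError(
            f"cube has {pages.shape[0]} pages but the axis lists {axis.size} wavenumbers"
        )
    return Hypercube(data=np.moveaxis(pages, 0, 2).astype(float), axis=axis)


def write_labels(path, labels: np.ndarray) -> None:
    """Write an integer label image as 16-bit TIFF (0 = background)."""
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer) and not labels.dtype == bool:
        raise InvalidArgumentError("label image must be integer or boolean")
    if labels.max() >= 2**16:
        raise InvalidArgumentError("label values exceed 16-bit range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise InvalidArgumentError(f"label image must be integer, got {arr.dtype}")
    return arr.astype(np.int32)


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False)


def read_table(path, required_columns: list[str] | None = None) -> pd.DataFrame:
    table = pd.read_csv(Path(path))
    if required_columns:
        missing = [c for c in required_columns if c not in table.columns]
        if missing:
            raise InvalidArgumentError(f"table {path} is missing columns: {missing}")
    return table


def write_feature_image(path, fi: FeatureImage) -> None:
    write_table(path, fi.table)


def read_feature_image(path, shape: tuple[int, int]) -> FeatureImage:
    table = read_table(path, required_columns=["row", "col", *FEATURE_NAMES])
    return FeatureImage(table=table, shape=tuple(shape))
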