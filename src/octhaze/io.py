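"""Reading and writing study tables, manifests and images."""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .measure import VRIMeasurement
from .synthetic import TABLE_COLUMNS, AcquisitionSetting, BScan

__all__ = [
    "read_study_table",
    "write_study_table",
    "measurements_to_table",
    "read_manifest",
    "load_bscan",
    "save_bscan",
]

_KEY_COLUMNS = ["subject", "position", "art", "focus", "repetition", "section"]


def _validate(table: pd.DataFrame, where: str) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{where}: missing columns {missing}")
    dup = table.duplicated(_KEY_COLUMNS)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{where}: duplicate measurement key at row {row}")
    failed = table["failed"].astype(bool)
    bad = failed & table["vri"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{where}: column 'vri' must be empty on failed row {row}")
    return table


def read_study_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a study CSV, enforcing the schema (failed rows carry no VRI)."""
    table = pd.read_csv(path)
    table["failed"] = table["failed"].astype(bool)
    return _validate(table, str(path))


def write_study_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a study CSV; round-trips through :func:`read_study_table`."""
    _validate(table, "write_study_table")
    table.to_csv(path, index=False)


def measurements_to_table(measurements: Iterable[VRIMeasurement]) -> pd.DataFrame:
    """Collect per-scan measurements into the long-format study table."""
    rows = []
    for m in measurements:
        s = m.setting or AcquisitionSetting()
        ok = m.ok
        rows.append(
            (m.subject, s.position, s.art, s.focus, m.repetition, m.section,
             m.vri if ok else np.nan,
             m.vitreous_mean if ok else np.nan,
             m.rpe_mean if ok else np.nan,
             not ok)
        )
    return pd.DataFrame.from_records(rows, columns=TABLE_COLUMNS)


def load_bscan(path: str | os.PathLike, **meta) -> BScan:
    """Load an 8-bit grayscale PNG/TIFF as a float image in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse identical RGB channels
        arr = arr[..., 0]
    pixels = arr.astype(float) / 255.0 if arr.dtype == np.uint8 else arr.astype(float)
    return BScan(pixels=np.clip(pixels, 0.0, 1.0), **meta)


def save_bscan(scan: BScan, path: str | os.PathLike) -> None:
    """Write the image as 8-bit grayscale."""
    img = np.clip(np.round(scan.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, img)


def read_manifest(path: str | os.PathLike) -> list[tuple[Path, dict]]:
    """Read a manifest CSV mapping image files to acquisition metadata.

    Columns: image, subject, position, art, focus, repetition, section.
    Paths are resolved relative to the manifest's directory; a missing
    image file is an error naming the path.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["image"] + _KEY_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    entries = []
    for row in df.itertuples():
        img = Path(row.image)
        if not img.is_absolute():
            img = path.parent / img
        if not img.exists():
            raise FileNotFoundError(f"manifest {path}: image file not found: {img}")
        meta = dict(
            subject=int(row.subject),
            setting=AcquisitionSetting(str(row.position), int(row.art), int(row.focus)),
            repetition=int(row.repetition),
            section=int(row.section),
        )
        entries.append((img, meta))
    return entries
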