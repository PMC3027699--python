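"""NIfTI, TSV and flat key-value I/O shared by the simulator and the runner."""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .structures import BoldSeries


def write_series(path: str | os.PathLike, series: BoldSeries) -> None:
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float32), series.affine)
    img.header.set_zooms(tuple(img.header.get_zooms()[:3]) + (series.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, os.fspath(path))


def read_series(path: str | os.PathLike, mask: np.ndarray,
                tr_s: float | None = None) -> BoldSeries:
    """Load a 4D NIfTI (plain or gzipped) as a BoldSeries.

    TR is taken from the header's time-axis zoom unless overridden.
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4D series, got {data.ndim} axes {data.shape}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"{path}: grid {data.shape[:3]} does not match mask grid {mask.shape}")
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldSeries(data=data, affine=img.affine, tr_s=tr_s, mask=mask)


def write_volume(path: str | os.PathLike, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             os.fspath(path))


def read_volume(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim} axes")
    return data, img.affine


def write_tsv(path: str | os.PathLike, table: np.ndarray) -> None:
    """Headerless tab-separated numeric table (t rows x k columns)."""
    np.savetxt(os.fspath(path), np.atleast_2d(table), delimiter="\t", fmt="%.8g")


def read_tsv(path: str | os.PathLike) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(os.fspath(path), delimiter="\t"))


def write_keyvalue(path: str | os.PathLike, entries: dict[str, str]) -> None:
    """Flat `dotted.key = value` text file; keys written in insertion order."""
    lines = [f"{k} = {v}" for k, v in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_keyvalue(path: str | os.PathLike) -> dict[str, str]:
    entries: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed line {raw!r}")
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    return entries
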