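"""Readers and writers: TIFF volumes/maps, two-column patterns, geometry
files, key-value sidecars and CSV result tables.

Unit conventions are fixed at these boundaries: micrometres for voxel and
pixel sizes, nm^-1 for q, arbitrary units for intensities.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .morphometry import LabeledVolume
from .scattering import Geometry, Pattern1D

_META_SUFFIX = ".meta.txt"


# --------------------------------------------------------------------------
# key-value sidecars
# --------------------------------------------------------------------------

def write_keyvalue(path: str, values: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        for key, val in values.items():
            fh.write(f"{key} = {val}\n")


def read_keyvalue(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out


# --------------------------------------------------------------------------
# volumes and maps (TIFF)
# --------------------------------------------------------------------------

def write_volume(path: str, vol: LabeledVolume) -> None:
    """Multi-page 8-bit label TIFF + ``.meta.txt`` sidecar with voxel_um."""
    tifffile.imwrite(path, vol.labels.astype(np.uint8))
    write_keyvalue(path + _META_SUFFIX, {"voxel_um": vol.voxel_um})


def read_volume(path: str, voxel_um: Optional[float] = None) -> LabeledVolume:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    labels = tifffile.imread(path)
    if labels.ndim == 2:
        labels = labels[None]
    if labels.ndim != 3:
        raise ValueError(f"{path}: expected a 2D/3D TIFF, got ndim={labels.ndim}")
    if voxel_um is None:
        meta_path = path + _META_SUFFIX
        if not os.path.exists(meta_path):
            raise ValueError(
                f"{path}: voxel size missing; pass voxel_um or provide {meta_path}"
            )
        voxel_um = float(read_keyvalue(meta_path)["voxel_um"])
    return LabeledVolume(labels, voxel_um)


def write_mask(path: str, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8))


def read_mask(path: str) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_map(path: str, data: np.ndarray) -> None:
    """Single-page 32-bit float intensity TIFF."""
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))


def read_map(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-page 2D TIFF")
    return np.asarray(data, dtype=float)


# --------------------------------------------------------------------------
# 1D patterns (two-column text) and geometry files
# --------------------------------------------------------------------------

def write_pattern(path: str, pattern: Pattern1D, header: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("# q_nm^-1  I_arb\n")
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for q, i in zip(pattern.q, pattern.I):
            fh.write(f"{q:.9e} {i:.9e}\n")


def read_pattern(path: str) -> Pattern1D:
    """Two-column whitespace-delimited text; '#' comment lines skipped."""
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {raw!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    return Pattern1D(q=arr[:, 0], I=arr[:, 1])  # validates monotone q


_GEOMETRY_KEYS = ("wavelength_nm", "distance_mm", "pixel_mm", "center_x_px", "center_y_px")


def write_geometry(path: str, geom: Geometry) -> None:
    write_keyvalue(path, {k: getattr(geom, k) for k in _GEOMETRY_KEYS})


def read_geometry(path: str) -> Geometry:
    kv = read_keyvalue(path)
    missing = [k for k in _GEOMETRY_KEYS if k not in kv]
    if missing:
        raise ValueError(f"{path}: missing geometry keys {missing}")
    return Geometry(**{k: float(kv[k]) for k in _GEOMETRY_KEYS})


# --------------------------------------------------------------------------
# result tables
# --------------------------------------------------------------------------

def write_results(records: Sequence[Mapping[str, object]], path: str) -> None:
    """CSV with stable column order (first-record key order) and header."""
    if not records:
        raise ValueError("no records to write")
    columns = list(records[0].keys())
    pd.DataFrame.from_records(records, columns=columns).to_csv(path, index=False)


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
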