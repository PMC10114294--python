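"""Read/write label volumes (TIFF, HDF5, MRC) and tile-score tables (CSV).

Axis convention on disk mirrors the in-memory one: z is the slowest axis (one
TIFF page per z-slice; HDF5/MRC datasets stored ``(z, y, x)``).  Spacing
travels as:

* TIFF — sidecar JSON ``<file>.json`` with ``{"spacing_nm_zyx": [sz, sy, sx]}``
  (TIFF resolution-tag dialects are too inconsistent to rely on);
* HDF5 — dataset attribute ``spacing_nm_zyx``;
* MRC — the standard ``cella``/``mx,my,mz`` cell-size fields.

An explicit ``spacing`` argument always overrides file metadata; if neither is
available a :class:`~fibmorph.errors.MetadataError` is raised.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import _mrc
from .errors import FormatError, MetadataError, SchemaError, ValidationError
from .tables import ORGANOID_COLUMNS, TILE_COLUMNS, TileScoreTable
from .volume import LabeledVolume

__all__ = ["read_label_volume", "write_label_volume", "read_tile_scores", "write_tile_scores"]

_H5_SUFFIXES = {".h5", ".hdf5", ".hdf"}
_TIFF_SUFFIXES = {".tif", ".tiff"}
_MRC_SUFFIXES = {".mrc", ".rec", ".map"}
_H5_DATASET = "labels"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _check_integer(arr: np.ndarray, path: Path) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr
    if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
        raise TypeError(f"{path}: voxel values are floating point; label volumes must be integer typed")
    raise TypeError(f"{path}: non-integer voxel values are not a label volume")


def read_label_volume(
    path,
    spacing: tuple[float, float, float] | None = None,
    class_name: str = "",
) -> LabeledVolume:
    """Read a label volume with its physical spacing.

    Parameters
    ----------
    path
        TIFF stack, HDF5 file (dataset ``labels``) or MRC file.
    spacing
        Optional ``(s_z, s_y, s_x)`` override in nm; required when the file
        carries no spacing metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    meta_spacing: tuple[float, float, float] | None = None

    if suffix in _TIFF_SUFFIXES:
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - tifffile error text varies
            raise FormatError(f"{path}: unreadable TIFF ({exc})") from exc
        if arr.ndim == 2:
            arr = arr[None]
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            meta_spacing = tuple(meta["spacing_nm_zyx"])
    elif suffix in _H5_SUFFIXES:
        try:
            with h5py.File(path, "r") as fh:
                if _H5_DATASET not in fh:
                    raise FormatError(f"{path}: no '{_H5_DATASET}' dataset")
                ds = fh[_H5_DATASET]
                arr = ds[()]
                if "spacing_nm_zyx" in ds.attrs:
                    meta_spacing = tuple(float(v) for v in ds.attrs["spacing_nm_zyx"])
        except OSError as exc:
            raise FormatError(f"{path}: unreadable HDF5 ({exc})") from exc
    elif suffix in _MRC_SUFFIXES:
        arr, meta_spacing = _mrc.read_mrc(path)
    else:
        raise FormatError(f"{path}: unsupported volume format '{suffix}' (use TIFF, HDF5 or MRC)")

    arr = _check_integer(np.asarray(arr), path)
    eff = spacing if spacing is not None else meta_spacing
    if eff is None:
        raise MetadataError(
            f"{path}: no voxel spacing in file metadata; pass spacing=(s_z, s_y, s_x) in nm"
        )
    return LabeledVolume(arr, tuple(float(s) for s in eff), class_name=class_name)


def write_label_volume(vol: LabeledVolume, path) -> None:
    """Write a volume; format chosen from the file suffix. Round-trips bit-exactly."""
    path = Path(path)
    suffix = path.suffix.lower()
    labels = vol.labels
    # store in the smallest unsigned dtype that holds the label range
    if labels.size and labels.max() > np.iinfo(np.uint16).max:
        store = labels.astype(np.uint32)
    elif labels.size and labels.max() > np.iinfo(np.uint8).max:
        store = labels.astype(np.uint16)
    else:
        store = labels.astype(np.uint8)
    try:
        if suffix in _TIFF_SUFFIXES:
            tifffile.imwrite(path, store, photometric="minisblack")
            _sidecar_path(path).write_text(
                json.dumps({"spacing_nm_zyx": list(vol.spacing_nm), "class_name": vol.class_name})
            )
        elif suffix in _H5_SUFFIXES:
            with h5py.File(path, "w") as fh:
                ds = fh.create_dataset(
                    _H5_DATASET, data=store, compression="gzip", compression_opts=4, track_times=False
                )
                ds.attrs["spacing_nm_zyx"] = np.asarray(vol.spacing_nm, dtype=np.float64)
                ds.attrs["class_name"] = vol.class_name
        elif suffix in _MRC_SUFFIXES:
            _mrc.write_mrc(path, labels, vol.spacing_nm)
        else:
            raise FormatError(f"{path}: unsupported volume format '{suffix}' (use TIFF, HDF5 or MRC)")
    except (PermissionError, OSError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_tile_scores(path, organoid_table=None) -> TileScoreTable:
    """Read per-tile damage scores (CSV), optionally with a per-organoid CSV.

    The tile CSV needs a header with columns ``sample_group, organoid_id,
    tile_id, damaged``; ``damaged`` accepts 0/1, true/false, yes/no in any
    case.  The organoid CSV needs ``organoid_id, organoid_area_um2, n_cells``.
    """
    tiles = pd.read_csv(path, dtype=str)
    missing = [c for c in TILE_COLUMNS if c not in tiles.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    organoids = None
    if organoid_table is not None:
        organoids = pd.read_csv(organoid_table)
        missing = [c for c in ORGANOID_COLUMNS if c not in organoids.columns]
        if missing:
            raise SchemaError(f"{organoid_table}: missing required columns {missing}")
    return TileScoreTable(tiles, organoids)


def write_tile_scores(table: TileScoreTable, path, organoid_path=None) -> None:
    table.tiles.to_csv(path, index=False)
    if organoid_path is not None:
        if table.organoids is None:
            raise ValidationError("table has no per-organoid data to write")
        table.organoids.to_csv(organoid_path, index=False)
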