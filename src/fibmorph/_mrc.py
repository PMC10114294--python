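"""Minimal MRC2014 reader/writer for integer label volumes.

Supports the integer data modes only: 0 (int8), 1 (int16) and 6 (uint16) —
the modes in which label exports are exchanged.  The voxel size is carried in
the standard ``cella / (mx, my, mz)`` header fields in Angstrom, so files
written here open with their spacing in any MRC-aware viewer.

Only little-endian files are produced; both byte orders are accepted on read.
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import FormatError, ValidationError

_HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 6: np.uint16}
_ANGSTROM_PER_NM = 10.0


def _pick_mode(labels: np.ndarray) -> tuple[int, np.dtype]:
    lo = int(labels.min()) if labels.size else 0
    hi = int(labels.max()) if labels.size else 0
    for mode, dt in ((0, np.int8), (1, np.int16), (6, np.uint16)):
        info = np.iinfo(dt)
        if lo >= info.min and hi <= info.max:
            return mode, np.dtype(dt)
    raise ValidationError(
        f"label range [{lo}, {hi}] does not fit any integer MRC mode (0/1/6); "
        "use TIFF or HDF5 for >16-bit label ids"
    )


def write_mrc(path, labels: np.ndarray, spacing_nm: tuple[float, float, float]) -> None:
    """Write a (z, y, x) integer array as a little-endian MRC2014 file."""
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValidationError("MRC writer expects a 3D (z, y, x) array")
    mode, dtype = _pick_mode(labels)
    nz, ny, nx = labels.shape
    sz, sy, sx = spacing_nm

    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, mode)
    # nxstart/nystart/nzstart stay 0; sampling grid == volume size
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40,
        nx * sx * _ANGSTROM_PER_NM, ny * sy * _ANGSTROM_PER_NM, nz * sz * _ANGSTROM_PER_NM,
    )  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc/mapr/maps: x fastest
    data = labels.astype(dtype, copy=False)
    struct.pack_into(
        "<3f", header, 76, float(data.min(initial=0)), float(data.max(initial=0)), float(data.mean() if data.size else 0.0)
    )
    struct.pack_into("<i", header, 88, 1)  # ispg: volume stack convention uses 1 for 3D
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0, 0))  # little-endian machine stamp

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(data).tobytes())


def read_mrc(path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    """Read an integer-mode MRC file.

    Returns
    -------
    labels : (nz, ny, nx) integer array
    spacing_nm : (s_z, s_y, s_x) in nm, or None if the header carries no cell size.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_BYTES)
        if len(header) < _HEADER_BYTES:
            raise FormatError(f"{path}: truncated MRC header")
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise FormatError(f"{path}: missing MRC 'MAP ' marker")
        stamp = header[212]
        endian = "<" if stamp in (0x44, 0x00) else ">"
        nx, ny, nz = struct.unpack_from(endian + "3i", header, 0)
        (mode,) = struct.unpack_from(endian + "i", header, 12)
        mx, my, mz = struct.unpack_from(endian + "3i", header, 28)
        xlen, ylen, zlen = struct.unpack_from(endian + "3f", header, 40)
        (nsymbt,) = struct.unpack_from(endian + "i", header, 92)
        if mode not in _MODE_DTYPES:
            raise FormatError(f"{path}: MRC mode {mode} is not an integer label mode (0/1/6)")
        fh.seek(_HEADER_BYTES + max(nsymbt, 0))
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder(endian)
        count = nx * ny * nz
        data = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype, count=count)
        if data.size != count:
            raise FormatError(f"{path}: truncated MRC data block")
    labels = data.reshape(nz, ny, nx).astype(_MODE_DTYPES[mode])
    spacing = None
    if mx > 0 and my > 0 and mz > 0 and xlen > 0 and ylen > 0 and zlen > 0:
        spacing = (
            zlen / mz / _ANGSTROM_PER_NM,
            ylen / my / _ANGSTROM_PER_NM,
            xlen / mx / _ANGSTROM_PER_NM,
        )
    return labels, spacing
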