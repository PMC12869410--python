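"""Minimal MRC2014 mode-2 (float32) reader/writer.

Covers exactly what this package needs: single 3D volumes and MRCS
image stacks, little-endian, no extended header.  Round trips are
bit-exact for finite float32 data.
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["write_mrc", "read_mrc"]

_HEADER_SIZE = 1024
_MODE_FLOAT32 = 2


def write_mrc(path, data: np.ndarray, voxel_size_A: float = 1.0,
              is_stack: bool = False) -> None:
    """Write a 3D array (nz, ny, nx) as MRC mode 2.

    ``is_stack`` marks the file as an image stack (MRCS semantics:
    nz = number of images, z voxel size irrelevant).
    """
    data = np.asarray(data, dtype="<f4")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    nz, ny, nx = data.shape
    header = bytearray(_HEADER_SIZE)
    mz = 1 if is_stack else nz
    struct.pack_into("<10i", header, 0,
                     nx, ny, nz, _MODE_FLOAT32, 0, 0, 0, nx, ny, mz)
    struct.pack_into("<6f", header, 40,
                     nx * voxel_size_A, ny * voxel_size_A, mz * voxel_size_A,
                     90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)     # mapc, mapr, maps
    struct.pack_into("<3f", header, 76,
                     float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 88, 0 if is_stack else 1)   # ispg
    struct.pack_into("<i", header, 92, 0)            # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC file; returns (data (nz, ny, nx), voxel size in Å)."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header")
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise ValueError(f"{path}: missing MAP identifier")
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        if mode != _MODE_FLOAT32:
            raise ValueError(
                f"{path}: unsupported MRC mode {mode} (only mode 2)"
            )
        mx = struct.unpack_from("<i", header, 28)[0]
        xlen = struct.unpack_from("<f", header, 40)[0]
        voxel = xlen / mx if mx else 1.0
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        fh.seek(_HEADER_SIZE + nsymbt)
        raw = fh.read(nx * ny * nz * 4)
        if len(raw) < nx * ny * nz * 4:
            raise ValueError(
                f"{path}: truncated data section "
                f"({len(raw)} of {nx * ny * nz * 4} bytes)"
            )
    data = np.frombuffer(raw, dtype="<f4").reshape(nz, ny, nx).copy()
    return data, float(voxel)
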