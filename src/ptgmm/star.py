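"""STAR-compatible metadata tables and pose conversions.

A single ``data_particles`` block with a ``loop_`` is read/written via
pandas.  Orientations follow the common cryo-EM convention: intrinsic
ZYZ Euler angles (rot, tilt, psi) in degrees; this package treats the
resulting rotation as mapping model coordinates into the lab frame
whose z axis is the projection direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .image_model import CtfParams

__all__ = [
    "write_star",
    "read_star",
    "euler_to_quat",
    "quat_to_euler",
    "metadata_to_records",
]

_MANDATORY = [
    "rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi",
    "rlnDefocusU", "rlnVoltage", "rlnSphericalAberration",
    "rlnAmplitudeContrast", "rlnImagePixelSize",
]


def write_star(path, df: pd.DataFrame, block: str = "particles") -> None:
    with open(path, "w") as fh:
        fh.write(f"\ndata_{block}\n\nloop_\n")
        for i, col in enumerate(df.columns, start=1):
            fh.write(f"_{col} #{i}\n")
        for _, row in df.iterrows():
            fields = []
            for v in row:
                if isinstance(v, (float, np.floating)):
                    fields.append(f"{v:.9g}")
                else:
                    fields.append(str(v))
            fh.write(" ".join(fields) + "\n")


def read_star(path) -> pd.DataFrame:
    cols: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                continue
            if line == "loop_":
                in_loop = True
                cols, rows = [], []
                continue
            if in_loop and line.startswith("_"):
                cols.append(line.split()[0].lstrip("_"))
                continue
            if in_loop:
                rows.append(line.split())
    if not cols:
        raise ValueError(f"{path}: no loop_ block found")
    df = pd.DataFrame(rows, columns=cols)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return df


def euler_to_quat(rot_tilt_psi_deg: np.ndarray) -> np.ndarray:
    """(n, 3) intrinsic ZYZ Euler degrees -> (n, 4) quaternion (x,y,z,w)."""
    return Rotation.from_euler(
        "ZYZ", np.atleast_2d(rot_tilt_psi_deg), degrees=True
    ).as_quat()


def quat_to_euler(quats: np.ndarray) -> np.ndarray:
    """(n, 4) quaternion -> (n, 3) intrinsic ZYZ Euler degrees."""
    return Rotation.from_quat(np.atleast_2d(quats)).as_euler(
        "ZYZ", degrees=True
    )


def metadata_to_records(df: pd.DataFrame):
    """STAR table -> (quaternions, shifts in px, list of CtfParams)."""
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory STAR columns: {missing}")
    euler = df[["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"]].to_numpy(
        dtype=np.float64
    )
    quats = euler_to_quat(euler)
    px = df["rlnImagePixelSize"].to_numpy(dtype=np.float64)
    if "rlnOriginXAngst" in df.columns:
        shifts = np.stack([
            df["rlnOriginXAngst"].to_numpy(dtype=np.float64) / px,
            df["rlnOriginYAngst"].to_numpy(dtype=np.float64) / px,
        ], axis=1)
    else:
        shifts = np.zeros((len(df), 2))
    ctfs = [
        CtfParams(
            defocus_um=row.rlnDefocusU * 1e-4,
            voltage_kv=row.rlnVoltage,
            cs_mm=row.rlnSphericalAberration,
            amplitude_contrast=row.rlnAmplitudeContrast,
            pixel_size_A=row.rlnImagePixelSize,
        )
        for row in df.itertuples()
    ]
    return quats, shifts, ctfs
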