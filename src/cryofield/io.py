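"""MRC/MRCS volume and RELION-dialect STAR metadata I/O (via gemmi).

Volumes are numpy arrays indexed (x, y, z); image stacks are (N, n, n).
Pixel size is carried in the MRC header as the unit-cell edge divided by
the grid size.  STAR files use the RELION particle labels (Euler angles
ZYZ rot/tilt/psi in degrees, origin shifts in Angstrom, standard CTF
labels) plus a custom state-label column for simulated ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import gemmi

from .forward_model import ImagingParams
from .geometry import MaskVolume, Pose

__all__ = [
    "write_mrc",
    "read_mrc",
    "write_mrcs",
    "read_mrcs",
    "read_mask",
    "write_star",
    "read_star",
    "particles_from_star",
]

_REQUIRED_POSE_LABELS = ["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"]
_REQUIRED_CTF_LABELS = ["rlnDefocusU", "rlnDefocusV", "rlnDefocusAngle",
                        "rlnVoltage", "rlnSphericalAberration",
                        "rlnAmplitudeContrast"]


def _write_map(data: np.ndarray, voxel_size: float, path) -> None:
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(data, dtype=np.float32))
    shape = data.shape
    m.grid.unit_cell = gemmi.UnitCell(
        shape[0] * voxel_size, shape[1] * voxel_size, shape[2] * voxel_size,
        90, 90, 90,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def write_mrc(volume: np.ndarray, voxel_size: float, path) -> None:
    """Write a 3D volume as MRC with the voxel size in the header."""
    if volume.ndim != 3:
        raise ValueError("write_mrc expects a 3D array")
    _write_map(volume, voxel_size, path)


def read_mrc(path):
    """Read an MRC volume; returns (array, voxel_size)."""
    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True).astype(float)
    voxel = m.grid.unit_cell.a / m.grid.nu
    return data, float(voxel)


def write_mrcs(stack: np.ndarray, pixel_size: float, path) -> None:
    """Write an (N, n, n) particle stack as MRCS."""
    if stack.ndim != 3:
        raise ValueError("write_mrcs expects an (N, n, n) array")
    _write_map(stack, pixel_size, path)


def read_mrcs(path):
    """Read an MRCS particle stack; returns (stack, pixel_size)."""
    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True).astype(float)
    voxel = m.grid.unit_cell.b / m.grid.nv
    return data, float(voxel)


def read_mask(path, cutoff: float = 0.0) -> MaskVolume:
    """Read an MRC mask volume, honoring the header pixel size."""
    data, voxel = read_mrc(path)
    return MaskVolume(data=np.maximum(data, 0.0), spacing=voxel, cutoff=cutoff)


def write_star(table: pd.DataFrame, path, block_name: str = "particles") -> None:
    """Write a metadata table as a RELION-dialect STAR loop."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    loop = block.init_loop("_", [str(c) for c in table.columns])
    for _, row in table.iterrows():
        loop.add_row([_format_value(v) for v in row])
    doc.write_file(str(path))


def _format_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))  # shortest round-trip representation
    return str(v)


def read_star(path, block_name: str | None = None) -> pd.DataFrame:
    """Read the first (or named) loop block of a STAR file into a DataFrame."""
    doc = gemmi.cif.read_file(str(path))
    block = doc[0] if block_name is None else doc.find_block(block_name)
    if block is None:
        raise ValueError(f"STAR block {block_name!r} not found")
    prefix = "_"
    cols = [item.loop.tags for item in block if item.loop is not None]
    if not cols:
        raise ValueError("STAR file contains no loop")
    tags = cols[0]
    table = block.find(tags)
    data = {tag.lstrip(prefix): [] for tag in tags}
    for row in table:
        for tag, val in zip(tags, row):
            data[tag.lstrip(prefix)].append(val)
    df = pd.DataFrame(data)
    for c in df.columns:
        try:
            # Python's float() is correctly rounded, so numeric labels
            # round-trip bit-exactly through the text format
            df[c] = df[c].map(float)
        except ValueError:
            pass  # non-numeric column (e.g. image names)
    return df


def particles_from_star(df: pd.DataFrame, pixel_size: float):
    """Convert a STAR table to (poses, imaging params, state labels).

    Missing pose or CTF columns raise an error listing the absent labels.
    """
    from scipy.spatial.transform import Rotation

    missing = [c for c in _REQUIRED_POSE_LABELS + _REQUIRED_CTF_LABELS
               if c not in df.columns]
    if missing:
        raise ValueError(
            "STAR table is missing required labels: " + ", ".join(missing)
        )
    poses, ctfs = [], []
    for _, row in df.iterrows():
        R = Rotation.from_euler(
            "ZYZ",
            [row["rlnAngleRot"], row["rlnAngleTilt"], row["rlnAnglePsi"]],
            degrees=True,
        ).as_matrix()
        tx = float(row.get("rlnOriginXAngst", 0.0))
        ty = float(row.get("rlnOriginYAngst", 0.0))
        poses.append(Pose(R, tx, ty))
        ctfs.append(
            ImagingParams(
                defocus_u=float(row["rlnDefocusU"]),
                defocus_v=float(row["rlnDefocusV"]),
                astigmatism_deg=float(row["rlnDefocusAngle"]),
                voltage_kv=float(row["rlnVoltage"]),
                cs_mm=float(row["rlnSphericalAberration"]),
                amplitude_contrast=float(row["rlnAmplitudeContrast"]),
                phase_shift_deg=float(row.get("rlnPhaseShift", 0.0)),
                pixel_size=pixel_size,
            )
        )
    if "cryofieldStateLabel" in df.columns:
        states = df["cryofieldStateLabel"].to_numpy().astype(int)
    else:
        states = np.zeros(len(df), dtype=int)
    return poses, ctfs, states
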