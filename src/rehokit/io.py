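"""NIfTI and tabular I/O.

All images move through the package as :class:`Scan4D` (4D BOLD series) or
plain boolean/float 3D arrays paired with a 4x4 affine.  NIfTI reading and
writing is delegated to nibabel; tables are tab-separated values with a
header row and empty fields for missing values.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Scan4D",
    "read_scan",
    "write_scan",
    "read_mask",
    "write_mask",
    "read_metadata",
    "write_metadata",
    "voxel_sizes_mm",
    "array_sha256",
    "METADATA_COLUMNS",
]

#: canonical column order of the subject metadata table
METADATA_COLUMNS = [
    "id",
    "group",
    "age_y",
    "sex",
    "education_y",
    "cigarettes_per_day",
    "dialysis_months",
    "mmse",
]


@dataclasses.dataclass
class Scan4D:
    """A single subject's 4D BOLD scan.

    Parameters
    ----------
    data:
        Voxel array with time as the last axis, shape ``(x, y, z, t)``.
    affine:
        4x4 voxel-to-world (mm) map.
    tr_s:
        Repetition time in seconds (sampling interval of the series).
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Scan4D requires a 4D array, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.isfinite(np.linalg.det(self.affine[:3, :3])) or np.linalg.det(self.affine[:3, :3]) == 0:
            raise ValueError("affine spatial block must be invertible")
        if not (self.tr_s > 0):
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_sizes_mm(self) -> np.ndarray:
        return voxel_sizes_mm(self.affine)


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the affine)."""
    return np.sqrt((np.asarray(affine, float)[:3, :3] ** 2).sum(axis=0))


def read_scan(path: str | Path, tr_s: float | None = None) -> Scan4D:
    """Load a 4D NIfTI file as a :class:`Scan4D`.

    The repetition time is taken from the header (``pixdim[4]``) unless
    ``tr_s`` overrides it; a missing/zero header TR without an override is an
    error because every temporal operation depends on it.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D scan, got {data.ndim}D")
    if tr_s is None:
        header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if header_tr <= 0:
            raise ValueError(
                f"{path}: header pixdim[4] (TR) is {header_tr}; pass tr_s explicitly"
            )
        tr_s = header_tr
    return Scan4D(data=data, affine=img.affine.copy(), tr_s=float(tr_s))


def write_scan(scan: Scan4D, path: str | Path) -> Path:
    """Write a scan to NIfTI-1, recording the TR in ``pixdim[4]``."""
    img = nib.Nifti1Image(np.asarray(scan.data, dtype=np.float32), scan.affine)
    img.header.set_zooms((*voxel_sizes_mm(scan.affine), scan.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI mask; returns ``(bool array, affine)``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D")
    return data > 0, img.affine.copy()


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.asarray(affine, float))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_map(values: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a 3D statistical/ReHo map as float32 NIfTI."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), np.asarray(affine, float))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the subject metadata TSV (missing values are empty fields)."""
    meta = pd.read_csv(path, sep="\t", dtype={"id": str, "group": str, "sex": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata table lacks columns {missing}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def array_sha256(arr: np.ndarray) -> str:
    """Stable content hash of an array (dtype-normalized to float64 bytes)."""
    a = np.ascontiguousarray(np.asarray(arr, dtype=np.float64))
    return hashlib.sha256(a.tobytes()).hexdigest()
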