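"""Volume container, NIfTI-1 I/O, resampling and intensity normalisation.

Conventions used throughout the package:

* voxel indices are 0-based;
* world coordinates are ``affine @ [i, j, k, 1]`` (homogeneous, mm);
* NIfTI files are written with both qform and sform set; on read the
  sform is authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


class GridError(ValueError):
    """Raised for invalid grids, affines or incompatible volume pairs."""


@dataclass
class Volume:
    """A 3D or 4D image on a regular grid with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise GridError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise GridError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GridError("affine is not invertible")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis spacing in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of 0-based voxel indices, shape (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_coords(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points, shape (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape3 == other.shape3 and np.allclose(
            self.affine, other.affine, atol=atol
        )


def load_nifti(path: str | Path) -> Volume:
    img = nib.load(str(path))
    # sform is authoritative when present
    affine = img.get_sform() if img.header["sform_code"] > 0 else img.affine
    return Volume(np.asarray(img.dataobj), np.asarray(affine))


def save_nifti(v: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data), v.affine)
    img.set_sform(v.affine, code=2)
    img.set_qform(v.affine, code=2)
    nib.save(img, str(path))


def resample_iso(v: Volume, target_mm: float, *, is_label: bool = False) -> Volume:
    """Resample onto an isotropic grid covering the input field of view.

    Continuous images use trilinear interpolation; label/mask images use
    nearest-neighbour (``is_label=True``) so no new label values appear.
    The output affine keeps the input orientation (direction cosines) and
    places the first output voxel center at the first input voxel center.
    """
    if target_mm <= 0:
        raise GridError("target spacing must be positive")
    if v.data.ndim != 3:
        raise GridError("resample_iso expects a 3D volume")
    spacing = v.voxel_size_mm
    # field of view spanned by voxel centers, per axis
    extent_mm = (np.array(v.shape3) - 1) * spacing
    new_shape = np.floor(extent_mm / target_mm + 1e-9).astype(int) + 1
    dirs = v.affine[:3, :3] / spacing  # unit direction cosines per column
    new_affine = np.eye(4)
    new_affine[:3, :3] = dirs * target_mm
    new_affine[:3, 3] = v.affine[:3, 3]

    # map output voxel indices to input voxel indices
    scale = target_mm / spacing
    order = 0 if is_label else 1
    out = np.empty(tuple(new_shape), dtype=float if not is_label else v.data.dtype)
    ndimage.affine_transform(
        v.data.astype(float) if not is_label else v.data,
        np.diag(scale),
        offset=0.0,
        output_shape=tuple(new_shape),
        output=out,
        order=order,
        mode="nearest",
    )
    return Volume(out, new_affine)


def normalize_intensity(v: Volume) -> Volume:
    """Affine min-max map of intensities onto [-1, 1].

    x -> 2 (x - min) / (max - min) - 1, so min maps to -1 and max to +1.
    Constant volumes are rejected (the scaling is undefined).
    """
    data = np.asarray(v.data, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise GridError("cannot normalize a constant volume")
    return Volume(2.0 * (data - lo) / (hi - lo) - 1.0, v.affine.copy())


def save_gradient_table(bvals: np.ndarray, bvecs: np.ndarray, prefix: str | Path) -> None:
    """Write FSL-style gradient tables: ``<prefix>.bval`` (one row) and
    ``<prefix>.bvec`` (three rows, one column per volume)."""
    bvals = np.atleast_1d(np.asarray(bvals, dtype=float))
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape != (len(bvals), 3):
        raise GridError("bvecs must have shape (n_volumes, 3)")
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), bvals[None, :], fmt="%.6g")
    np.savetxt(prefix.with_suffix(".bvec"), bvecs.T, fmt="%.8f")


def load_gradient_table(prefix: str | Path) -> tuple[np.ndarray, np.ndarray]:
    prefix = Path(prefix)
    bvals = np.loadtxt(prefix.with_suffix(".bval")).reshape(-1)
    bvecs = np.loadtxt(prefix.with_suffix(".bvec")).reshape(3, -1).T
    return bvals, bvecs


def save_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
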