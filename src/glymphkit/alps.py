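"""ALPS (diffusivity along perivascular spaces) index computation.

Four 5-mm spherical ROIs are placed at the lateral-ventricle-body level:
per hemisphere one in the projection-fiber area (tracts running
superior-inferior) and one in the association-fiber area (tracts running
anterior-posterior).  With x the left-right axis, the index per hemisphere
is

    ALPS = (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)

on ROI-mean tensor diagonal elements; the left/right mean is the
subject-level measure.  An index of 1 means no preferential diffusion
along the perivascular (x) direction; higher values indicate more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dti import TensorField
from .imgio import Volume


class RoiError(ValueError):
    """Raised when an ROI is empty or otherwise unusable."""


# Template-space ROI centers (mm).  The source protocol labels the
# positive-x pair "left"; pass laterality="radiological" to swap if the
# data follow the opposite convention.
DEFAULT_PROJ_LEFT = (24.0, -12.0, 24.0)
DEFAULT_PROJ_RIGHT = (-28.0, -12.0, 24.0)
DEFAULT_ASSOC_LEFT = (36.0, -12.0, 24.0)
DEFAULT_ASSOC_RIGHT = (-40.0, -12.0, 24.0)


@dataclass
class AlpsRoiSpec:
    proj_left_mm: tuple[float, float, float] = DEFAULT_PROJ_LEFT
    proj_right_mm: tuple[float, float, float] = DEFAULT_PROJ_RIGHT
    assoc_left_mm: tuple[float, float, float] = DEFAULT_ASSOC_LEFT
    assoc_right_mm: tuple[float, float, float] = DEFAULT_ASSOC_RIGHT
    diameter_mm: float = 5.0
    laterality: str = "printed"  # "printed" | "radiological"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise RoiError("sphere diameter must be positive")
        if self.laterality not in ("printed", "radiological"):
            raise RoiError("laterality must be 'printed' or 'radiological'")
        if self.laterality == "radiological":
            self.proj_left_mm, self.proj_right_mm = self.proj_right_mm, self.proj_left_mm
            self.assoc_left_mm, self.assoc_right_mm = self.assoc_right_mm, self.assoc_left_mm
            self.laterality = "printed"  # normalised; swap applied once

    def centers(self) -> dict[str, tuple[float, float, float]]:
        return {
            "proj_left": self.proj_left_mm,
            "proj_right": self.proj_right_mm,
            "assoc_left": self.assoc_left_mm,
            "assoc_right": self.assoc_right_mm,
        }


@dataclass
class AlpsResult:
    alps_left: float
    alps_right: float
    alps_mean: float
    diffusivities: dict[str, float] = field(default_factory=dict)
    roi_voxel_counts: dict[str, int] = field(default_factory=dict)


def sphere_mask(center_mm, diameter_mm: float, grid: Volume) -> np.ndarray:
    """Binary mask of voxels whose world centers lie within the sphere.

    Membership is boundary-inclusive: distance(center) <= diameter/2.
    """
    if diameter_mm <= 0:
        raise RoiError("sphere diameter must be positive")
    center = np.asarray(center_mm, dtype=float)
    shape = grid.shape3
    # bound the search box in voxel space to avoid scanning the whole grid
    radius = diameter_mm / 2.0
    cvox = grid.voxel_coords(center)
    pad = radius / grid.voxel_size_mm.min() + 2
    lo = np.maximum(np.floor(cvox - pad).astype(int), 0)
    hi = np.minimum(np.ceil(cvox + pad).astype(int) + 1, shape)
    if np.any(hi <= lo):
        raise RoiError(f"sphere at {tuple(center)} does not intersect the grid")
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    dists = np.linalg.norm(grid.world_coords(idx) - center, axis=1)
    mask = np.zeros(shape, bool)
    inside = idx[dists <= radius]
    if len(inside) == 0:
        raise RoiError(f"empty sphere ROI at center {tuple(center)}")
    mask[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    return mask


def project_roi(
    roi_mask_template: Volume,
    affine_template_to_subject: np.ndarray,
    subject_grid: Volume,
) -> np.ndarray:
    """Resample a template-space ROI mask onto the subject grid.

    The transform maps template world coordinates to subject world
    coordinates; resampling is nearest-neighbour (masks stay binary).
    """
    T = np.asarray(affine_template_to_subject, dtype=float)
    if T.shape != (4, 4) or abs(np.linalg.det(T[:3, :3])) < 1e-12:
        raise RoiError("template-to-subject transform must be an invertible 4x4")
    # subject voxel -> subject world -> template world -> template voxel
    full = np.linalg.inv(roi_mask_template.affine) @ np.linalg.inv(T) @ subject_grid.affine
    out = ndimage.affine_transform(
        roi_mask_template.data.astype(np.uint8),
        full[:3, :3],
        offset=full[:3, 3],
        output_shape=subject_grid.shape3,
        order=0,
        mode="constant",
        cval=0,
    ).astype(bool)
    if not out.any():
        raise RoiError("projected ROI is empty on the subject grid")
    return out


def compute_alps(tf: TensorField, rois: dict[str, np.ndarray]) -> AlpsResult:
    """ALPS indices from ROI-mean tensor diagonal elements.

    ``rois`` maps {proj_left, proj_right, assoc_left, assoc_right} to
    binary masks on the tensor grid.  Invalid tensor voxels are excluded
    from ROI means.
    """
    required = {"proj_left", "proj_right", "assoc_left", "assoc_right"}
    missing = required - rois.keys()
    if missing:
        raise RoiError(f"missing ROIs: {sorted(missing)}")

    def roi_mean(name: str, element: int) -> tuple[float, int]:
        m = np.asarray(rois[name], bool) & tf.valid
        n = int(m.sum())
        if n == 0:
            raise RoiError(f"ROI '{name}' contains no valid tensor voxels")
        return float(tf.tensor[m, element].mean()), n

    diffs: dict[str, float] = {}
    counts: dict[str, int] = {}
    out = {}
    for side in ("left", "right"):
        dx_proj, n1 = roi_mean(f"proj_{side}", 0)
        dy_proj, _ = roi_mean(f"proj_{side}", 1)
        dx_assoc, n2 = roi_mean(f"assoc_{side}", 0)
        dz_assoc, _ = roi_mean(f"assoc_{side}", 2)
        denom = dy_proj + dz_assoc
        if denom <= 0:
            raise RoiError(f"non-positive ALPS denominator on the {side} side")
        out[side] = (dx_proj + dx_assoc) / denom
        diffs.update(
            {
                f"dx_proj_{side}": dx_proj,
                f"dy_proj_{side}": dy_proj,
                f"dx_assoc_{side}": dx_assoc,
                f"dz_assoc_{side}": dz_assoc,
            }
        )
        counts[f"proj_{side}"] = n1
        counts[f"assoc_{side}"] = n2
    return AlpsResult(
        alps_left=out["left"],
        alps_right=out["right"],
        alps_mean=(out["left"] + out["right"]) / 2.0,
        diffusivities=diffs,
        roi_voxel_counts=counts,
    )


def alps_for_subject(
    tf: TensorField,
    affine_template_to_subject: np.ndarray,
    template_grid: Volume,
    roi_spec: AlpsRoiSpec | None = None,
) -> AlpsResult:
    """Place the template ROIs, project them to subject space, compute ALPS."""
    spec = roi_spec or AlpsRoiSpec()
    subject_grid = Volume(np.zeros(tf.tensor.shape[:3], np.uint8), tf.affine)
    rois = {}
    for name, center in spec.centers().items():
        tmask = sphere_mask(center, spec.diameter_mm, template_grid)
        rois[name] = project_roi(
            Volume(tmask.astype(np.uint8), template_grid.affine),
            affine_template_to_subject,
            subject_grid,
        )
    return compute_alps(tf, rois)
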