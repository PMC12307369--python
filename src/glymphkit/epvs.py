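"""Enlarged-perivascular-space (EPVS) morphometrics and agreement metrics.

EPVS appear as linear or ovoid CSF-isointense structures, typically
under 3 mm in diameter, concentrated in the basal ganglia (BG) and
centrum semiovale (CSO).  This module labels candidate lesions as
26-connected components, measures per-lesion length and volume, applies
the >= 2 mm minimum-length filter used to suppress false positives, and
computes voxelwise Dice / recall / precision between segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgio import Volume

# atlas label codes shared across the package
LABEL_BACKGROUND = 0
LABEL_BRAIN = 1
LABEL_BG = 2
LABEL_CSO = 3
LABEL_MIDBRAIN = 4
REGION_NAMES = {
    LABEL_BRAIN: "other",
    LABEL_BG: "BG",
    LABEL_CSO: "CSO",
    LABEL_MIDBRAIN: "midbrain",
}

# full 3x3x3 neighbourhood: 26-connectivity
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

# Table-style volume fractions are reported per mille of whole-brain volume
DEFAULT_FRACTION_SCALE = 1e3


class MaskError(ValueError):
    """Raised for incompatible grids or invalid mask inputs."""


@dataclass
class Lesion:
    lesion_id: int
    voxels: np.ndarray  # (n, 3) int indices
    volume_mm3: float
    length_mm: float
    region: str


@dataclass
class LesionSet:
    lesions: list[Lesion]
    affine: np.ndarray
    grid_shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.lesions)

    def total_volume_mm3(self) -> float:
        return float(sum(l.volume_mm3 for l in self.lesions))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lesion_id": [l.lesion_id for l in self.lesions],
                "region": [l.region for l in self.lesions],
                "volume_mm3": [l.volume_mm3 for l in self.lesions],
                "length_mm": [l.length_mm for l in self.lesions],
            }
        )

    def to_mask(self) -> np.ndarray:
        out = np.zeros(self.grid_shape, bool)
        for l in self.lesions:
            out[l.voxels[:, 0], l.voxels[:, 1], l.voxels[:, 2]] = True
        return out


@dataclass
class EpvsMetrics:
    total_volume_mm3: float
    total_number: int
    bg_fraction: float
    cso_fraction: float
    bg_volume_mm3: float = 0.0
    cso_volume_mm3: float = 0.0


@dataclass
class SegEval:
    tp: int
    fp: int
    fn: int
    dsc: float
    recall: float
    precision: float


def lesion_length_mm(voxels: np.ndarray, affine: np.ndarray) -> float:
    """Lesion length: spread of voxel centers along the first principal
    axis of their world-coordinate covariance, plus one voxel edge.

    For a straight tube this reduces to the end-to-end extent; adding one
    voxel edge accounts for the physical size of the end voxels (a single
    voxel has length one edge, not zero).
    """
    pts = voxels @ affine[:3, :3].T + affine[:3, 3]
    edge = float(np.linalg.norm(affine[:3, :3], axis=0).min())
    if len(pts) == 1:
        return edge
    centered = pts - pts.mean(axis=0)
    # principal direction of the point cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    return float(proj.max() - proj.min()) + edge


def label_lesions(mask: Volume | np.ndarray, atlas: Volume | None = None,
                  affine: np.ndarray | None = None) -> LesionSet:
    """Label 26-connected components of a binary mask as lesions.

    Per-lesion volume is voxel count x voxel volume; region membership is
    a majority vote of member voxels over the atlas labels.
    """
    if isinstance(mask, Volume):
        data = np.asarray(mask.data).astype(bool)
        aff = mask.affine
    else:
        data = np.asarray(mask).astype(bool)
        aff = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    atlas_data = None
    if atlas is not None:
        atlas_data = np.asarray(atlas.data if isinstance(atlas, Volume) else atlas)
        if atlas_data.shape != data.shape:
            raise MaskError("atlas grid does not match the mask grid")

    labels, n = ndimage.label(data, structure=STRUCT_26)
    voxvol = float(abs(np.linalg.det(aff[:3, :3])))
    lesions: list[Lesion] = []
    objects = ndimage.find_objects(labels)
    for i in range(1, n + 1):
        sl = objects[i - 1]
        local = np.argwhere(labels[sl] == i)
        vox = local + np.array([s.start for s in sl])
        region = "other"
        if atlas_data is not None:
            codes, counts = np.unique(
                atlas_data[vox[:, 0], vox[:, 1], vox[:, 2]], return_counts=True
            )
            region = REGION_NAMES.get(int(codes[np.argmax(counts)]), "other")
        lesions.append(
            Lesion(
                lesion_id=i,
                voxels=vox,
                volume_mm3=len(vox) * voxvol,
                length_mm=lesion_length_mm(vox, aff),
                region=region,
            )
        )
    return LesionSet(lesions=lesions, affine=aff, grid_shape=data.shape)


def filter_by_length(ls: LesionSet, min_length_mm: float = 2.0) -> LesionSet:
    """Drop lesions shorter than ``min_length_mm`` (boundary inclusive:
    a lesion of exactly the threshold length is retained)."""
    if min_length_mm < 0:
        raise MaskError("length threshold must be non-negative")
    kept = [l for l in ls.lesions if l.length_mm >= min_length_mm]
    return LesionSet(lesions=kept, affine=ls.affine, grid_shape=ls.grid_shape)


def lesion_metrics(
    ls: LesionSet,
    atlas: Volume,
    fraction_scale: float = DEFAULT_FRACTION_SCALE,
) -> EpvsMetrics:
    """Total EPVS volume/number and regional volume fractions.

    Regional fraction = (volume of lesions assigned to the region) /
    whole-brain volume x ``fraction_scale``.  Whole brain is every atlas
    voxel with a non-background label.
    """
    atlas_data = np.asarray(atlas.data)
    if atlas_data.shape != ls.grid_shape:
        raise MaskError("atlas grid does not match the lesion grid")
    voxvol = atlas.voxel_volume_mm3()
    brain_vol = float((atlas_data != LABEL_BACKGROUND).sum()) * voxvol
    if brain_vol <= 0:
        raise MaskError("whole-brain volume is zero")
    bg_vol = sum(l.volume_mm3 for l in ls.lesions if l.region == "BG")
    cso_vol = sum(l.volume_mm3 for l in ls.lesions if l.region == "CSO")
    return EpvsMetrics(
        total_volume_mm3=ls.total_volume_mm3(),
        total_number=len(ls),
        bg_fraction=bg_vol / brain_vol * fraction_scale,
        cso_fraction=cso_vol / brain_vol * fraction_scale,
        bg_volume_mm3=float(bg_vol),
        cso_volume_mm3=float(cso_vol),
    )


@dataclass
class SegmenterParams:
    """Thresholds for the rule-based stand-in segmenter on [-1, 1] images."""

    t1_max: float = -0.3  # EPVS are dark (CSF-like) on T1
    t2_min: float = 0.3   # and bright on T2
    max_diameter_mm: float | None = None  # optional STRIVE-style size veto


def segment_epvs_rulebased(
    t1_like: Volume,
    t2_like: Volume,
    atlas: Volume,
    params: SegmenterParams | None = None,
) -> np.ndarray:
    """Intensity-rule segmentation of CSF-isointense tubular lesions.

    A voxel is a candidate iff it is dark on T1, bright on T2 and inside
    the brain label.  If ``max_diameter_mm`` is set, components whose
    maximum cross-sectional extent perpendicular to their principal axis
    exceeds it are removed (EPVS are < 3 mm in diameter by convention).
    This is a transparent rule-based segmenter, not a learned model.
    """
    params = params or SegmenterParams()
    if not (t1_like.same_grid(t2_like) and t1_like.same_grid(atlas)):
        raise MaskError("T1, T2 and atlas must share one grid")
    brain = np.asarray(atlas.data) != LABEL_BACKGROUND
    cand = (
        (np.asarray(t1_like.data) <= params.t1_max)
        & (np.asarray(t2_like.data) >= params.t2_min)
        & brain
    )
    if params.max_diameter_mm is not None and cand.any():
        labels, n = ndimage.label(cand, structure=STRUCT_26)
        aff = t1_like.affine
        for i in range(1, n + 1):
            vox = np.argwhere(labels == i)
            pts = vox @ aff[:3, :3].T
            if len(pts) > 1:
                centered = pts - pts.mean(axis=0)
                _, _, vt = np.linalg.svd(centered, full_matrices=False)
                perp = centered - np.outer(centered @ vt[0], vt[0])
                width = 2 * np.linalg.norm(perp, axis=1).max()
                if width > params.max_diameter_mm:
                    cand[labels == i] = False
    return cand


def seg_eval(pred, refs, mode: str = "single") -> SegEval:
    """Voxelwise agreement between a predicted mask and reference masks.

    mode "single" uses the one given reference; "union"/"intersection"
    combine two rater masks voxelwise first.  Conventions: both masks
    empty -> all metrics 1 (perfect agreement on absence); exactly one
    empty -> all metrics 0.
    """
    def as_mask(m):
        return np.asarray(m.data if isinstance(m, Volume) else m).astype(bool)

    pred_m = as_mask(pred)
    if isinstance(refs, (list, tuple)):
        ref_list = [as_mask(r) for r in refs]
    else:
        ref_list = [as_mask(refs)]
    for r in ref_list:
        if r.shape != pred_m.shape:
            raise MaskError("prediction and reference grids differ")

    if mode == "single":
        if len(ref_list) != 1:
            raise MaskError("mode 'single' takes exactly one reference mask")
        ref_m = ref_list[0]
    elif mode in ("union", "intersection"):
        if len(ref_list) != 2:
            raise MaskError(f"mode '{mode}' requires two reference masks")
        ref_m = ref_list[0] | ref_list[1] if mode == "union" else ref_list[0] & ref_list[1]
    else:
        raise MaskError(f"unknown mode '{mode}'")

    tp = int(np.count_nonzero(pred_m & ref_m))
    fp = int(np.count_nonzero(pred_m & ~ref_m))
    fn = int(np.count_nonzero(~pred_m & ref_m))
    if tp == fp == fn == 0:  # both empty
        return SegEval(0, 0, 0, 1.0, 1.0, 1.0)
    dsc = 2 * tp / (2 * tp + fp + fn)
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    return SegEval(tp, fp, fn, dsc, recall, precision)
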