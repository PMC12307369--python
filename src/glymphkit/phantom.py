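"""Ground-truthed synthetic MRI phantom: single subjects and cohorts.

The phantom emulates the imaging substrate the ALPS/EPVS analysis needs
at the lateral-ventricle-body level:

* a diagonal diffusion-tensor field with a projection-fiber slab
  (principal axis superior-inferior, z) and an association-fiber slab
  (principal axis anterior-posterior, y).  In both slabs the left-right
  (x) diffusivity is ``g * D_PERP`` where ``g`` is the subject's true
  ALPS index, and the two denominator diffusivities (Dyy in the
  projection slab, Dzz in the association slab) are ``D_PERP`` — so the
  ALPS formula recovers ``g`` by construction;
* DWI signals S = S0 exp(-b g^T D g) with Rician noise at a configured
  SNR (noise on the two quadrature channels of the complex signal);
* tubular CSF-isointense lesions (dark on T1, bright on T2, diameter one
  voxel < 3 mm) planted in the basal-ganglia and centrum-semiovale
  boxes, every lesion at least two voxels long so it survives the 2 mm
  length filter;
* cohort-level group structure: per-subject ALPS drawn from a normal,
  per-subject lesion count and total lesion volume from lognormals, and
  cognitive scores linearly linked to ALPS.

The template world frame is MNI-like with the origin at the grid
center, so the published ROI millimetre coordinates fall inside the
fiber slabs without any further offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dti import DiffusionAcquisition
from .epvs import (
    LABEL_BACKGROUND,
    LABEL_BG,
    LABEL_BRAIN,
    LABEL_CSO,
    LABEL_MIDBRAIN,
    STRUCT_26,
)
from .imgio import Volume
from scipy import ndimage

# diffusivities (mm^2/s)
D_PERP = 0.4e-3    # denominator diffusivities: Dyy(proj) = Dzz(assoc)
D_AXIAL = 1.4e-3   # along-fiber diffusivity, typical coherent white matter
D_ISO = 0.8e-3     # isotropic brain background

# structural intensities (arbitrary units on roughly [-1, 1])
T1_BACKGROUND, T1_TISSUE, T1_LESION = -1.0, 0.5, -0.8
T2_BACKGROUND, T2_TISSUE, T2_LESION = -1.0, -0.2, 0.9


class PhantomConfigError(ValueError):
    """Raised for invalid phantom specifications."""


class LesionPlacementError(RuntimeError):
    """Raised when the requested lesion count cannot be placed."""


# largest single lesion, in voxels (135 mm^3 at 1.5 mm spacing); single
# perivascular spaces larger than this are not anatomically plausible
MAX_LESION_VOX = 40

# correlation between the lognormal draws of per-subject lesion count and
# total lesion volume: subjects with more lesions carry more total volume
LESION_VOL_COUNT_RHO = 0.6


Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open voxel extents


def _default_region_boxes() -> dict[str, Box]:
    return {
        "brain": ((4, 60), (4, 60), (2, 38)),
        "bg": ((20, 44), (24, 40), (8, 18)),
        "cso": ((16, 48), (20, 44), (22, 32)),
        "midbrain": ((28, 36), (28, 36), (2, 8)),
        # the association slab spans the full peritrigonal band; the
        # projection slab sits inside it and takes precedence where they
        # overlap, so each ROI sphere samples the intended tensor type
        "proj_slab": ((10, 52), (18, 30), (30, 38)),
        "assoc_slab": ((2, 60), (18, 30), (30, 38)),
    }


@dataclass
class PhantomSpec:
    """Geometry and acquisition parameters of the phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_size_mm: float = 1.5
    region_boxes: dict[str, Box] = field(default_factory=_default_region_boxes)
    s0: float = 1000.0
    snr: float | None = 30.0  # None disables noise
    n_directions: int = 25
    bval: float = 1000.0
    noise_model: str = "rician"  # or "gaussian"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] *= self.voxel_size_mm
        a[:3, 3] = -np.asarray(self.grid_shape) * self.voxel_size_mm / 2.0
        return a

    def grid(self) -> Volume:
        return Volume(np.zeros(self.grid_shape, np.uint8), self.affine)

    def validate(self) -> None:
        if self.voxel_size_mm <= 0:
            raise PhantomConfigError("voxel size must be positive")
        if self.snr is not None and not (self.snr > 0):
            raise PhantomConfigError("snr must be positive (or None for noiseless)")
        if self.noise_model not in ("rician", "gaussian"):
            raise PhantomConfigError("noise_model must be 'rician' or 'gaussian'")
        required = {"brain", "bg", "cso", "midbrain", "proj_slab", "assoc_slab"}
        missing = required - self.region_boxes.keys()
        if missing:
            raise PhantomConfigError(f"missing region boxes: {sorted(missing)}")
        for name, box in self.region_boxes.items():
            for ax, (lo, hi) in enumerate(box):
                if not (0 <= lo < hi <= self.grid_shape[ax]):
                    raise PhantomConfigError(
                        f"region box '{name}' extends outside the grid on axis {ax}"
                    )
        if _boxes_overlap(self.region_boxes["bg"], self.region_boxes["cso"]):
            raise PhantomConfigError("region boxes 'bg' and 'cso' overlap")


def _boxes_overlap(a: Box, b: Box) -> bool:
    return all(a[ax][0] < b[ax][1] and b[ax][0] < a[ax][1] for ax in range(3))


def _box_mask(shape, box: Box) -> np.ndarray:
    m = np.zeros(shape, bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    m[x0:x1, y0:y1, z0:z1] = True
    return m


@dataclass
class GroupConfig:
    """Cohort-level generator calibration for one diagnostic group."""

    name: str
    n_subjects: int
    alps_mean: float
    alps_between_sd: float
    lesion_count_log_median: float
    lesion_count_log_sigma: float
    total_vol_log_median_mm3: float
    total_vol_log_sigma: float
    bg_share: float = 0.8
    mmse_slope: float = 0.0
    mmse_intercept: float = 25.0
    mmse_noise_sd: float = 0.0
    moca_slope: float = 0.0
    moca_intercept: float = 25.0
    moca_noise_sd: float = 0.0
    age_mean: float = 67.0
    age_sd: float = 9.0
    male_p: float = 0.5
    edu_mean: float = 8.0
    edu_sd: float = 4.0
    brain_vol_mean: float = 1.45e6
    brain_vol_sd: float = 1.3e5

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise PhantomConfigError("n_subjects must be >= 1")
        if self.alps_mean <= 0:
            raise PhantomConfigError("alps_mean must be positive")
        if min(self.alps_between_sd, self.lesion_count_log_sigma,
               self.total_vol_log_sigma, self.mmse_noise_sd, self.moca_noise_sd) < 0:
            raise PhantomConfigError("sigmas must be non-negative")
        if not 0 <= self.bg_share <= 1:
            raise PhantomConfigError("bg_share must lie in [0, 1]")


# ---------------------------------------------------------------------------
# default cohort calibration
# ---------------------------------------------------------------------------

# group summary values the generator is calibrated to: mean-ALPS SEM and n
# per group, EPVS total-volume and count medians with upper quartiles, and
# cognitive score means/SDs
_CAL = {
    "AD": dict(n=89, alps=1.308, alps_sem=0.015,
               vol_med=457.5, vol_q3=735.4, cnt_med=19.0, cnt_q3=29.0,
               mmse=17.27, mmse_sd=5.670, moca=13.38, moca_sd=6.173,
               age=68.750, age_sd=9.292, male=40 / 89, edu=7.83, edu_sd=4.360),
    "aMCI": dict(n=24, alps=1.450, alps_sem=0.040,
                 vol_med=330.9, vol_q3=512.4, cnt_med=14.0, cnt_q3=20.5,
                 mmse=25.92, mmse_sd=0.974, moca=20.88, moca_sd=3.982,
                 age=67.250, age_sd=9.317, male=12 / 24, edu=8.25, edu_sd=4.173),
    "NC": dict(n=32, alps=1.570, alps_sem=0.027,
               vol_med=320.6, vol_q3=473.7, cnt_med=12.0, cnt_q3=17.5,
               mmse=28.59, mmse_sd=0.798, moca=27.28, moca_sd=1.420,
               age=65.410, age_sd=7.551, male=12 / 32, edu=8.72, edu_sd=2.543),
}

# Z_75: standard-normal upper quartile; a lognormal's Q3/median ratio is
# exp(sigma * Z_75), so sigma = ln(Q3/median) / Z_75
_Z75 = 0.6745


def _cognition_links() -> dict[str, tuple[float, float]]:
    """Shared ALPS->score slopes (least squares through the three group
    means) and per-group intercepts that re-center each group exactly."""
    x = np.array([_CAL[g]["alps"] for g in _CAL])
    out = {}
    for score in ("mmse", "moca"):
        y = np.array([_CAL[g][score] for g in _CAL])
        slope = float(np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2))
        out[score] = slope
    return out


def default_groups(n_subjects: dict[str, int] | None = None) -> list[GroupConfig]:
    """AD / aMCI / NC generator configurations at the default calibration.

    The between-subject ALPS SD is the printed SEM of the group mean
    scaled by sqrt(n).  Cognitive noise SDs absorb whatever score
    variance the ALPS link does not explain (floored at zero).
    """
    slopes = _cognition_links()
    groups = []
    for name, c in _CAL.items():
        n = (n_subjects or {}).get(name, c["n"])
        alps_sd = c["alps_sem"] * math.sqrt(c["n"])
        cfg = dict(
            name=name,
            n_subjects=n,
            alps_mean=c["alps"],
            alps_between_sd=alps_sd,
            lesion_count_log_median=math.log(c["cnt_med"]),
            lesion_count_log_sigma=math.log(c["cnt_q3"] / c["cnt_med"]) / _Z75,
            total_vol_log_median_mm3=math.log(c["vol_med"]),
            total_vol_log_sigma=math.log(c["vol_q3"] / c["vol_med"]) / _Z75,
            age_mean=c["age"], age_sd=c["age_sd"], male_p=c["male"],
            edu_mean=c["edu"], edu_sd=c["edu_sd"],
        )
        for score in ("mmse", "moca"):
            slope = slopes[score]
            resid_var = c[f"{score}_sd"] ** 2 - slope**2 * alps_sd**2
            cfg[f"{score}_slope"] = slope
            cfg[f"{score}_intercept"] = c[score] - slope * c["alps"]
            cfg[f"{score}_noise_sd"] = math.sqrt(max(0.0, resid_var))
        groups.append(GroupConfig(**cfg))
    return groups


# ---------------------------------------------------------------------------
# atlas and tensor field
# ---------------------------------------------------------------------------

def make_template_atlas(spec: PhantomSpec) -> Volume:
    """Labeled template volume: 0 background, 1 brain, 2 BG, 3 CSO,
    4 midbrain.  BG/CSO/midbrain are disjoint boxes inside the brain."""
    spec.validate()
    for a, b in (("bg", "cso"), ("bg", "midbrain"), ("cso", "midbrain")):
        if _boxes_overlap(spec.region_boxes[a], spec.region_boxes[b]):
            raise PhantomConfigError(f"region boxes '{a}' and '{b}' overlap")
    lab = np.zeros(spec.grid_shape, np.uint8)
    lab[_box_mask(spec.grid_shape, spec.region_boxes["brain"])] = LABEL_BRAIN
    lab[_box_mask(spec.grid_shape, spec.region_boxes["bg"])] = LABEL_BG
    lab[_box_mask(spec.grid_shape, spec.region_boxes["cso"])] = LABEL_CSO
    lab[_box_mask(spec.grid_shape, spec.region_boxes["midbrain"])] = LABEL_MIDBRAIN
    return Volume(lab, spec.affine)


def tensor_field_for_alps(spec: PhantomSpec, g: float) -> np.ndarray:
    """Diagonal diffusivities (x, y, z, 3) realising a true ALPS of ``g``."""
    diag = np.zeros(spec.grid_shape + (3,))
    brain = _box_mask(spec.grid_shape, spec.region_boxes["brain"])
    diag[brain] = D_ISO
    assoc = _box_mask(spec.grid_shape, spec.region_boxes["assoc_slab"]) & brain
    proj = _box_mask(spec.grid_shape, spec.region_boxes["proj_slab"]) & brain
    assoc &= ~proj  # projection slab takes precedence in the overlap
    diag[assoc] = (g * D_PERP, D_AXIAL, D_PERP)
    diag[proj] = (g * D_PERP, D_PERP, D_AXIAL)
    return diag


def gradient_scheme(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """One b=0 volume plus ``n_directions`` directions on a spherical
    Fibonacci lattice (deterministic, well spread)."""
    n = spec.n_directions
    i = np.arange(n) + 0.5
    phi = math.pi * (1 + math.sqrt(5)) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([[0.0], np.full(n, spec.bval)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return bvals, bvecs


def _synth_dwi(spec: PhantomSpec, diag: np.ndarray, rng: np.random.Generator) -> DiffusionAcquisition:
    bvals, bvecs = gradient_scheme(spec)
    brain = _box_mask(spec.grid_shape, spec.region_boxes["brain"])
    # diagonal tensor: exponent = -b (gx^2 Dxx + gy^2 Dyy + gz^2 Dzz)
    atten = np.einsum("xyzc,vc->xyzv", diag, bvals[:, None] * bvecs**2)
    signals = (spec.s0 * np.exp(-atten) * brain[..., None]).astype(np.float32)
    if spec.snr is not None and np.isfinite(spec.snr):
        sigma = spec.s0 / spec.snr
        if spec.noise_model == "rician":
            n1 = rng.normal(0.0, sigma, signals.shape).astype(np.float32)
            n2 = rng.normal(0.0, sigma, signals.shape).astype(np.float32)
            signals = np.sqrt((signals + n1) ** 2 + n2**2)
        else:
            signals = signals + rng.normal(0.0, sigma, signals.shape).astype(np.float32)
    return DiffusionAcquisition(
        signals=signals, bvals=bvals, bvecs=bvecs, affine=spec.affine, mask=brain
    )


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

def _apportion(total: int, weights: np.ndarray, min_size: int,
               max_size: int | None = None) -> np.ndarray:
    """Split ``total`` into integer parts proportional to ``weights`` by
    largest remainder, each part in [min_size, max_size]; the parts sum
    to ``total`` exactly when the bounds allow it."""
    ideal = weights / weights.sum() * total
    sizes = np.floor(ideal).astype(int)
    rema = ideal - sizes
    for i in np.argsort(-rema)[: total - sizes.sum()]:
        sizes[i] += 1
    # enforce the floor by taking voxels from the largest parts
    while np.any(sizes < min_size):
        i = int(np.argmin(sizes))
        j = int(np.argmax(sizes))
        take = min(min_size - sizes[i], sizes[j] - min_size)
        if take <= 0:
            break  # total == min_size * n; everything is at the floor
        sizes[i] += take
        sizes[j] -= take
    if max_size is not None:
        # shave oversized parts onto the smallest ones
        while np.any(sizes > max_size):
            i = int(np.argmax(sizes))
            j = int(np.argmin(sizes))
            give = min(sizes[i] - max_size, max_size - sizes[j])
            if give <= 0:
                break  # total exceeds n * max_size; leave the excess
            sizes[i] -= give
            sizes[j] += give
    return sizes


def _plant_lesions(
    spec: PhantomSpec,
    n_lesions: int,
    total_volume_mm3: float,
    bg_share: float,
    rng: np.random.Generator,
    max_tries: int = 500,
) -> np.ndarray:
    """Plant ``n_lesions`` one-voxel-thick digital tubes with total volume
    close to the target.  Lesions never touch each other under
    26-connectivity and each has at least 2 voxels (length >= 2 mm after
    the standard length definition).  Raises on placement shortfall."""
    voxvol = spec.voxel_size_mm**3
    weights = rng.lognormal(0.0, 0.5, n_lesions)
    weights /= weights.sum()
    # every lesion needs >= 2 voxels to survive the 2 mm length filter;
    # the cap keeps single tubes placeable inside the region boxes (it
    # truncates only the extreme upper tail, leaving medians untouched)
    total_vox = int(np.rint(total_volume_mm3 / voxvol))
    total_vox = min(max(total_vox, 2 * n_lesions), MAX_LESION_VOX * n_lesions)
    sizes = _apportion(total_vox, weights, min_size=2, max_size=MAX_LESION_VOX)
    in_bg = rng.random(n_lesions) < bg_share

    # voxel enumeration per region, reused across lesions
    box_voxels = {
        name: np.argwhere(_box_mask(spec.grid_shape, spec.region_boxes[name]))
        for name in ("bg", "cso")
    }
    mask = np.zeros(spec.grid_shape, bool)
    blocked = np.zeros(spec.grid_shape, bool)  # lesions dilated by one voxel
    for k in range(n_lesions):
        first = "bg" if in_bg[k] else "cso"
        # if the preferred region is too crowded, fall back to the other
        regions = [first, "cso" if first == "bg" else "bg"]
        placed = False
        for region in regions:
            if placed:
                break
            cand_all = box_voxels[region]
            extents = np.array(
                [hi - lo for lo, hi in spec.region_boxes[region]], float
            )
            for _ in range(max_tries):
                start = cand_all[rng.integers(len(cand_all))].astype(float)
                d = rng.normal(size=3)
                if sizes[k] > 20:
                    # long tubes follow the region's long axis (penetrating
                    # vessels run the length of the structure)
                    d = 0.35 * d + rng.choice([-1.0, 1.0], 3) * extents / extents.max()
                d /= np.linalg.norm(d)
                # digital tube: voxels within 1 voxel of the line through
                # start along d, ordered by position along the axis
                rel = cand_all - start
                t = rel @ d
                perp = np.linalg.norm(rel - np.outer(t, d), axis=1)
                tube = perp <= 1.0
                idx_tube = cand_all[tube][np.argsort(t[tube], kind="stable")]
                if len(idx_tube) < sizes[k]:
                    continue
                # first contiguous window of the tube free of other lesions
                free = ~blocked[idx_tube[:, 0], idx_tube[:, 1], idx_tube[:, 2]]
                csum = np.concatenate([[0], np.cumsum(free)])
                wins = np.flatnonzero(
                    csum[sizes[k]:] - csum[:-sizes[k]] == sizes[k]
                )
                if len(wins) == 0:
                    continue
                vox = idx_tube[wins[0]: wins[0] + sizes[k]]
                # the tube must be one 26-connected component
                lo = vox.min(axis=0)
                sub = np.zeros(vox.max(axis=0) - lo + 1, bool)
                sub[tuple((vox - lo).T)] = True
                if ndimage.label(sub, structure=STRUCT_26)[1] != 1:
                    continue
                mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
                dlo = np.maximum(lo - 2, 0)
                dhi = np.minimum(vox.max(axis=0) + 3, spec.grid_shape)
                win = tuple(slice(dlo[a], dhi[a]) for a in range(3))
                blocked[win] |= ndimage.binary_dilation(mask[win], STRUCT_26)
                placed = True
                break
        if not placed:
            raise LesionPlacementError(
                f"could not place lesion {k + 1}/{n_lesions} after {max_tries} tries"
            )
    return mask


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    alps: float
    lesion_count: int
    lesion_total_volume_mm3: float  # voxelised (as planted)
    lesion_target_volume_mm3: float  # continuous draw before voxelisation
    mmse: float
    moca: float
    age: float
    sex: int  # 1 = male
    education: float
    total_brain_volume_mm3: float


@dataclass
class SubjectBundle:
    t1_like: Volume
    t2_like: Volume
    dwi: DiffusionAcquisition | None
    gt_epvs_mask: Volume
    atlas: Volume
    affine_template_to_subject: np.ndarray
    truth: SubjectTruth


def _draw_truth(rng: np.random.Generator, group: GroupConfig,
                subject_id: str) -> SubjectTruth:
    g = group.alps_mean + group.alps_between_sd * rng.standard_normal()
    # correlated lognormals: the correlation leaves both marginals (and
    # hence the calibrated medians and quartiles) unchanged
    z1, z2 = rng.standard_normal(2)
    zv = LESION_VOL_COUNT_RHO * z1 + math.sqrt(1 - LESION_VOL_COUNT_RHO**2) * z2
    count = max(1, int(np.rint(math.exp(
        group.lesion_count_log_median + group.lesion_count_log_sigma * z1))))
    vol = math.exp(group.total_vol_log_median_mm3 + group.total_vol_log_sigma * zv)
    mmse = np.clip(group.mmse_intercept + group.mmse_slope * g
                   + group.mmse_noise_sd * rng.standard_normal(), 0.0, 30.0)
    moca = np.clip(group.moca_intercept + group.moca_slope * g
                   + group.moca_noise_sd * rng.standard_normal(), 0.0, 30.0)
    return SubjectTruth(
        subject_id=subject_id,
        group=group.name,
        alps=float(g),
        lesion_count=count,
        lesion_total_volume_mm3=float("nan"),  # filled after planting
        lesion_target_volume_mm3=float(vol),
        mmse=float(mmse),
        moca=float(moca),
        age=float(group.age_mean + group.age_sd * rng.standard_normal()),
        sex=int(rng.random() < group.male_p),
        education=float(max(0.0, group.edu_mean + group.edu_sd * rng.standard_normal())),
        total_brain_volume_mm3=float(
            group.brain_vol_mean + group.brain_vol_sd * rng.standard_normal()
        ),
    )


def synth_subject(
    spec: PhantomSpec,
    group: GroupConfig,
    subject_seed: int,
    *,
    include_dwi: bool = True,
    subject_id: str | None = None,
) -> SubjectBundle:
    """Generate one fully ground-truthed subject.

    Independent substreams are used for the truth scalars, the lesion
    geometry, the DWI noise and the structural noise, so toggling
    ``include_dwi`` does not perturb the other draws.
    """
    spec.validate()
    ss = np.random.SeedSequence(subject_seed)
    rng_truth, rng_lesion, rng_dwi, rng_struct = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    sid = subject_id or f"{group.name}_{subject_seed}"
    truth = _draw_truth(rng_truth, group, sid)

    atlas = make_template_atlas(spec)
    lesion_mask = _plant_lesions(
        spec, truth.lesion_count, truth.lesion_target_volume_mm3,
        group.bg_share, rng_lesion,
    )
    truth.lesion_total_volume_mm3 = float(
        lesion_mask.sum() * spec.voxel_size_mm**3
    )

    dwi = None
    if include_dwi:
        diag = tensor_field_for_alps(spec, truth.alps)
        dwi = _synth_dwi(spec, diag, rng_dwi)

    brain = np.asarray(atlas.data) != LABEL_BACKGROUND
    t1 = np.full(spec.grid_shape, T1_BACKGROUND)
    t2 = np.full(spec.grid_shape, T2_BACKGROUND)
    t1[brain] = T1_TISSUE
    t2[brain] = T2_TISSUE
    t1[lesion_mask] = T1_LESION
    t2[lesion_mask] = T2_LESION
    if spec.snr is not None and np.isfinite(spec.snr):
        sd = 1.0 / spec.snr
        t1 = t1 + rng_struct.normal(0.0, sd, spec.grid_shape)
        t2 = t2 + rng_struct.normal(0.0, sd, spec.grid_shape)

    return SubjectBundle(
        t1_like=Volume(t1, spec.affine),
        t2_like=Volume(t2, spec.affine),
        dwi=dwi,
        gt_epvs_mask=Volume(lesion_mask, spec.affine),
        atlas=atlas,
        affine_template_to_subject=np.eye(4),
        truth=truth,
    )


def _subject_seeds(seed: int, n: int) -> np.ndarray:
    # deterministic per-subject seeds below 2^31
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) & 0x7FFFFFFF


def truth_table(truths: list[SubjectTruth]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truths])


def iter_cohort(
    spec: PhantomSpec,
    groups: list[GroupConfig],
    seed: int,
    *,
    include_dwi: bool = True,
):
    """Yield subject bundles one at a time (memory-friendly for full
    cohorts with DWI)."""
    if len(groups) == 0:
        raise PhantomConfigError("need at least one group")
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise PhantomConfigError("duplicate group names")
    n_total = sum(g.n_subjects for g in groups)
    seeds = _subject_seeds(seed, n_total)
    i = 0
    for group in groups:
        for j in range(group.n_subjects):
            yield synth_subject(
                spec, group, int(seeds[i]),
                include_dwi=include_dwi,
                subject_id=f"{group.name}_{j:03d}",
            )
            i += 1


@dataclass
class CohortBundle:
    bundles: list[SubjectBundle]
    truths: pd.DataFrame


def synth_cohort(
    spec: PhantomSpec,
    groups: list[GroupConfig],
    seed: int,
    *,
    include_dwi: bool = True,
) -> CohortBundle:
    """Materialise a whole cohort.  For large cohorts with DWI prefer
    :func:`iter_cohort` and process subjects streamingly."""
    bundles = list(iter_cohort(spec, groups, seed, include_dwi=include_dwi))
    return CohortBundle(bundles=bundles, truths=truth_table([b.truth for b in bundles]))


def draw_cohort_truths(groups: list[GroupConfig], seed: int) -> pd.DataFrame:
    """Scalar-only cohort draw (no images): the same truth stream the
    imaging generator uses, for calibration and power checks."""
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise PhantomConfigError("duplicate group names")
    n_total = sum(g.n_subjects for g in groups)
    seeds = _subject_seeds(seed, n_total)
    truths = []
    i = 0
    for group in groups:
        for j in range(group.n_subjects):
            ss = np.random.SeedSequence(int(seeds[i]))
            rng_truth = np.random.default_rng(ss.spawn(4)[0])
            truths.append(_draw_truth(rng_truth, group, f"{group.name}_{j:03d}"))
            i += 1
    return truth_table(truths)


# ---------------------------------------------------------------------------
# rater simulation
# ---------------------------------------------------------------------------

def simulate_rater(
    mask: np.ndarray | Volume,
    mode: str,
    rate: float,
    seed: int,
    brain: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate a human rater revising a segmentation at its boundary.

    add_only flips outside boundary voxels into the mask (output is a
    superset of the input); delete_only removes inside boundary voxels
    (subset); mixed does both.  Each eligible boundary voxel is flipped
    independently with probability ``rate``.  Added voxels never leave
    the brain label when one is supplied.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if mode not in ("add_only", "delete_only", "mixed"):
        raise ValueError(f"unknown rater mode '{mode}'")
    m = np.asarray(mask.data if isinstance(mask, Volume) else mask).astype(bool)
    rng = np.random.default_rng(seed)
    out = m.copy()
    if mode in ("add_only", "mixed"):
        halo = ndimage.binary_dilation(m, STRUCT_26) & ~m
        if brain is not None:
            halo &= np.asarray(brain, bool)
        cand = np.argwhere(halo)
        pick = rng.random(len(cand)) < rate
        sel = cand[pick]
        out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    if mode in ("delete_only", "mixed"):
        interior = ndimage.binary_erosion(m, STRUCT_26, border_value=0)
        boundary = np.argwhere(m & ~interior)
        pick = rng.random(len(boundary)) < rate
        sel = boundary[pick]
        out[sel[:, 0], sel[:, 1], sel[:, 2]] = False
    return out


def validate_roi_containment(spec: PhantomSpec, roi_spec=None) -> None:
    """Check that each ALPS ROI sphere lies inside its fiber slab."""
    from .alps import AlpsRoiSpec, sphere_mask

    rs = roi_spec or AlpsRoiSpec()
    grid = spec.grid()
    proj = _box_mask(spec.grid_shape, spec.region_boxes["proj_slab"])
    assoc = _box_mask(spec.grid_shape, spec.region_boxes["assoc_slab"])
    for name, center in rs.centers().items():
        m = sphere_mask(center, rs.diameter_mm, grid)
        slab = proj if name.startswith("proj") else assoc
        if not np.all(slab[m]):
            raise PhantomConfigError(
                f"ALPS ROI '{name}' is not contained in its fiber slab"
            )
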