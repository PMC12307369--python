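"""Diffusion tensor estimation and scalar maps (FA, MD).

The tensor is fit per voxel by unweighted log-linear least squares on

    ln S_i = ln S0 - b_i * g_i^T D g_i

over all acquired volumes.  Tensor axes are the image axes, so the
diagonal elements Dxx/Dyy/Dzz are the diffusivities along left-right,
anterior-posterior and superior-inferior for an axial acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# eigenvalue floor (mm^2/s): keeps diffusivities positive under noise so
# downstream ALPS denominators cannot vanish
EIG_FLOOR = 1e-6

# ordering of the unique tensor elements in TensorField.tensor
TENSOR_ELEMENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


class AcquisitionError(ValueError):
    """Raised when a diffusion acquisition cannot support a tensor fit."""


@dataclass
class DiffusionAcquisition:
    """4D diffusion signals plus the gradient scheme.

    signals: (x, y, z, n_volumes); bvals: (n_volumes,) in s/mm^2;
    bvecs: (n_volumes, 3) unit directions for b > 0; mask: brain mask.
    """

    signals: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).reshape(-1)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.signals.ndim != 4:
            raise AcquisitionError("signals must be 4D (x, y, z, volume)")
        n = self.signals.shape[3]
        if len(self.bvals) != n or self.bvecs.shape != (n, 3):
            raise AcquisitionError("bvals/bvecs length must match volume count")
        self.validate()

    def validate(self) -> None:
        dwi = self.bvals > 0
        if not np.any(self.bvals == 0):
            raise AcquisitionError("need at least one b=0 volume")
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise AcquisitionError("b>0 gradient directions must be unit norm")
        if _n_independent_directions(self.bvecs[dwi]) < 6:
            raise AcquisitionError(
                "need >= 6 non-collinear diffusion directions for a tensor fit"
            )


def _n_independent_directions(vecs: np.ndarray) -> int:
    """Rank of the quadratic-form design spanned by the directions."""
    if len(vecs) == 0:
        return 0
    g = vecs
    quad = np.column_stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
    )
    return int(np.linalg.matrix_rank(quad))


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor with derived scalar maps.

    tensor: (x, y, z, 6) in the TENSOR_ELEMENTS order, mm^2/s;
    fa/md/s0: (x, y, z); valid: voxels with a usable fit.
    """

    tensor: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def full_tensor(self) -> np.ndarray:
        """Expand to (x, y, z, 3, 3) symmetric matrices."""
        t = self.tensor
        out = np.empty(t.shape[:3] + (3, 3))
        out[..., 0, 0] = t[..., 0]
        out[..., 1, 1] = t[..., 1]
        out[..., 2, 2] = t[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = t[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = t[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = t[..., 5]
        return out


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to ln S."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(acq: DiffusionAcquisition, *, weighted: bool = False) -> TensorField:
    """Log-linear least-squares tensor fit over the masked voxels.

    Voxels where some signal samples are non-positive are refit with those
    samples dropped; if fewer than 7 samples remain the voxel is invalid.
    ``weighted=True`` applies one round of signal-magnitude weighting
    (WLS with weights S^2), a common refinement of the plain fit.
    """
    shape = acq.signals.shape[:3]
    mask = np.ones(shape, bool) if acq.mask is None else np.asarray(acq.mask, bool)
    X = design_matrix(acq.bvals, acq.bvecs)

    sig = acq.signals[mask]  # (n_voxels, n_volumes)
    n_vox = sig.shape[0]
    coefs = np.full((n_vox, 7), np.nan)
    ok = np.all(sig > 0, axis=1)

    if np.any(ok):
        logs = np.log(sig[ok])
        sol, *_ = np.linalg.lstsq(X, logs.T, rcond=None)
        if weighted:
            # one reweighting pass: weights proportional to predicted signal
            pred = X @ sol  # (n_volumes, n_ok)
            w = np.exp(pred)
            sol_w = np.empty_like(sol)
            for j in range(sol.shape[1]):
                Xw = X * w[:, j : j + 1]
                sol_w[:, j], *_ = np.linalg.lstsq(Xw, w[:, j] * logs[j], rcond=None)
            sol = sol_w
        coefs[ok] = sol.T

    # salvage voxels with some non-positive samples
    bad_idx = np.flatnonzero(~ok)
    for i in bad_idx:
        keep = sig[i] > 0
        if keep.sum() < 7 or _n_independent_directions(acq.bvecs[keep & (acq.bvals > 0)]) < 6:
            continue
        if not np.any(acq.bvals[keep] == 0):
            continue
        c, *_ = np.linalg.lstsq(X[keep], np.log(sig[i, keep]), rcond=None)
        coefs[i] = c

    valid_flat = ~np.isnan(coefs[:, 0])
    tensor = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    valid = np.zeros(shape, bool)
    tensor[mask] = np.nan_to_num(coefs[:, 1:])
    s0[mask] = np.where(valid_flat, np.exp(np.nan_to_num(coefs[:, 0])), 0.0)
    vtmp = np.zeros(n_vox, bool)
    vtmp[:] = valid_flat
    valid[mask] = vtmp

    fa, md = _scalars_from_tensor(tensor, valid)
    return TensorField(tensor=tensor, fa=fa, md=md, s0=s0, valid=valid, affine=acq.affine)


def _scalars_from_tensor(tensor: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    shape = tensor.shape[:3]
    fa = np.full(shape, np.nan)
    md = np.full(shape, np.nan)
    if not np.any(valid):
        return fa, md
    t = tensor[valid]
    mats = np.empty((len(t), 3, 3))
    mats[:, 0, 0] = t[:, 0]
    mats[:, 1, 1] = t[:, 1]
    mats[:, 2, 2] = t[:, 2]
    mats[:, 0, 1] = mats[:, 1, 0] = t[:, 3]
    mats[:, 0, 2] = mats[:, 2, 0] = t[:, 4]
    mats[:, 1, 2] = mats[:, 2, 1] = t[:, 5]
    lam = np.linalg.eigvalsh(mats)
    lam = np.maximum(lam, EIG_FLOOR)
    fa[valid] = fa_from_eigenvalues(lam)
    md[valid] = lam.mean(axis=1)
    return fa, md


def fa_from_eigenvalues(lam: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam|| for eigenvalue triples."""
    lam = np.atleast_2d(lam)
    mean = lam.mean(axis=1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=1))
    den = np.sqrt((lam**2).sum(axis=1))
    out = np.sqrt(1.5) * np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return out if out.size > 1 else out[0]


def scalar_maps(tf: TensorField) -> tuple[np.ndarray, np.ndarray]:
    """Recompute (FA, MD) maps from the tensor field; invalid voxels are NaN."""
    return _scalars_from_tensor(tf.tensor, tf.valid)
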