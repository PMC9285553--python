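"""Diffusion tensor estimation and scalar metrics.

The tensor is fit voxel-wise by ordinary (log-)linear least squares, using
all image repetitions jointly without prior averaging: with the per-volume
b-matrix B = b * g g^T, the model is

    ln S_v = ln S0 - (Bxx Dxx + Byy Dyy + Bzz Dzz + 2 Bxy Dxy + 2 Bxz Dxz + 2 Byz Dyz)

solved per voxel over all volumes with positive signal.  Eigenvalues are
sorted descending; mean diffusivity is their average and fractional
anisotropy is the usual normalised eigenvalue-dispersion index

    FA = sqrt(1/2) * sqrt(((l1-l2)^2 + (l1-l3)^2 + (l2-l3)^2) / (l1^2 + l2^2 + l3^2)).

Eigenvalues are deliberately not clamped to be non-negative: under noise
small negative eigenvalues occur and MD/FA are computed from the raw values,
matching a direct-fit convention (so FA can exceed 1 for such voxels).
Non-positive signals cannot enter the log and are excluded per voxel; a
voxel with fewer than 7 usable measurements is marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import AcquisitionScheme, DWIStack

__all__ = [
    "BMatrix",
    "TensorField",
    "build_bmatrix",
    "design_matrix",
    "select_bvalues",
    "resolve_combo",
    "fit_tensor_lls",
    "tensor_metrics",
    "repetition_series",
]

MIN_MEASUREMENTS = 7  # intercept + six tensor components


@dataclass(frozen=True)
class BMatrix:
    """Per-volume symmetric b-matrices b * g g^T (s/mm^2)."""

    matrices: np.ndarray  # (N, 3, 3)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1:] != (3, 3):
            raise ValueError("b-matrices must be (N, 3, 3)")
        object.__setattr__(self, "matrices", m)

    def __len__(self) -> int:
        return self.matrices.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """(N, 6) rows (bxx, byy, bzz, bxy, bxz, byz)."""
        m = self.matrices
        return np.stack(
            [m[:, 0, 0], m[:, 1, 1], m[:, 2, 2], m[:, 0, 1], m[:, 0, 2], m[:, 1, 2]], axis=1
        )

    @property
    def trace(self) -> np.ndarray:
        return np.trace(self.matrices, axis1=1, axis2=2)


def build_bmatrix(scheme: AcquisitionScheme) -> BMatrix:
    """B = b * g g^T per volume (zero matrix for b = 0)."""
    g = scheme.directions
    outer = np.einsum("vi,vj->vij", g, g)
    return BMatrix(matrices=scheme.bvalues[:, None, None] * outer)


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """LLS design: columns [1, -bxx, -byy, -bzz, -2bxy, -2bxz, -2byz]."""
    flat = build_bmatrix(scheme).flat
    X = np.empty((len(scheme), 7))
    X[:, 0] = 1.0
    X[:, 1:4] = -flat[:, :3]
    X[:, 4:7] = -2.0 * flat[:, 3:]
    return X


def resolve_combo(combo: Sequence, scheme: AcquisitionScheme) -> tuple[float, ...]:
    """Map a b-value combination (which may contain the label ``"b_low"``)
    onto numeric b-values of the given scheme."""
    resolved = []
    for b in combo:
        resolved.append(scheme.b_low if isinstance(b, str) and b == "b_low" else float(b))
    return tuple(resolved)


def select_bvalues(stack: DWIStack, combo: Sequence) -> DWIStack:
    """Restrict a stack to the volumes whose b-value is in ``combo``.

    ``combo`` entries are b-values in s/mm^2; the string ``"b_low"`` stands
    for the scheme's low-b value and is matched exactly.  Subsets that leave
    fewer than 7 volumes per repetition cannot determine a tensor and raise.
    """
    scheme = stack.scheme
    resolved = resolve_combo(combo, scheme)
    missing = [b for b in resolved if not np.any(scheme.volumes_matching(b))]
    if missing:
        raise ValueError(f"b-values {missing} not present in the scheme")
    keep = np.zeros(len(scheme), dtype=bool)
    for b in resolved:
        keep |= scheme.volumes_matching(b)
    per_rep = keep.sum() / scheme.n_repetitions
    if per_rep < MIN_MEASUREMENTS:
        raise ValueError(
            f"combination {tuple(combo)} leaves {per_rep:.0f} volumes per repetition; "
            f"at least {MIN_MEASUREMENTS} are needed for a tensor fit"
        )
    return DWIStack(
        signal=stack.signal[..., keep],
        voxel_size=stack.voxel_size,
        scheme=scheme.subset(keep),
        meta=dict(stack.meta),
    )


def tensor_metrics(eigenvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean diffusivity and fractional anisotropy from eigenvalues.

    Works on any (..., 3) array.  All-zero eigenvalue triples have undefined
    FA and are flagged as NaN.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected eigenvalue triples on the last axis")
    md = lam.mean(axis=-1)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5 * num / den)
    fa = np.where(den == 0, np.nan, fa)
    return md, fa


@dataclass
class TensorField:
    """Voxel-wise tensor fit results on the stack's grid.

    ``tensor`` holds the symmetric 3x3 tensor (mm^2/s), ``eigenvalues`` the
    descending-sorted eigenvalues, and ``valid`` marks voxels where the fit
    was possible.  Invalid voxels carry NaN metrics.
    """

    tensor: np.ndarray  # (..., 3, 3)
    ln_s0: np.ndarray
    eigenvalues: np.ndarray  # (..., 3) descending
    md: np.ndarray
    fa: np.ndarray
    valid: np.ndarray

    def roi_values(self, mask: np.ndarray, metric: str) -> np.ndarray:
        """Metric values over the valid voxels of a mask."""
        arr = getattr(self, metric.lower())
        sel = mask & self.valid
        return arr[sel]

    def to_nifti(self, outdir, voxel_size: tuple[float, float, float]) -> dict:
        """Write md/fa/ln_s0/valid maps as NIfTI files; returns the paths."""
        from pathlib import Path

        from .io import write_scalar_nifti

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        return {
            name: write_scalar_nifti(getattr(self, name), voxel_size, outdir / f"{name}.nii.gz")
            for name in ("md", "fa", "ln_s0", "valid")
        }


def _fit_voxels(logS: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Solve OLS for many voxels sharing the design matrix. logS: (n_vox, N)."""
    beta, *_ = np.linalg.lstsq(X, logS.T, rcond=None)
    return beta.T  # (n_vox, 7)


def _beta_to_tensor(beta: np.ndarray) -> np.ndarray:
    """(n_vox, 7) coefficients -> (n_vox, 3, 3) symmetric tensors."""
    t = np.empty(beta.shape[:-1] + (3, 3))
    t[..., 0, 0] = beta[..., 1]
    t[..., 1, 1] = beta[..., 2]
    t[..., 2, 2] = beta[..., 3]
    t[..., 0, 1] = t[..., 1, 0] = beta[..., 4]
    t[..., 0, 2] = t[..., 2, 0] = beta[..., 5]
    t[..., 1, 2] = t[..., 2, 1] = beta[..., 6]
    return t


def fit_tensor_lls(stack: DWIStack, roi_mask: np.ndarray | None = None) -> TensorField:
    """Ordinary least-squares tensor fit per voxel.

    All repetitions enter the regression jointly (no prior averaging).
    Voxels outside ``roi_mask`` (when given), with fewer than 7 positive
    signals, or with a rank-deficient reduced design, are invalid.
    """
    grid = stack.grid_shape
    n_vol = stack.signal.shape[-1]
    if n_vol < MIN_MEASUREMENTS:
        raise ValueError(f"at least {MIN_MEASUREMENTS} volumes required")
    X = design_matrix(stack.scheme)

    if roi_mask is None:
        roi_mask = np.ones(grid, dtype=bool)
    flat_idx = np.flatnonzero(roi_mask.reshape(-1))
    sig = stack.signal.reshape(-1, n_vol)[flat_idx]

    tensor = np.full(grid + (3, 3), np.nan)
    ln_s0 = np.full(grid, np.nan)
    eigenvalues = np.full(grid + (3,), np.nan)
    valid = np.zeros(grid, dtype=bool)

    positive = sig > 0
    usable = positive.sum(axis=1) >= MIN_MEASUREMENTS
    all_pos = positive.all(axis=1)

    betas = np.full((sig.shape[0], 7), np.nan)
    full = np.flatnonzero(all_pos)
    if full.size:
        with np.errstate(divide="ignore"):
            betas[full] = _fit_voxels(np.log(sig[full]), X)
    partial = np.flatnonzero(usable & ~all_pos)
    for i in partial:
        rows = positive[i]
        Xi = X[rows]
        if np.linalg.matrix_rank(Xi) < MIN_MEASUREMENTS:
            continue
        b, *_ = np.linalg.lstsq(Xi, np.log(sig[i, rows]), rcond=None)
        betas[i] = b
    ok = np.all(np.isfinite(betas), axis=1)
    if not ok.any():
        raise ValueError("no voxel in the ROI could be fitted")

    tensors = _beta_to_tensor(betas[ok])
    lam = np.linalg.eigvalsh(tensors)[..., ::-1]  # descending

    grid_idx = flat_idx[ok]
    ijk = np.unravel_index(grid_idx, grid)
    tensor[ijk] = tensors
    ln_s0[ijk] = betas[ok, 0]
    eigenvalues[ijk] = lam
    valid[ijk] = True
    md, fa = tensor_metrics(eigenvalues)
    md[~valid] = np.nan
    fa[~valid] = np.nan
    return TensorField(tensor=tensor, ln_s0=ln_s0, eigenvalues=eigenvalues, md=md, fa=fa, valid=valid)


def repetition_series(
    stack: DWIStack, combo: Sequence, roi_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """ROI-mean (MD, FA) per single repetition, in acquisition order.

    The tensor is refit independently on each repetition of the selected
    b-value combination -- the time course behind drift and stability
    metrics.
    """
    sub = select_bvalues(stack, combo)
    if sub.scheme.repetition_index is None:
        raise ValueError("scheme has no repetition structure")
    mds, fas = [], []
    for rep_mask in sub.scheme.repetition_masks():
        rep_stack = DWIStack(
            signal=sub.signal[..., rep_mask],
            voxel_size=sub.voxel_size,
            scheme=sub.scheme.subset(rep_mask),
            meta=dict(sub.meta),
        )
        field = fit_tensor_lls(rep_stack, roi_mask=roi_mask)
        mds.append(float(np.nanmean(field.md[roi_mask & field.valid])))
        fas.append(float(np.nanmean(field.fa[roi_mask & field.valid])))
    return np.asarray(mds), np.asarray(fas)
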