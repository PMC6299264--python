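"""Diffusion-tensor fitting on a single shell and the derived scalar maps.

The tensor is fitted to the lower shell only (b = 750 s/mm^2 in the study
acquisition): at high b-values the Gaussian (tensor) signal model no longer
holds in tissue, so the high shell is excluded by contract, not by option.
The estimator is signal-squared-weighted linear least squares on the
log-signal, the standard fast estimator for single-shell data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import GradientScheme

__all__ = ["TensorFit", "DtiScalars", "fit_tensor", "tensor_scalars", "fit_dti_map"]


@dataclass(frozen=True)
class TensorFit:
    """A fitted diffusion tensor with its eigendecomposition.

    ``evals`` are sorted descending; ``evecs[:, i]`` is the eigenvector of
    ``evals[i]``.  ``flagged`` marks voxels where the signal had to be clamped
    before the log-domain fit or where negative eigenvalues appeared.
    """

    D: np.ndarray          # symmetric 3x3, mm^2/s
    s0: float              # baseline signal, arbitrary units
    evals: np.ndarray      # (3,), descending
    evecs: np.ndarray      # (3, 3), orthonormal columns
    flagged: bool = False

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if np.abs(D - D.T).max() > 1e-12:
            raise ValueError("tensor must be symmetric")
        ev = np.asarray(self.evals, dtype=float)
        if np.any(np.diff(ev) > 0):
            raise ValueError("eigenvalues must be sorted descending")
        V = np.asarray(self.evecs, dtype=float)
        if np.abs(V.T @ V - np.eye(3)).max() > 1e-8:
            raise ValueError("eigenvectors must be orthonormal")
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "evals", ev)
        object.__setattr__(self, "evecs", V)


@dataclass(frozen=True)
class DtiScalars:
    """Rotation-invariant tensor summaries (all diffusivities in mm^2/s)."""

    fa: float
    md: float
    ad: float
    rd: float


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map (log s0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to log-signal."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return np.column_stack([
        np.ones_like(bvals),
        -bvals * gx * gx,
        -bvals * gy * gy,
        -bvals * gz * gz,
        -2.0 * bvals * gx * gy,
        -2.0 * bvals * gx * gz,
        -2.0 * bvals * gy * gz,
    ])


def fit_tensor(signal: np.ndarray, scheme: GradientScheme, shell: float = 750.0) -> TensorFit:
    """Weighted linear least-squares tensor fit on one shell.

    Uses only the diffusion-weighted volumes of the selected shell plus that
    shell's b0 volumes (averaged into a single baseline observation before
    fitting).  Weights are the squared model-free signals, the usual
    first-order correction for log-transforming Rician-corrupted data.

    Non-positive signal values are clamped to 1e-3 times the smallest positive
    signal in the voxel (the log fit requires positivity) and the fit is
    flagged for QC.  Returns an all-NaN flagged fit if no positive signal
    exists.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] != scheme.n_volumes:
        raise ValueError("signal length does not match scheme")
    sid = scheme.shell_for_bval(shell)
    dw = scheme.dw_mask(sid)
    b0 = scheme.b0_mask(sid)
    if dw.sum() < 6 or b0.sum() < 1:
        raise ValueError(
            f"shell {shell}: need >= 6 directions and >= 1 b0, "
            f"got {int(dw.sum())} and {int(b0.sum())}"
        )
    s_dw = signal[dw]
    s_b0 = float(signal[b0].mean())
    s = np.concatenate([[s_b0], s_dw])
    flagged = False
    if np.any(s <= 0):
        pos = s[s > 0]
        if pos.size == 0:
            nan3 = np.full(3, np.nan)
            return TensorFit(np.full((3, 3), np.nan), np.nan, nan3, np.eye(3), flagged=True)
        s = np.where(s <= 0, pos.min() * 1e-3, s)
        flagged = True
    bvals = np.concatenate([[0.0], scheme.bvals[dw]])
    bvecs = np.vstack([[0.0, 0.0, 1.0], scheme.bvecs[dw]])
    X = _design_matrix(bvals, bvecs)
    w = s  # sqrt of the signal^2 weights
    beta, *_ = np.linalg.lstsq(X * w[:, None], np.log(s) * w, rcond=None)
    D = np.array([
        [beta[1], beta[4], beta[5]],
        [beta[4], beta[2], beta[6]],
        [beta[5], beta[6], beta[3]],
    ])
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.any(evals < 0):
        flagged = True
    return TensorFit(D, float(np.exp(beta[0])), evals, evecs, flagged=flagged)


def tensor_scalars(fit: TensorFit) -> DtiScalars:
    """FA, MD, AD and RD from the tensor eigenvalues.

    MD keeps the raw (possibly negative) eigenvalues so it stays unbiased;
    FA's normalisation clamps negatives at zero so FA remains in [0, 1].
    An all-zero tensor has FA defined as 0.
    """
    lam = np.asarray(fit.evals, dtype=float)
    md = float(lam.mean())
    ad = float(lam[0])
    rd = float(0.5 * (lam[1] + lam[2]))
    lam_fa = np.clip(lam, 0.0, None)
    norm = np.linalg.norm(lam_fa)
    if norm == 0:
        fa = 0.0
    else:
        fa = float(np.sqrt(1.5) * np.linalg.norm(lam_fa - lam_fa.mean()) / norm)
        fa = min(fa, 1.0)
    return DtiScalars(fa=fa, md=md, ad=ad, rd=rd)


def fit_dti_map(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    shell: float = 750.0,
) -> dict[str, np.ndarray]:
    """Voxelwise tensor scalars over a 4D volume.

    Returns FA/MD/AD/RD maps plus the principal eigenvector map ("E1") and a
    boolean QC flag map; voxels outside the mask hold NaN.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[-1] != scheme.n_volumes:
        raise ValueError("dwi must be 4D with one volume per scheme entry")
    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != shape:
        raise ValueError("mask shape mismatch")
    maps = {k: np.full(shape, np.nan) for k in ("FA", "MD", "AD", "RD")}
    maps["E1"] = np.full(shape + (3,), np.nan)
    maps["FLAG"] = np.zeros(shape, dtype=bool)
    for idx in zip(*np.nonzero(mask)):
        fit = fit_tensor(dwi[idx], scheme, shell=shell)
        if np.isnan(fit.evals).any():
            maps["FLAG"][idx] = True
            continue
        sc = tensor_scalars(fit)
        maps["FA"][idx] = sc.fa
        maps["MD"][idx] = sc.md
        maps["AD"][idx] = sc.ad
        maps["RD"][idx] = sc.rd
        maps["E1"][idx] = fit.evecs[:, 0]
        maps["FLAG"][idx] = fit.flagged
    return maps
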