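"""Multi-shell acquisition geometry.

A :class:`GradientScheme` holds, per acquired volume, the b-value, the unit
gradient direction, a shell label and a b0 flag.  The b0 volumes carry the
shell label of the shell they were acquired with, which matters here because
the two shells are acquired with different echo times and must be normalised
by their own b0 baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradientScheme", "make_scheme", "electrostatic_directions"]

_B0_THRESHOLD = 50.0  # s/mm^2; below this a volume counts as non-diffusion-weighted


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume acquisition geometry of a multi-shell dMRI series.

    Parameters
    ----------
    bvals : (n,) array
        b-value of each volume in s/mm^2 (0 for b0 volumes).
    bvecs : (n, 3) array
        Unit direction cosines; arbitrary for b0 volumes.
    shell_id : (n,) int array
        Shell label of each volume; b0s carry the label of their shell.
    is_b0 : (n,) bool array
        True for non-diffusion-weighted volumes.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_id: np.ndarray
    is_b0: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        shell_id = np.asarray(self.shell_id, dtype=int)
        is_b0 = np.asarray(self.is_b0, dtype=bool)
        n = bvals.shape[0]
        if bvecs.shape != (n, 3) or shell_id.shape != (n,) or is_b0.shape != (n,):
            raise ValueError("inconsistent scheme array shapes")
        if np.any(bvals[is_b0] != 0):
            raise ValueError("b0 volumes must have b-value 0")
        norms = np.linalg.norm(bvecs[~is_b0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-b0 direction vectors must be unit norm")
        for s in np.unique(shell_id):
            dw = (~is_b0) & (shell_id == s)
            if not np.any(dw):
                raise ValueError(f"shell {s} has no diffusion-weighted volumes")
            if np.unique(bvals[dw]).size != 1:
                raise ValueError(f"shell {s} maps to more than one nominal b-value")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "shell_id", shell_id)
        object.__setattr__(self, "is_b0", is_b0)

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.shell_id)

    def nominal_bval(self, shell: int) -> float:
        dw = (~self.is_b0) & (self.shell_id == shell)
        return float(self.bvals[dw][0])

    def shell_for_bval(self, bval: float, tol: float = 1.0) -> int:
        for s in self.shells:
            if abs(self.nominal_bval(int(s)) - bval) <= tol:
                return int(s)
        raise ValueError(f"no shell with nominal b-value {bval}")

    def dw_mask(self, shell: int | None = None) -> np.ndarray:
        m = ~self.is_b0
        if shell is not None:
            m = m & (self.shell_id == shell)
        return m

    def b0_mask(self, shell: int | None = None) -> np.ndarray:
        m = self.is_b0.copy()
        if shell is not None:
            m = m & (self.shell_id == shell)
        return m

    def subset(self, keep: np.ndarray) -> "GradientScheme":
        """Scheme restricted to the volumes selected by boolean mask ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        return GradientScheme(
            self.bvals[keep], self.bvecs[keep], self.shell_id[keep], self.is_b0[keep]
        )

    def _key(self) -> tuple:
        return (
            self.bvals.tobytes(),
            self.bvecs.tobytes(),
            self.shell_id.tobytes(),
            self.is_b0.tobytes(),
        )


def electrostatic_directions(n: int, seed: int = 0, n_iter: int = 300) -> np.ndarray:
    """Approximately uniform antipodally-symmetric unit directions.

    Minimises the Coulomb energy of ``n`` point charges and their antipodes on
    the unit sphere by projected gradient descent from a seeded random start.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x
    step = 0.05
    for _ in range(n_iter):
        # pairwise forces from both charge images (antipodal symmetry)
        diff = x[:, None, :] - x[None, :, :]
        dsum = x[:, None, :] + x[None, :, :]
        r1 = np.linalg.norm(diff, axis=-1)
        r2 = np.linalg.norm(dsum, axis=-1)
        np.fill_diagonal(r1, np.inf)
        np.fill_diagonal(r2, np.inf)
        force = (diff / r1[..., None] ** 3).sum(axis=1) + (dsum / r2[..., None] ** 3).sum(axis=1)
        # tangential projection keeps the update on the sphere
        force -= (force * x).sum(axis=1, keepdims=True) * x
        fmax = np.linalg.norm(force, axis=1).max()
        if fmax > 0:
            x = x + step * force / fmax
            x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def make_scheme(
    n_low: int,
    n_high: int,
    n_b0_low: int,
    n_b0_high: int,
    seed: int = 0,
    b_low: float = 750.0,
    b_high: float = 2500.0,
) -> GradientScheme:
    """Two-shell acquisition scheme with repulsion-optimised directions.

    Volumes are ordered: low-shell b0s, low-shell directions, high-shell b0s,
    high-shell directions.  Shell 0 is the lower b-value, shell 1 the higher.
    """
    for name, v in (("n_low", n_low), ("n_high", n_high),
                    ("n_b0_low", n_b0_low), ("n_b0_high", n_b0_high)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    dirs_low = electrostatic_directions(n_low, seed=seed)
    dirs_high = electrostatic_directions(n_high, seed=seed + 1)
    bvals = np.concatenate([
        np.zeros(n_b0_low), np.full(n_low, b_low),
        np.zeros(n_b0_high), np.full(n_high, b_high),
    ])
    zlow = np.tile([[0.0, 0.0, 1.0]], (n_b0_low, 1))
    zhigh = np.tile([[0.0, 0.0, 1.0]], (n_b0_high, 1))
    bvecs = np.vstack([zlow, dirs_low, zhigh, dirs_high])
    shell_id = np.concatenate([
        np.zeros(n_b0_low + n_low, dtype=int),
        np.ones(n_b0_high + n_high, dtype=int),
    ])
    is_b0 = bvals == 0
    return GradientScheme(bvals, bvecs, shell_id, is_b0)


def scheme_from_bvals_bvecs(bvals: np.ndarray, bvecs: np.ndarray) -> GradientScheme:
    """Build a scheme from FSL-convention b-value/direction tables.

    Shells are inferred by grouping nominal b-values; each b0 is assigned the
    shell of the next diffusion-weighted volume in acquisition order (b0s
    lead their shell's block), falling back to the preceding one for
    trailing b0s.
    """
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape == (3, bvals.size):
        bvecs = bvecs.T
    is_b0 = bvals < _B0_THRESHOLD
    bvals = np.where(is_b0, 0.0, bvals)
    nominal = np.unique(bvals[~is_b0])
    shell_of_b = {b: i for i, b in enumerate(np.sort(nominal))}
    shell_id = np.zeros(bvals.size, dtype=int)
    dw_idx = np.flatnonzero(~is_b0)
    for i in range(bvals.size):
        if is_b0[i]:
            after = dw_idx[dw_idx > i]
            ref = after[0] if after.size else dw_idx[dw_idx < i][-1]
            shell_id[i] = shell_of_b[bvals[ref]]
        else:
            shell_id[i] = shell_of_b[bvals[i]]
    norms = np.linalg.norm(bvecs, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    bvecs = bvecs / safe[:, None]
    return GradientScheme(bvals, bvecs, shell_id, is_b0)
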