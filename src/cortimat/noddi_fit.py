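"""Per-voxel inversion of the three-compartment model, with the adaptations
used for neonatal data.

Two acquisition shells with different echo times cannot share a common
baseline, so each shell is first normalised by the mean of its own b0
volumes.  Initialisation is a restricted grid search — the intra-neurite
fraction start range is lowered to [0, 0.3], appropriate for the premyelinated
cortex, while the optimiser itself keeps the full [0, 1] bound — followed by
bounded nonlinear least squares.  Voxels whose first-pass fit does not
converge are re-initialised from a linearised dictionary decomposition
(non-negative least squares on a small atom set, orientation taken from the
tensor's principal eigenvector) and refitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .dti import fit_tensor
from .noddi_model import (
    ModelConstants,
    NoddiParams,
    a_extra,
    a_intra,
    forward_signal,
    kappa_from_odi,
    odi_from_kappa,
)
from .scheme import GradientScheme, electrostatic_directions

__all__ = [
    "NoddiFitResult",
    "ExclusionList",
    "GridSpec",
    "DictionarySpec",
    "normalise_shells",
    "apply_exclusions",
    "grid_init",
    "refine_fit",
    "dictionary_init",
    "fit_volume",
]

_KAPPA_MAX = 128.0
_LOGK_MAX = float(np.log1p(_KAPPA_MAX))


@dataclass(frozen=True)
class NoddiFitResult:
    params: NoddiParams
    objective: float                 # residual sum of squares, normalised-signal scale
    converged: bool
    init_source: str                 # "grid" or "dictionary"
    n_volumes_used: int
    degenerate: bool = False         # fiso ~ 1: vin/kappa unidentifiable

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be >= 0")
        if self.init_source not in ("grid", "dictionary"):
            raise ValueError("init_source must be 'grid' or 'dictionary'")


@dataclass(frozen=True)
class ExclusionList:
    """Volume indices to drop (e.g., motion-corrupted directions)."""

    indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(sorted(set(int(i) for i in self.indices))))


def normalise_shells(signal: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """Divide each volume by the mean b0 of its own shell.

    This removes the per-shell baseline (TR/TE) mismatch: b0 entries become 1
    and the result is invariant to any global positive rescaling of the raw
    signal.  Raises if a shell's mean b0 is not strictly positive.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] != scheme.n_volumes:
        raise ValueError("signal length does not match scheme")
    out = np.empty_like(signal)
    for s in scheme.shells:
        b0 = scheme.b0_mask(int(s))
        if not b0.any():
            raise ValueError(f"shell {s} has no b0 volume")
        baseline = signal[b0].mean()
        if baseline <= 0:
            raise ValueError(f"shell {s} mean b0 is non-positive; voxel cannot be fitted")
        sel = scheme.shell_id == s
        out[sel] = signal[sel] / baseline
    return out


def apply_exclusions(
    signal: np.ndarray, scheme: GradientScheme, exclusions: ExclusionList
) -> tuple[np.ndarray, GradientScheme]:
    """Drop excluded volumes consistently from signal and scheme.

    Refuses to drop a shell below 6 diffusion directions or below its last
    b0 volume.
    """
    signal = np.asarray(signal, dtype=float)
    n = scheme.n_volumes
    idx = np.asarray(exclusions.indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("exclusion index out of range")
    keep = np.ones(n, dtype=bool)
    keep[idx] = False
    sub = scheme.subset(keep)
    for s in scheme.shells:
        n_dw = int(sub.dw_mask(int(s)).sum())
        n_b0 = int(sub.b0_mask(int(s)).sum())
        if n_dw < 6:
            raise ValueError(f"exclusions leave shell {s} with {n_dw} < 6 directions")
        if n_b0 < 1:
            raise ValueError(f"exclusions leave shell {s} with no b0 volume")
    return signal[..., keep], sub


@dataclass(frozen=True)
class GridSpec:
    """Cartesian grid for initialisation.

    vin spans only [0, 0.3] — the restricted start range for the unmyelinated
    cortex — while the subsequent optimisation keeps the full [0, 1] bound.
    """

    vin: tuple[float, ...] = tuple(np.linspace(0.0, 0.3, 13))
    kappa: tuple[float, ...] = tuple(np.expm1(np.linspace(0.0, np.log1p(64.0), 8)))
    fiso: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 11))
    n_mu: int = 30


@dataclass(frozen=True)
class DictionarySpec:
    """Linearised-decomposition dictionary: (vin x kappa) tissue atoms plus
    one isotropic free-water atom, solved by L2-regularised NNLS."""

    n_vin: int = 12
    n_kappa: int = 12
    reg: float = 1e-3

    def vin_values(self) -> np.ndarray:
        return np.linspace(0.02, 0.95, self.n_vin)

    def kappa_values(self) -> np.ndarray:
        return np.expm1(np.linspace(np.log1p(0.25), np.log1p(64.0), self.n_kappa))


_grid_cache: dict[tuple, tuple] = {}


def _grid_atoms(scheme: GradientScheme, constants: ModelConstants, spec: GridSpec):
    """Precomputed model signals on the full (vin, fiso, kappa, mu) grid.

    Returns (atoms (n_grid, n_vol), params list aligned with rows).  Row
    order is C-order over (vin, fiso, kappa, mu), so ``argmin`` tie-breaking
    selects the lexicographically smallest (vin, fiso, kappa) tuple.
    """
    key = (scheme._key(), constants.d_par, constants.d_iso,
           spec.vin, spec.kappa, spec.fiso, spec.n_mu)
    if key in _grid_cache:
        return _grid_cache[key]
    mus = electrostatic_directions(spec.n_mu, seed=42)
    b, g = scheme.bvals, scheme.bvecs
    aiso = np.exp(-b * constants.d_iso)
    n_vol = scheme.n_volumes
    shape = (len(spec.vin), len(spec.fiso), len(spec.kappa), spec.n_mu)
    atoms = np.empty(shape + (n_vol,))
    for k_i, kap in enumerate(spec.kappa):
        for m_i in range(spec.n_mu):
            mu = mus[m_i]
            ain = a_intra(b, g, mu, kap, constants)
            for v_i, vin in enumerate(spec.vin):
                aen = a_extra(b, g, mu, kap, vin, constants)
                tissue = vin * ain + (1.0 - vin) * aen
                for f_i, fiso in enumerate(spec.fiso):
                    atoms[v_i, f_i, k_i, m_i] = (1.0 - fiso) * tissue + fiso * aiso
    flat = atoms.reshape(-1, n_vol)
    params = []
    for v_i, vin in enumerate(spec.vin):
        for f_i, fiso in enumerate(spec.fiso):
            for k_i, kap in enumerate(spec.kappa):
                for m_i in range(spec.n_mu):
                    params.append((vin, fiso, kap, m_i))
    result = (flat, params, mus, np.einsum("ij,ij->i", flat, flat))
    _grid_cache[key] = result
    return result


def grid_init(
    norm_signal: np.ndarray,
    scheme: GradientScheme,
    constants: ModelConstants = ModelConstants(),
    grid_spec: GridSpec = GridSpec(),
) -> NoddiParams:
    """Exhaustive search over the initialisation grid; returns the
    minimum-RSS grid point (ties broken toward lower (vin, fiso, kappa))."""
    norm_signal = np.asarray(norm_signal, dtype=float)
    atoms, params, mus, atom_sq = _grid_atoms(scheme, constants, grid_spec)
    # RSS = ||a||^2 - 2 a.s + ||s||^2; the ||s||^2 term is common
    score = atom_sq - 2.0 * atoms @ norm_signal
    best = int(np.argmin(score))
    vin, fiso, kap, m_i = params[best]
    return NoddiParams(vin=vin, kappa=kap, fiso=fiso, mu=mus[m_i])


def _rss(params: NoddiParams, norm_signal, scheme, constants) -> float:
    r = forward_signal(params, scheme, constants) - norm_signal
    return float(r @ r)


def _angles_from_mu(mu: np.ndarray) -> tuple[float, float]:
    theta = float(np.arccos(np.clip(mu[2], -1.0, 1.0)))
    phi = float(np.arctan2(mu[1], mu[0]))
    return theta, phi


def _mu_from_angles(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def refine_fit(
    norm_signal: np.ndarray,
    scheme: GradientScheme,
    init: NoddiParams,
    constants: ModelConstants = ModelConstants(),
    init_source: str = "grid",
    fit_mu: bool = True,
) -> NoddiFitResult:
    """Bounded nonlinear least squares from an initial parameter set.

    Optimises (vin, log(1+kappa), fiso, orientation angles); the log1p
    parameterisation of kappa avoids the boundary pathology at kappa = 0.
    Convergence requires the optimiser's success flag, a final RSS no more
    than twice the initialisation RSS, and no parameter pinned at a bound
    with a non-vanishing outward gradient.  On optimiser failure the
    initialisation is returned with ``converged=False``.
    """
    norm_signal = np.asarray(norm_signal, dtype=float)
    init_rss = _rss(init, norm_signal, scheme, constants)
    theta0, phi0 = _angles_from_mu(init.mu)

    def unpack(x):
        vin, lk, fiso = x[0], x[1], x[2]
        mu = _mu_from_angles(x[3], x[4]) if fit_mu else init.mu
        return NoddiParams(vin=vin, kappa=float(np.expm1(lk)), fiso=fiso, mu=mu)

    def resid(x):
        return forward_signal(unpack(x), scheme, constants) - norm_signal

    x0 = [init.vin, np.log1p(init.kappa), init.fiso]
    lo = [0.0, 0.0, 0.0]
    hi = [1.0, _LOGK_MAX, 1.0]
    if fit_mu:
        x0 += [theta0, phi0]
        lo += [-np.inf, -np.inf]
        hi += [np.inf, np.inf]
    x0 = np.clip(x0, lo, hi)
    try:
        res = least_squares(
            resid, x0, bounds=(lo, hi), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
        )
    except Exception:
        return NoddiFitResult(
            params=init, objective=init_rss, converged=False,
            init_source=init_source, n_volumes_used=scheme.n_volumes,
        )
    params = unpack(res.x)
    rss = float(2.0 * res.cost)
    pinned = False
    for i in range(3):
        at_lo = res.x[i] - lo[i] < 1e-10
        at_hi = hi[i] - res.x[i] < 1e-10
        if (at_lo and res.grad[i] > 1e-4) or (at_hi and res.grad[i] < -1e-4):
            pinned = True
    converged = bool(res.success) and rss <= 2.0 * init_rss + 1e-12 and not pinned
    if rss > init_rss:  # objective must never increase from the init
        params, rss = init, init_rss
        converged = False
    return NoddiFitResult(
        params=params, objective=rss, converged=converged,
        init_source=init_source, n_volumes_used=scheme.n_volumes,
        degenerate=params.fiso >= 0.99,
    )


_dict_cache: dict[tuple, tuple] = {}


def _dictionary_atoms(scheme, constants, spec, mu):
    key = (scheme._key(), constants.d_par, constants.d_iso,
           spec.n_vin, spec.n_kappa, tuple(np.round(mu, 12)))
    if key in _dict_cache:
        return _dict_cache[key]
    b, g = scheme.bvals, scheme.bvecs
    vins = spec.vin_values()
    kappas = spec.kappa_values()
    cols = []
    pars = []
    for kap in kappas:
        ain = a_intra(b, g, mu, kap, constants)
        for vin in vins:
            aen = a_extra(b, g, mu, kap, vin, constants)
            cols.append(vin * ain + (1.0 - vin) * aen)
            pars.append((vin, kap))
    cols.append(np.exp(-b * constants.d_iso))
    A = np.column_stack(cols)
    out = (A, pars)
    _dict_cache[key] = out
    return out


def dictionary_init(
    norm_signal: np.ndarray,
    scheme: GradientScheme,
    constants: ModelConstants = ModelConstants(),
    dict_spec: DictionarySpec = DictionarySpec(),
    mu: np.ndarray | None = None,
) -> NoddiParams:
    """Linearised initialisation: NNLS decomposition onto a small dictionary.

    The orientation is fixed from the lower-shell tensor's principal
    eigenvector (or given explicitly); the normalised signal is decomposed by
    non-negative least squares, with a small L2 ridge, onto tissue atoms
    spanning (vin, kappa) plus one isotropic atom.  Returned parameters are
    the weight-averaged atom parameters (dispersion averaged on the ODI
    scale, where atoms are evenly comparable).
    """
    norm_signal = np.asarray(norm_signal, dtype=float)
    if mu is None:
        tensor = fit_tensor(norm_signal, scheme, shell=scheme.nominal_bval(0))
        mu = tensor.evecs[:, 0]
        if np.isnan(mu).any():
            mu = np.array([0.0, 0.0, 1.0])
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    A, pars = _dictionary_atoms(scheme, constants, dict_spec, mu)
    n_atom = A.shape[1]
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("degenerate dictionary atom matrix")
    A_aug = np.vstack([A, np.sqrt(dict_spec.reg) * np.eye(n_atom)])
    y_aug = np.concatenate([norm_signal, np.zeros(n_atom)])
    w, _ = nnls(A_aug, y_aug)
    w_iso = w[-1]
    w_tis = w[:-1]
    total = w_iso + w_tis.sum()
    if total <= 0:
        return NoddiParams(vin=0.15, kappa=1.0, fiso=0.5, mu=mu)
    fiso = float(np.clip(w_iso / total, 0.0, 1.0))
    if w_tis.sum() <= 0:
        return NoddiParams(vin=0.15, kappa=1.0, fiso=fiso, mu=mu)
    wn = w_tis / w_tis.sum()
    vin = float(np.clip(sum(wi * p[0] for wi, p in zip(wn, pars)), 0.0, 1.0))
    odi = float(np.clip(sum(wi * odi_from_kappa(p[1]) for wi, p in zip(wn, pars)), 1e-6, 1.0))
    return NoddiParams(vin=vin, kappa=kappa_from_odi(odi), fiso=fiso, mu=mu)


def fit_voxel(
    signal: np.ndarray,
    scheme: GradientScheme,
    constants: ModelConstants = ModelConstants(),
    grid_spec: GridSpec = GridSpec(),
    dict_spec: DictionarySpec = DictionarySpec(),
    fit_mu: bool = True,
) -> NoddiFitResult:
    """Full single-voxel pipeline: normalise, grid-init, refine, fall back
    to the dictionary initialisation if the first pass does not converge."""
    norm = normalise_shells(signal, scheme)
    init = grid_init(norm, scheme, constants, grid_spec)
    result = refine_fit(norm, scheme, init, constants, init_source="grid", fit_mu=fit_mu)
    if fit_mu and (not result.converged or result.params.kappa <= 1e-8):
        # A kappa pinned at 0 is often a local minimum reached from a poorly
        # oriented start: in weakly anisotropic voxels the grid orientation is
        # underdetermined.  The tensor's principal eigenvector is axially
        # aligned with the true mean orientation, so restart from it.
        try:
            tensor = fit_tensor(norm, scheme, shell=scheme.nominal_bval(0))
            mu_dti = tensor.evecs[:, 0]
            if not np.isnan(mu_dti).any():
                restart = NoddiParams(
                    vin=result.params.vin,
                    kappa=max(result.params.kappa, 1.0),
                    fiso=result.params.fiso,
                    mu=mu_dti / np.linalg.norm(mu_dti),
                )
                second = refine_fit(
                    norm, scheme, restart, constants, init_source="grid", fit_mu=fit_mu
                )
                if second.objective < result.objective:
                    result = second
        except ValueError:
            pass
    if not result.converged:
        try:
            init2 = dictionary_init(norm, scheme, constants, dict_spec)
            second = refine_fit(
                norm, scheme, init2, constants, init_source="dictionary", fit_mu=fit_mu
            )
            if second.objective <= result.objective or second.converged:
                result = second
        except ValueError:
            pass
    return result


def fit_volume(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    exclusions: ExclusionList = ExclusionList(),
    constants: ModelConstants = ModelConstants(),
    grid_spec: GridSpec = GridSpec(),
    dict_spec: DictionarySpec = DictionarySpec(),
    fit_mu: bool = True,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Voxelwise model fit over a masked 4D volume.

    Returns (maps, qc): maps of NDI, ODI, FISO, OBJ (residual sum of
    squares), CONVERGED and INIT_SOURCE (0 grid, 1 dictionary); voxels
    outside the mask hold NaN (-1 for INIT_SOURCE).  Per-voxel failures are
    recorded in the QC table and never abort the volume.
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
    maps = {k: np.full(shape, np.nan) for k in ("NDI", "ODI", "FISO", "OBJ")}
    maps["CONVERGED"] = np.zeros(shape, dtype=bool)
    maps["INIT_SOURCE"] = np.full(shape, -1, dtype=int)
    qc_rows = []
    for idx in zip(*np.nonzero(mask)):
        voxel = dwi[idx]
        try:
            sig, sch = apply_exclusions(voxel, scheme, exclusions)
            result = fit_voxel(sig, sch, constants, grid_spec, dict_spec, fit_mu=fit_mu)
        except ValueError as err:
            qc_rows.append({"i": idx[0], "j": idx[1], "k": idx[2],
                            "status": "failed", "detail": str(err)})
            continue
        maps["NDI"][idx] = result.params.vin
        maps["ODI"][idx] = result.params.odi
        maps["FISO"][idx] = result.params.fiso
        maps["OBJ"][idx] = result.objective
        maps["CONVERGED"][idx] = result.converged
        maps["INIT_SOURCE"][idx] = 0 if result.init_source == "grid" else 1
        qc_rows.append({
            "i": idx[0], "j": idx[1], "k": idx[2],
            "status": "converged" if result.converged else "not_converged",
            "detail": result.init_source,
        })
    qc = pd.DataFrame(qc_rows, columns=["i", "j", "k", "status", "detail"])
    return maps, qc
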