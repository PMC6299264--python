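"""Three-compartment tissue model for diffusion in cortical grey matter.

The normalised diffusion signal in a voxel is modelled as

    A = (1 - f_iso) * (v_in * A_in + (1 - v_in) * A_en) + f_iso * A_iso

where ``A_in`` is the signal of a Watson-dispersed population of zero-radius
"sticks" (intra-neurite space), ``A_en`` an axially symmetric Gaussian
tensor whose perpendicular diffusivity follows the tortuosity rule
``d_perp = d_par * (1 - v_in)`` (extra-neurite space), and
``A_iso = exp(-b * d_iso)`` free (CSF-like) water.  Orientation dispersion is
summarised by ODI = (2/pi) * arctan(1/kappa), mapping the Watson
concentration kappa to [0, 1] (0 = perfectly parallel, 1 = isotropic).

Compartment diffusivities are fixed, not fitted.  The defaults are the
standard adult values (d_par = 1.7e-3 mm^2/s, d_iso = 3.0e-3 mm^2/s); they
are configurable because no reference values exist for the neonatal cortex
and the fixed-diffusivity assumption may bias estimates at this age.

All Watson orientation averages are evaluated exactly: the sphere integral of
``exp(n^T B n)`` for a symmetric 3x3 ``B`` reduces, in the eigenbasis of
``B``, to a 1-D integral with a modified-Bessel azimuthal factor, computed
with fixed-order Gauss-Legendre quadrature in a numerically shifted
(overflow-free) form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, hyp1f1, i0e, roots_legendre

from .scheme import GradientScheme

__all__ = [
    "ModelConstants",
    "NoddiParams",
    "odi_from_kappa",
    "kappa_from_odi",
    "watson_density",
    "a_intra",
    "a_extra",
    "forward_signal",
]

_GL_ORDER = 128
_GL_NODES, _GL_WEIGHTS = roots_legendre(_GL_ORDER)


@dataclass(frozen=True)
class ModelConstants:
    """Fixed compartment diffusivities, in mm^2/s."""

    d_par: float = 1.7e-3
    d_iso: float = 3.0e-3

    def __post_init__(self) -> None:
        if self.d_par <= 0 or self.d_iso <= 0:
            raise ValueError("diffusivities must be strictly positive")
        if self.d_iso <= self.d_par:
            raise ValueError("free-water diffusivity must exceed d_par")


@dataclass(frozen=True)
class NoddiParams:
    """Per-voxel tissue parameters.

    ``vin`` is the intra-neurite volume fraction within the non-free-water
    tissue (the neurite density index, NDI), ``kappa`` the Watson
    concentration, ``fiso`` the free-water fraction, ``mu`` the mean neurite
    orientation (unit 3-vector).
    """

    vin: float
    kappa: float
    fiso: float
    mu: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.vin <= 1.0:
            raise ValueError(f"vin must lie in [0, 1], got {self.vin}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if not 0.0 <= self.fiso <= 1.0:
            raise ValueError(f"fiso must lie in [0, 1], got {self.fiso}")
        mu = np.asarray(self.mu, dtype=float)
        if mu.shape != (3,) or abs(np.linalg.norm(mu) - 1.0) > 1e-6:
            raise ValueError("mu must be a unit 3-vector")
        object.__setattr__(self, "mu", mu)

    @property
    def odi(self) -> float:
        return odi_from_kappa(self.kappa)


def odi_from_kappa(kappa):
    """Orientation dispersion index, (2/pi) * arctan(1/kappa); ODI(0) = 1."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    with np.errstate(divide="ignore"):
        out = (2.0 / np.pi) * np.arctan2(1.0, kappa)
    return out if out.ndim else float(out)


def kappa_from_odi(odi):
    """Inverse of :func:`odi_from_kappa`; kappa(1) = 0."""
    odi = np.asarray(odi, dtype=float)
    if np.any(odi <= 0) or np.any(odi > 1):
        raise ValueError("odi must lie in (0, 1]")
    out = 1.0 / np.tan(np.pi * odi / 2.0)
    out = np.where(odi == 1.0, 0.0, out)
    return out if out.ndim else float(out)


def _log_m_half(kappa):
    """log M(1/2, 3/2, kappa), overflow-free via the Kummer transform."""
    kappa = np.asarray(kappa, dtype=float)
    return kappa + np.log(hyp1f1(1.0, 1.5, -kappa))


def watson_density(n, mu, kappa):
    """Watson probability density on the sphere, per steradian.

    ``f(n) = exp(kappa * (mu.n)^2) / (4 pi M(1/2, 3/2, kappa))``; antipodally
    symmetric, uniform (1/4pi) at kappa = 0.  Stable up to kappa ~ 1e4.
    """
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    for v, name in ((n, "n"), (mu, "mu")):
        norms = np.linalg.norm(v, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError(f"{name} must be unit-norm")
    t2 = np.einsum("...i,i->...", n, mu) ** 2
    # exp(kappa*(t^2 - 1)) / (4 pi M(1,3/2,-kappa)) avoids exp(kappa) overflow
    return np.exp(kappa * (t2 - 1.0)) / (4.0 * np.pi * hyp1f1(1.0, 1.5, -kappa))


def _log_sphere_integral(ev: np.ndarray) -> np.ndarray:
    """log of the surface integral of exp(n^T B n) over the unit sphere.

    ``ev`` is (..., 3), the eigenvalues of B.  In the eigenbasis, with the
    third eigenvector as polar axis,

        I = 2 pi * int_-1^1 exp(e3 t^2 + (e1+e2)(1-t^2)/2)
                           * I0((e1-e2)(1-t^2)/2) dt.

    Shifting all eigenvalues by their maximum makes every exponent
    non-positive, so the quadrature never overflows for any kappa or b.
    For extremely peaked integrands (eigenvalue spread beyond what the
    fixed-order rule resolves, ~1.2e3) the Laplace approximation around the
    dominant eigenvector is used instead; its relative error is O(1/spread).
    """
    ev = np.asarray(ev, dtype=float)
    m = ev.max(axis=-1, keepdims=True)
    e = ev - m  # all <= 0
    e1, e2, e3 = e[..., 0], e[..., 1], e[..., 2]
    t = _GL_NODES  # (q,)
    t2 = t * t
    s2 = 1.0 - t2
    a = e3[..., None] * t2 + 0.5 * (e1 + e2)[..., None] * s2
    x = 0.5 * (e1 - e2)[..., None] * s2
    # I0(x) = i0e(x) * exp(|x|); a + |x| <= 0 by construction
    integrand = np.exp(a + np.abs(x)) * i0e(x)
    with np.errstate(divide="ignore"):
        out = m[..., 0] + np.log(2.0 * np.pi * (integrand * _GL_WEIGHTS).sum(axis=-1))

    srt = np.sort(ev, axis=-1)[..., ::-1]
    b1, b2, b3 = srt[..., 0], srt[..., 1], srt[..., 2]
    peaked = (b1 - b3 > 1.2e3) & (b1 - b2 > 60.0)
    if np.any(peaked):
        with np.errstate(divide="ignore", invalid="ignore"):
            lap = b1 + np.log(2.0 * np.pi) - 0.5 * (np.log(b1 - b2) + np.log(b1 - b3))
        out = np.where(peaked, lap, out)
    return out


def _stick_quadform_eigvals(b, cos_gm, kappa, d_par):
    """Eigenvalues of B = kappa mu mu^T - b d_par g g^T (third eigenvalue 0).

    B has rank <= 2; in the plane spanned by mu and g, with c = g.mu and
    s^2 = 1 - c^2, the 2x2 restriction is
    [[kappa - bd c^2, -bd c s], [-bd c s, -bd s^2]].
    """
    b = np.asarray(b, dtype=float)
    c = np.asarray(cos_gm, dtype=float)
    bd = b * d_par
    c2 = np.clip(c * c, 0.0, 1.0)
    s2 = 1.0 - c2
    tr = kappa - bd
    det = -kappa * bd * s2
    disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0))
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    return np.stack([lam1, lam2, np.zeros_like(lam1)], axis=-1)


def a_intra(b, g, mu, kappa, constants: ModelConstants = ModelConstants()):
    """Normalised intra-neurite (dispersed stick) signal.

    Watson-weighted orientation average of ``exp(-b d_par (g.n)^2)``; equals
    1 at b = 0 and the analytic sphere average
    ``sqrt(pi/(4 b d)) * erf(sqrt(b d))`` at kappa = 0.
    """
    b = np.asarray(b, dtype=float)
    g = np.asarray(g, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if b.ndim and b.shape[0] != g.shape[0]:
        raise ValueError("b and g must align")
    cos_gm = np.einsum("...i,i->...", g, mu)
    ev = _stick_quadform_eigvals(b, cos_gm, kappa, constants.d_par)
    log_num = _log_sphere_integral(ev)
    log_den = _log_sphere_integral(np.array([kappa, 0.0, 0.0]))
    out = np.exp(log_num - log_den)
    return out if out.ndim else float(out)


def _watson_tau1(kappa: float) -> float:
    """Mean of (mu.n)^2 under the Watson distribution (1/3 at kappa = 0).

    tau1 = M(3/2, 5/2, kappa) / (3 M(1/2, 3/2, kappa)), evaluated via the
    Kummer transform so both factors stay bounded for large kappa.
    """
    return float(hyp1f1(1.0, 2.5, -kappa) / (3.0 * hyp1f1(1.0, 1.5, -kappa)))


def a_extra(b, g, mu, kappa, vin, constants: ModelConstants = ModelConstants()):
    """Normalised extra-neurite signal: Gaussian in the dispersion-averaged
    axially symmetric tensor.

    The cylindrical tensor with parallel diffusivity d_par and tortuosity
    perpendicular diffusivity d_perp = d_par (1 - vin) is averaged over the
    Watson orientation distribution: the mean tensor keeps the trace
    d_par + 2 d_perp, has ``d_perp + (d_par - d_perp) tau1`` along mu
    (tau1 = mean squared cosine to mu), and shares the remainder equally
    across the perpendicular plane.
    """
    if not 0.0 <= vin <= 1.0:
        raise ValueError("vin must lie in [0, 1]")
    b = np.asarray(b, dtype=float)
    g = np.asarray(g, dtype=float)
    mu = np.asarray(mu, dtype=float)
    d_par = constants.d_par
    d_perp = d_par * (1.0 - vin)
    tau1 = _watson_tau1(kappa)
    d_axial = d_perp + (d_par - d_perp) * tau1
    d_radial = 0.5 * (d_par + 2.0 * d_perp - d_axial)
    cos2 = np.einsum("...i,i->...", g, mu) ** 2
    out = np.exp(-b * (d_radial + (d_axial - d_radial) * cos2))
    return out if out.ndim else float(out)


def forward_signal(
    params: NoddiParams,
    scheme: GradientScheme,
    constants: ModelConstants = ModelConstants(),
) -> np.ndarray:
    """Normalised model signal for every volume of a scheme.

    Equals 1 exactly at every b0 volume for any parameter values.
    """
    b = scheme.bvals
    g = scheme.bvecs
    ain = a_intra(b, g, params.mu, params.kappa, constants)
    aen = a_extra(b, g, params.mu, params.kappa, params.vin, constants)
    aiso = np.exp(-b * constants.d_iso)
    tissue = params.vin * ain + (1.0 - params.vin) * aen
    return (1.0 - params.fiso) * tissue + params.fiso * aiso


def isotropic_stick_average(bd):
    """Closed-form sphere average of the stick signal at kappa = 0:
    sqrt(pi / (4 x)) * erf(sqrt(x)) with x = b * d_par (1 at x = 0)."""
    bd = np.asarray(bd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            bd > 0,
            np.sqrt(np.pi / (4.0 * np.where(bd > 0, bd, 1.0)))
            * erf(np.sqrt(np.where(bd > 0, bd, 1.0))),
            1.0,
        )
    return out if out.ndim else float(out)
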