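"""Synthetic data with known ground truth.

Two generators stand in for the study's (undeposited) raw data:

* voxel/phantom simulation — noiseless signals from the three-compartment
  forward model, scaled by a per-shell b0 baseline to emulate the echo-time
  mismatch between the two shells, then Rician-corrupted (magnitude MRI);

* cohort simulation — per-acquisition regional metric tables with continuous
  piecewise-linear age trajectories (breakpoint near 38 weeks
  post-menstrual age), covariate effects, per-subject random intercepts and
  repeated scans, mirroring the structure of a 99-infant cohort with 8
  infants scanned twice.

Defaults encode the study conditions: 99 subjects, 8 rescans, scans between
25 and 47 weeks PMA, 60% male, 30% small-for-gestational-age, gestational
age at birth 24-37 weeks, and a high-shell b0 baseline at 0.85 of the
low-shell one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .noddi_model import ModelConstants, NoddiParams, forward_signal
from .scheme import GradientScheme

__all__ = [
    "VoxelTruth",
    "simulate_voxel",
    "simulate_phantom",
    "MetricTrajectory",
    "SyntheticCohortSpec",
    "simulate_cohort",
    "DEFAULT_TRAJECTORIES",
]


@dataclass(frozen=True)
class VoxelTruth:
    """Ground-truth tissue parameters of one voxel."""

    ndi: float
    odi: float
    fiso: float
    mu: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.ndi <= 1.0:
            raise ValueError(f"ndi must lie in [0, 1], got {self.ndi}")
        if not 0.0 < self.odi <= 1.0:
            raise ValueError(f"odi must lie in (0, 1], got {self.odi}")
        if not 0.0 <= self.fiso <= 1.0:
            raise ValueError(f"fiso must lie in [0, 1], got {self.fiso}")
        mu = np.asarray(self.mu, dtype=float)
        if mu.shape != (3,) or abs(np.linalg.norm(mu) - 1.0) > 1e-6:
            raise ValueError("mu must be a unit 3-vector")
        object.__setattr__(self, "mu", mu)

    def params(self) -> NoddiParams:
        from .noddi_model import kappa_from_odi

        return NoddiParams(vin=self.ndi, kappa=kappa_from_odi(self.odi),
                           fiso=self.fiso, mu=self.mu)


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((S + e1)^2 + e2^2), e1, e2 ~ N(0, sigma)."""
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    e1 = rng.normal(0.0, sigma, size=np.shape(signal))
    e2 = rng.normal(0.0, sigma, size=np.shape(signal))
    return np.sqrt((signal + e1) ** 2 + e2**2)


def simulate_voxel(
    truth: VoxelTruth,
    scheme: GradientScheme,
    b0_scale_per_shell: dict[int, float] | None = None,
    sigma: float = 0.05,
    seed: int | np.random.Generator = 0,
    constants: ModelConstants = ModelConstants(),
) -> np.ndarray:
    """One voxel's signal across all scheme volumes.

    The noiseless normalised forward signal is multiplied by its shell's b0
    baseline (default 1.0 for shell 0 and 0.85 for shell 1, emulating the
    echo-time difference between the two shells) and Rician-corrupted with
    noise SD ``sigma`` (the default corresponds to SNR 20 at the low-shell
    b0).  Deterministic for a fixed seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if b0_scale_per_shell is None:
        b0_scale_per_shell = {0: 1.0, 1: 0.85}
    for s in scheme.shells:
        if b0_scale_per_shell.get(int(s), 0.0) <= 0:
            raise ValueError(f"b0 scale for shell {s} must be strictly positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = forward_signal(truth.params(), scheme, constants)
    scale = np.array([b0_scale_per_shell[int(s)] for s in scheme.shell_id])
    return rician(A * scale, sigma, rng)


def simulate_phantom(
    truth_maps: dict[str, np.ndarray],
    labels: np.ndarray,
    scheme: GradientScheme,
    sigma: float = 0.05,
    seed: int = 0,
    b0_scale_per_shell: dict[int, float] | None = None,
    constants: ModelConstants = ModelConstants(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise simulation over a labelled 3D grid.

    ``truth_maps`` holds "ndi", "odi", "fiso" (3D) and "mu" (3D + 3);
    ``labels`` is an integer region-ID volume (0 = background).  Returns
    (4D signal, label volume, grey-matter mask); the mask is labels > 0.
    Bit-identical for a fixed seed.
    """
    labels = np.asarray(labels)
    shape = labels.shape
    for k in ("ndi", "odi", "fiso"):
        if k not in truth_maps or np.shape(truth_maps[k]) != shape:
            raise ValueError(f"truth map '{k}' missing or shape mismatch with labels")
    if np.shape(truth_maps["mu"]) != shape + (3,):
        raise ValueError("truth map 'mu' must have shape labels.shape + (3,)")
    rng = np.random.default_rng(seed)
    signal = np.zeros(shape + (scheme.n_volumes,))
    for idx in np.ndindex(shape):
        truth = VoxelTruth(
            ndi=float(truth_maps["ndi"][idx]),
            odi=float(truth_maps["odi"][idx]),
            fiso=float(truth_maps["fiso"][idx]),
            mu=np.asarray(truth_maps["mu"][idx]),
        )
        signal[idx] = simulate_voxel(
            truth, scheme, b0_scale_per_shell, sigma, rng, constants
        )
    gm_mask = labels > 0
    return signal, labels.copy(), gm_mask


@dataclass(frozen=True)
class MetricTrajectory:
    """Continuous piecewise-linear age trajectory of one metric.

    ``value_at_break`` is the trend value at the breakpoint; ``slope_pre``
    and ``slope_post`` are in metric units per week; ``noise_sd`` the
    residual SD in metric units.
    """

    value_at_break: float
    slope_pre: float
    slope_post: float
    noise_sd: float

    def trend(self, pma: np.ndarray, breakpoint: float) -> np.ndarray:
        d = np.asarray(pma, dtype=float) - breakpoint
        return self.value_at_break + np.where(d < 0, self.slope_pre * d, self.slope_post * d)


# Whole-cortex trajectory shapes following the developmental pattern the
# model is built to detect: FA falls then rises, MD falls throughout, NDI
# dips then rises, ODI rises then plateaus; grey-matter volume (mm^3) grows
# throughout and curvature (1/mm) rises then plateaus.  Levels are plausible
# cortical values at term; each noise SD is calibrated so the generated
# whole-cortex age correlations match the strengths reported for this cohort
# (ODI ~0.77 and FA ~-0.66 before 38 weeks, FA ~0.43 and NDI ~0.47 after,
# MD ~-0.63 and volume ~0.82 across the full range).
DEFAULT_TRAJECTORIES: dict[str, MetricTrajectory] = {
    "FA": MetricTrajectory(0.15, -0.010, +0.006, 0.022),
    "MD": MetricTrajectory(1.10e-3, -1.5e-5, -1.5e-5, 6.0e-5),
    "NDI": MetricTrajectory(0.20, -0.004, +0.006, 0.015),
    "ODI": MetricTrajectory(0.45, +0.012, 0.0, 0.019),
    "volume": MetricTrajectory(1.0e5, 6.0e3, 6.0e3, 1.4e4),
    "curvature": MetricTrajectory(0.35, +0.012, 0.0, 0.019),
}

#: Default covariate effect sizes, expressed per metric noise SD so one set
#: is meaningful across metrics of very different scales.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "sex": 0.2,            # per level
    "sga": -0.4,           # small-for-gestational-age
    "resp_days": -0.01,    # per day of respiratory support
    "coil": 0.5,           # 32-channel vs 8-channel offset
    "ga_birth": 0.05,      # per week of gestational age at birth
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Design of a synthetic cohort.

    ``subject_intercept_sd`` and the covariate effects are expressed in
    units of each metric's own noise SD, so a single number applies across
    metrics with different physical scales.
    """

    n_subjects: int = 99
    n_rescanned: int = 8
    pma_range: tuple[float, float] = (25.0, 47.0)
    ga_range: tuple[float, float] = (24.0, 37.0)
    breakpoint_true: float = 38.0
    trajectories: dict[str, MetricTrajectory] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES)
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    subject_intercept_sd: float = 1.0
    noise_scale: float = 1.0          # global multiplier on every noise_sd
    male_fraction: float = 0.6
    sga_prevalence: float = 0.30
    n_regions: int = 82
    region_offset_sd: float = 0.5     # per-region intercept SD, in noise-SD units
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pma_range[0] < self.breakpoint_true < self.pma_range[1]:
            raise ValueError("breakpoint_true must lie inside pma_range")
        if self.n_rescanned > self.n_subjects:
            raise ValueError("n_rescanned must be <= n_subjects")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def simulate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Long-format per-acquisition cohort table with known generative truth.

    One row per acquisition (``n_subjects + n_rescanned`` rows).  Covariates
    are sampled once per subject; each metric value is the continuous
    piecewise-linear age trend plus covariate effects, a subject random
    intercept and Gaussian noise.  Columns: subject/acquisition IDs, the
    covariates, and one column per metric and region named
    ``{metric}__cortex`` or ``{metric}__r{i:02d}``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    lo, hi = spec.pma_range

    ga = rng.uniform(*spec.ga_range, size=n)
    sex = (rng.random(n) < spec.male_fraction).astype(int)
    sga = (rng.random(n) < spec.sga_prevalence).astype(int)
    resp = np.clip(np.round(rng.lognormal(np.log(3.0), 1.2, size=n)), 0, 142).astype(int)
    coil = (rng.random(n) < 0.5).astype(int)

    rescanned = rng.choice(n, size=spec.n_rescanned, replace=False)
    rows: list[dict] = []
    for s in range(n):
        if s in rescanned:
            # early scan plus a term-equivalent scan
            lo1 = max(lo, ga[s] + 0.2)
            hi1 = max(lo1 + 1.0, min(lo + 11.0, hi - 2.0))
            p1 = rng.uniform(lo1, hi1)
            p2 = rng.uniform(max(p1 + 2.0, spec.breakpoint_true - 1.0), hi)
            pmas = [p1, p2]
        else:
            # term-skewed scan-age distribution matching the cohort's
            # reported quartiles (~35 / ~39 / ~42 weeks)
            p = lo + (hi - lo) * rng.beta(2.8, 1.8)
            pmas = [min(max(p, ga[s] + 0.2), hi)]
        for p in pmas:
            rows.append({"subject_id": f"s{s:03d}", "pma": p, "ga_birth": ga[s],
                         "sex": sex[s], "sga": sga[s], "resp_days": resp[s],
                         "coil": coil[s]})
    table = pd.DataFrame(rows)
    table.insert(1, "acq_id", [f"a{i:03d}" for i in range(len(table))])

    subj_index = table["subject_id"].str.slice(1).astype(int).to_numpy()
    regions = ["cortex"] + [f"r{i:02d}" for i in range(spec.n_regions)]
    for metric, traj in spec.trajectories.items():
        sd = traj.noise_sd * spec.noise_scale
        subj_int = rng.normal(0.0, spec.subject_intercept_sd * sd, size=n)
        eff = spec.covariate_effects
        cov_term = sd * (
            eff.get("sex", 0.0) * table["sex"].to_numpy()
            + eff.get("sga", 0.0) * table["sga"].to_numpy()
            + eff.get("resp_days", 0.0) * table["resp_days"].to_numpy()
            + eff.get("coil", 0.0) * table["coil"].to_numpy()
            + eff.get("ga_birth", 0.0) * (table["ga_birth"].to_numpy() - 31.0)
        )
        trend = traj.trend(table["pma"].to_numpy(), spec.breakpoint_true)
        base = trend + cov_term + subj_int[subj_index]
        for r in regions:
            offset = 0.0 if r == "cortex" else rng.normal(0.0, spec.region_offset_sd * sd)
            noise = rng.normal(0.0, sd, size=len(table))
            table[f"{metric}__{r}"] = base + offset + noise
    return table
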