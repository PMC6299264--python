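"""Developmental-trajectory statistics.

The analysis layer answers three questions about per-region metric tables:

* how each metric relates to age (post-menstrual age, PMA) — Spearman
  partial correlations controlling for sex, small-for-gestational-age
  status, respiratory-support days, head coil and gestational age at birth,
  with the covariates regressed out by a linear mixed-effects model (random
  intercept per subject) whenever repeated scans are present;

* whether a trajectory is biphasic — a continuous two-segment ("broken
  line") regression with the breakpoint searched between the 1st and 3rd
  PMA quartiles, compared against a single line by small-sample-corrected
  AIC;

* how micro- and macrostructural metrics relate to each other, optionally
  controlling for PMA.

Age windows follow the <38 / >=38-week split (a scan at exactly 38.0 weeks
falls in the post window).  Multiple testing across regions is controlled
per contrast (one metric x window x correlation family) with the
Benjamini-Hochberg false-discovery-rate procedure at 5%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "PartialCorrResult",
    "BiphasicFit",
    "StatsConfig",
    "CohortResults",
    "residualise",
    "partial_spearman",
    "window_split",
    "fit_biphasic",
    "micro_macro_association",
    "fdr_adjust",
    "run_cohort_analysis",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "sga", "resp_days", "coil", "ga_birth")


@dataclass(frozen=True)
class PartialCorrResult:
    rho: float
    p: float
    n: int
    window: str = "full"

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0 or not 0.0 <= self.p <= 1.0:
            raise ValueError("invalid correlation result")
        if self.window not in ("full", "pre38", "post38"):
            raise ValueError(f"unknown window {self.window!r}")


@dataclass(frozen=True)
class BiphasicFit:
    breakpoint: float
    slope_pre: float
    slope_post: float
    intercept: float            # trend value at the breakpoint
    aicc_biphasic: float
    aicc_mono: float
    preferred: str

    def __post_init__(self) -> None:
        if self.preferred not in ("biphasic", "monophasic"):
            raise ValueError("preferred must be 'biphasic' or 'monophasic'")


def _design(covariates) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j - 1] if j - 1 < len(names) else f"col{j}")
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")


def residualise(values, covariates=None, subject_ids=None, repeated: bool = False) -> np.ndarray:
    """Covariate-adjusted residuals of a metric vector.

    With ``repeated=True`` and at least one subject observed twice, a linear
    mixed model with a per-subject random intercept is fitted and the
    conditional residuals (observed minus fixed effects minus the predicted
    subject intercept) are returned; otherwise ordinary least-squares
    residuals.  An intercept is always included, so the residuals are
    (essentially) mean-zero.
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    Xc, names = _design(covariates)
    if Xc.size:
        if Xc.shape[0] != n:
            raise ValueError("covariates length mismatch")
        X = np.column_stack([np.ones(n), Xc])
    else:
        X = np.ones((n, 1))
    _check_full_rank(X, names)
    # standardise the covariate columns: a pure reparameterisation (the
    # residuals are unchanged) that keeps the optimiser well conditioned
    if X.shape[1] > 1:
        sd = X[:, 1:].std(axis=0)
        sd[sd == 0] = 1.0
        X = np.column_stack([X[:, 0], (X[:, 1:] - X[:, 1:].mean(axis=0)) / sd])

    use_lme = False
    groups = None
    if repeated:
        if subject_ids is None:
            raise ValueError("repeated=True requires subject_ids")
        groups = np.asarray(subject_ids)
        if pd.Series(groups).duplicated().any():
            use_lme = True
        else:
            logger.info("no subject observed twice; residualisation reduces to OLS")
    if not use_lme:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    model = MixedLM(y, X, groups=groups)
    try:
        with warnings.catch_warnings():
            # a near-zero random-intercept variance is a legitimate boundary
            # solution here (few subjects are scanned twice), not a failure
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
    except Exception:
        logger.warning("mixed-model fit failed; falling back to OLS residuals")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta
    fixed = X @ fit.fe_params
    re = fit.random_effects
    ranef = np.array([float(np.asarray(re[g]).ravel()[0]) for g in groups])
    return y - fixed - ranef


def _spearman_perm_p(rx: np.ndarray, ry: np.ndarray, rho: float, seed: int,
                     n_perm: int = 10000) -> float:
    rng = np.random.default_rng(seed)
    count = 0
    ry_ranks = stats.rankdata(ry)
    rx_ranks = stats.rankdata(rx)
    for _ in range(n_perm):
        perm = rng.permutation(ry_ranks)
        r = np.corrcoef(rx_ranks, perm)[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def partial_spearman(
    x,
    y,
    covariates=None,
    subject_ids=None,
    repeated: bool = False,
    window: str = "full",
    seed: int = 0,
) -> PartialCorrResult:
    """Spearman correlation of covariate-residualised x and y.

    Both variables are residualised with :func:`residualise` first, then
    rank-correlated.  The p-value uses the usual t approximation for
    n > 10 and a seeded 10,000-draw permutation test for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 8:
        raise ValueError(f"need at least 8 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: correlation undefined")
    rx = residualise(x, covariates, subject_ids, repeated)
    ry = residualise(y, covariates, subject_ids, repeated)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant residual vector: correlation undefined")
    rho, p = stats.spearmanr(rx, ry)
    if n <= 10:
        p = _spearman_perm_p(rx, ry, rho, seed)
    return PartialCorrResult(rho=float(rho), p=float(min(p, 1.0)), n=n, window=window)


def window_split(table: pd.DataFrame, split_week: float = 38.0,
                 pma_col: str = "pma") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition acquisitions into pre (< split) and post (>= split) windows."""
    pma = table[pma_col].to_numpy(dtype=float)
    if not (pma.min() <= split_week <= pma.max()):
        logger.warning("split week %.1f outside observed PMA range", split_week)
    pre = table[pma < split_week]
    post = table[pma >= split_week]
    if len(pre) == 0 or len(post) == 0:
        logger.warning("empty window at split %.1f", split_week)
    return pre, post


def _segment_design(pma: np.ndarray, bp: float) -> np.ndarray:
    d = pma - bp
    return np.column_stack([np.ones_like(pma), np.minimum(d, 0.0), np.maximum(d, 0.0)])


def _aicc(rss: float, n: int, k: int, floor: float) -> float:
    rss = max(rss, floor)
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_biphasic(
    pma,
    values,
    search_lo: float | None = None,
    search_hi: float | None = None,
    grid_step: float = 0.1,
    continuous: bool = True,
) -> BiphasicFit:
    """Continuous broken-line regression with grid-searched breakpoint.

    Candidate breakpoints run from ``search_lo`` to ``search_hi`` (defaults:
    1st and 3rd quartiles of the PMA values) in ``grid_step`` increments; a
    candidate needs at least 3 observations strictly on each side.  The
    minimum-RSS candidate wins, ties broken toward the smaller breakpoint.
    Model choice compares small-sample-corrected AIC of the broken line
    (k = 4 + error variance) against a single line (k = 2 + error
    variance); the biphasic model is preferred only if its AICc is strictly
    lower.  A discontinuous two-line variant is available with
    ``continuous=False``.
    """
    pma = np.asarray(pma, dtype=float)
    y = np.asarray(values, dtype=float)
    if pma.shape[0] != y.shape[0]:
        raise ValueError("pma and values must align")
    n = pma.shape[0]
    if n < 8:
        raise ValueError("need at least 8 observations")
    if search_lo is None:
        search_lo = float(np.percentile(pma, 25))
    if search_hi is None:
        search_hi = float(np.percentile(pma, 75))
    n_steps = int(np.floor((search_hi - search_lo) / grid_step + 1e-9))
    candidates = search_lo + grid_step * np.arange(n_steps + 1)

    # RSS floor relative to total variance keeps AICc finite on noiseless
    # data without affecting the breakpoint (pure argmin of RSS) and is
    # invariant to affine rescaling of the response.
    tss = float(np.sum((y - y.mean()) ** 2))
    floor = max(tss, 1.0e-300) * 1e-12

    best = None
    for bp in candidates:
        n_pre = int((pma < bp).sum())
        n_post = n - n_pre
        if n_pre < 3 or n_post < 3:
            continue
        if continuous:
            X = _segment_design(pma, bp)
        else:
            pre = pma < bp
            d = pma - bp
            X = np.column_stack([pre, d * pre, ~pre, d * ~pre]).astype(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        if best is None or rss < best[0] - 1e-15 * max(tss, 1.0):
            best = (rss, float(bp), beta)
    if best is None:
        raise ValueError("no candidate breakpoint has 3 observations on each side")
    rss_bi, bp, beta = best

    Xm = np.column_stack([np.ones(n), pma])
    bm, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    rss_mono = float(np.sum((y - Xm @ bm) ** 2))

    k_bi = (4 if continuous else 5) + 1
    k_mono = 2 + 1
    aicc_bi = _aicc(rss_bi, n, k_bi, floor)
    aicc_mono = _aicc(rss_mono, n, k_mono, floor)
    if continuous:
        intercept, slope_pre, slope_post = beta
    else:
        slope_pre, slope_post = beta[1], beta[3]
        intercept = beta[2]
    return BiphasicFit(
        breakpoint=bp,
        slope_pre=float(slope_pre),
        slope_post=float(slope_post),
        intercept=float(intercept),
        aicc_biphasic=aicc_bi,
        aicc_mono=aicc_mono,
        preferred="biphasic" if aicc_bi < aicc_mono else "monophasic",
    )


def fdr_adjust(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment within one contrast.

    Adjusted p-values are ``p_(i) * m / i`` on the sorted vector with a
    running minimum applied from the largest rank down (the step-up rule),
    capped at 1.  Returns (adjusted p-values, significance flags at
    ``alpha``); agrees with ``statsmodels.stats.multitest.multipletests``
    to floating-point rounding.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    return p_adj, p_adj <= alpha


def micro_macro_association(
    table: pd.DataFrame,
    micro: str,
    macro: str,
    window: str = "full",
    control_pma: bool = False,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    split_week: float = 38.0,
    regions: list[str] | None = None,
    seed: int = 0,
) -> dict[str, PartialCorrResult]:
    """Per-region partial Spearman between a micro- and a macrostructural
    metric (``macro`` in {volume, curvature}), with the standard covariate
    set plus PMA when ``control_pma`` is true."""
    sub = _window_table(table, window, split_week)
    if regions is None:
        regions = _regions_in(table, micro)
    covs = list(covariates) + (["pma"] if control_pma else [])
    out: dict[str, PartialCorrResult] = {}
    for r in regions:
        xcol, ycol = f"{micro}__{r}", f"{macro}__{r}"
        if xcol not in sub.columns or ycol not in sub.columns:
            continue
        out[r] = partial_spearman(
            sub[xcol], sub[ycol], sub[covs], sub["subject_id"],
            repeated=True, window=window, seed=seed,
        )
    return out


def _window_table(table: pd.DataFrame, window: str, split_week: float) -> pd.DataFrame:
    if window == "full":
        return table
    pre, post = window_split(table, split_week)
    if window == "pre38":
        return pre
    if window == "post38":
        return post
    raise ValueError(f"unknown window {window!r}")


def _regions_in(table: pd.DataFrame, metric: str) -> list[str]:
    prefix = f"{metric}__"
    return [c[len(prefix):] for c in table.columns if c.startswith(prefix)]


@dataclass(frozen=True)
class StatsConfig:
    """Configuration of the cohort analysis."""

    split_week: float = 38.0
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.05
    grid_step: float = 0.1
    breakpoint_mode: str = "quartile"      # or "fixed"
    search_lo: float = 35.0                # used in "fixed" mode
    search_hi: float = 42.0
    continuous: bool = True
    metrics: tuple[str, ...] | None = None
    regions: tuple[str, ...] | None = None  # restrict analysed regions
    micro_metrics: tuple[str, ...] = ("FA", "MD", "NDI", "ODI")
    macro_metrics: tuple[str, ...] = ("volume", "curvature")
    seed: int = 0


@dataclass
class CohortResults:
    """Tidy result tables of one cohort analysis run."""

    trajectories: pd.DataFrame
    biphasic: pd.DataFrame
    micro_macro: pd.DataFrame
    manifest: dict


class _Residualiser:
    """Caches covariate-residualised columns per (window, covariate-set)."""

    def __init__(self, covariates: tuple[str, ...]):
        self.covariates = covariates
        self._cache: dict[tuple, np.ndarray] = {}

    def get(self, sub: pd.DataFrame, window: str, col: str, extra: tuple[str, ...] = ()):
        key = (window, col, extra)
        if key not in self._cache:
            y = sub[col].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                raise ValueError(f"column {col!r} is constant: correlation undefined")
            covs = list(self.covariates) + list(extra)
            self._cache[key] = residualise(y, sub[covs], sub["subject_id"], repeated=True)
        return self._cache[key]


def _spearman_of_residuals(rx, ry, n, window, seed) -> PartialCorrResult:
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant residual vector: correlation undefined")
    rho, p = stats.spearmanr(rx, ry)
    if n <= 10:
        p = _spearman_perm_p(np.asarray(rx), np.asarray(ry), rho, seed)
    return PartialCorrResult(rho=float(rho), p=float(min(p, 1.0)), n=int(n), window=window)


def run_cohort_analysis(table: pd.DataFrame, config: StatsConfig = StatsConfig()) -> CohortResults:
    """Deterministic orchestration of the full statistical analysis.

    Produces three tidy tables:

    * ``trajectories`` — metric-vs-PMA partial Spearman per (region, metric,
      window), FDR-adjusted across regions within each (metric, window)
      contrast (the whole-cortex row is its own single-test contrast);
    * ``biphasic`` — breakpoint regression per (region, metric) with AICc
      model choice;
    * ``micro_macro`` — micro-vs-macro partial correlations per (region,
      pair, window), FDR-adjusted per contrast.

    Errors in one (region, metric) cell are logged with context and skipped;
    the run always completes.
    """
    required = {"subject_id", "pma", *config.covariates}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")

    metrics = config.metrics
    if metrics is None:
        metrics = tuple(sorted({c.split("__")[0] for c in table.columns if "__" in c}))
    all_regions = _regions_in(table, metrics[0])
    if config.regions is not None:
        all_regions = [r for r in all_regions if r in config.regions or r == "cortex"]

    windows = {"full": table}
    pre, post = window_split(table, config.split_week)
    if len(pre) >= 8:
        windows["pre38"] = pre
    if len(post) >= 8:
        windows["post38"] = post

    res = _Residualiser(config.covariates)
    traj_rows = []
    for window, sub in windows.items():
        rx = res.get(sub, window, "pma")
        for metric in metrics:
            for region in all_regions:
                col = f"{metric}__{region}"
                if col not in sub.columns:
                    continue
                try:
                    ry = res.get(sub, window, col)
                    r = _spearman_of_residuals(rx, ry, len(sub), window, config.seed)
                except Exception as err:
                    logger.warning("trajectory %s/%s/%s skipped: %s",
                                   metric, region, window, err)
                    continue
                traj_rows.append({"region": region, "metric": metric, "window": window,
                                  "rho": r.rho, "p": r.p, "n": r.n})
    traj = pd.DataFrame(traj_rows)
    traj = _fdr_per_contrast(traj, ["metric", "window"], config.alpha)

    bi_rows = []
    lo = config.search_lo if config.breakpoint_mode == "fixed" else None
    hi = config.search_hi if config.breakpoint_mode == "fixed" else None
    for metric in metrics:
        for region in all_regions:
            col = f"{metric}__{region}"
            if col not in table.columns:
                continue
            try:
                fit = fit_biphasic(
                    table["pma"], table[col], search_lo=lo, search_hi=hi,
                    grid_step=config.grid_step, continuous=config.continuous,
                )
            except Exception as err:
                logger.warning("biphasic %s/%s skipped: %s", metric, region, err)
                continue
            bi_rows.append({
                "region": region, "metric": metric, "breakpoint": fit.breakpoint,
                "slope_pre": fit.slope_pre, "slope_post": fit.slope_post,
                "aicc_biphasic": fit.aicc_biphasic, "aicc_mono": fit.aicc_mono,
                "preferred": fit.preferred,
            })
    biphasic = pd.DataFrame(bi_rows)

    mm_rows = []
    mm_jobs = [(w, False) for w in ("pre38", "post38") if w in windows]
    mm_jobs.append(("full", True))
    for window, control in mm_jobs:
        sub = windows[window]
        extra = ("pma",) if control else ()
        for micro in config.micro_metrics:
            if micro not in metrics:
                continue
            for macro in config.macro_metrics:
                if macro not in metrics:
                    continue
                for region in all_regions:
                    xcol, ycol = f"{micro}__{region}", f"{macro}__{region}"
                    if xcol not in sub.columns or ycol not in sub.columns:
                        continue
                    try:
                        rx = res.get(sub, window, xcol, extra)
                        ry = res.get(sub, window, ycol, extra)
                        r = _spearman_of_residuals(rx, ry, len(sub), window, config.seed)
                    except Exception as err:
                        logger.warning("micro-macro %s~%s/%s/%s skipped: %s",
                                       micro, macro, region, window, err)
                        continue
                    mm_rows.append({
                        "region": region, "micro": micro, "macro": macro,
                        "window": window, "control_pma": control,
                        "rho": r.rho, "p": r.p, "n": r.n,
                    })
    mm = pd.DataFrame(mm_rows)
    mm = _fdr_per_contrast(mm, ["micro", "macro", "window", "control_pma"], config.alpha)

    manifest = {
        "n_rows": int(len(table)),
        "n_subjects": int(table["subject_id"].nunique()),
        "split_week": config.split_week,
        "covariates": list(config.covariates),
        "alpha": config.alpha,
        "breakpoint_mode": config.breakpoint_mode,
        "continuous": config.continuous,
        "metrics": list(metrics),
        "n_regions": len([r for r in all_regions if r != "cortex"]),
        "seed": config.seed,
    }
    return CohortResults(trajectories=traj, biphasic=biphasic, micro_macro=mm,
                         manifest=manifest)


def _fdr_per_contrast(df: pd.DataFrame, contrast_cols: list[str], alpha: float) -> pd.DataFrame:
    """FDR across regions within each contrast; the whole-cortex row forms
    its own single-member family."""
    if df.empty:
        df = df.copy()
        df["p_fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df = df.copy()
    df["p_fdr"] = np.nan
    df["significant"] = False
    is_cortex = df["region"] == "cortex"
    for _, idx in df[~is_cortex].groupby(contrast_cols).groups.items():
        p_adj, flags = fdr_adjust(df.loc[idx, "p"].to_numpy(), alpha)
        df.loc[idx, "p_fdr"] = p_adj
        df.loc[idx, "significant"] = flags
    df.loc[is_cortex, "p_fdr"] = df.loc[is_cortex, "p"]
    df.loc[is_cortex, "significant"] = df.loc[is_cortex, "p"] <= alpha
    return df
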