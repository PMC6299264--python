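"""Statistical layer: residualisation, partial Spearman, breakpoint
regression, FDR, and the cohort orchestration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortimat.devstats import (
    StatsConfig,
    fdr_adjust,
    fit_biphasic,
    micro_macro_association,
    partial_spearman,
    residualise,
    run_cohort_analysis,
    window_split,
)
from cortimat.dwi_synth import MetricTrajectory, SyntheticCohortSpec, simulate_cohort


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up by direct enumeration: the
    adjusted value of the i-th smallest p is min(1, min_{j >= i} p_(j)*m/j),
    computed with explicit loops rather than vectorised running minima."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    adj = np.empty(m)
    for i in range(m):
        candidates = [p_sorted[j] * m / (j + 1) for j in range(i, m)]
        adj[i] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adj
    return out


class TestResidualise:
    def test_exact_linear_gives_zero_residuals(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 2.0 + 3.0 * x
        r = residualise(y, x[:, None])
        assert np.abs(r).max() < 1e-10

    def test_null_covariates_leave_centred_values(self):
        """With zero-effect covariates the residuals stay close to the
        centred values: fitting k unrelated regressors removes about k/n of
        the variance, so the correlation stays near sqrt(1 - k/n) ~ 0.98."""
        cors = []
        for seed in range(10):
            spec = SyntheticCohortSpec(covariate_effects={}, n_regions=0, seed=seed)
            t = simulate_cohort(spec)
            y = t["NDI__cortex"].to_numpy()
            covs = t[["sex", "sga", "resp_days", "coil", "ga_birth"]]
            r = residualise(y, covs)
            cors.append(np.corrcoef(r, y - y.mean())[0, 1])
        assert np.mean(cors) >= 0.95

    def test_mixed_model_beats_ols_with_subject_intercepts(self):
        """Strong per-subject intercepts: conditional mixed-model residuals
        have lower variance than OLS residuals."""
        spec = SyntheticCohortSpec(n_subjects=40, n_rescanned=40,
                                   subject_intercept_sd=4.0, n_regions=0, seed=8)
        t = simulate_cohort(spec)
        y = t["FA__cortex"].to_numpy()
        covs = t[["sex", "sga", "resp_days", "coil", "ga_birth"]]
        r_lme = residualise(y, covs, t["subject_id"], repeated=True)
        r_ols = residualise(y, covs)
        assert r_lme.var() < r_ols.var()

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        covs = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            residualise(rng.normal(size=30), covs)


class TestPartialSpearman:
    def test_equals_plain_spearman_without_covariates(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        r = partial_spearman(x, y)
        rho, p = stats.spearmanr(x, y)
        assert r.rho == pytest.approx(rho, abs=1e-14)
        assert r.p == pytest.approx(p, abs=1e-14)

    def test_monotone_limit(self, rng):
        x = rng.normal(size=80)
        y = np.exp(x)  # strictly monotone, no noise
        covs = rng.normal(size=(80, 2))
        r = partial_spearman(x, y, covs)
        assert r.rho > 0.95

    def test_small_sample_uses_permutation(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        r = partial_spearman(x, y, seed=1)
        r2 = partial_spearman(x, y, seed=1)
        assert r.p == r2.p  # seeded permutation is deterministic
        assert 0 < r.p <= 1

    def test_constant_residuals_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError):
            partial_spearman(x, np.ones(20))

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            partial_spearman(np.arange(5.0), np.arange(5.0))

    def test_sign_recovery_against_generator(self):
        """The post-break rise designed into the neurite-density trajectory
        surfaces as a positive covariate-adjusted correlation."""
        hits = 0
        for seed in range(20):
            t = simulate_cohort(SyntheticCohortSpec(n_regions=0, seed=seed))
            post = t[t["pma"] >= 38.0]
            covs = post[["sex", "sga", "resp_days", "coil", "ga_birth"]]
            r = partial_spearman(post["pma"], post["NDI__cortex"], covs,
                                 post["subject_id"], repeated=True)
            hits += r.rho > 0
        assert hits >= 19


class TestWindowSplit:
    def test_exact_boundary_goes_post(self):
        t = pd.DataFrame({"pma": [36.0, 38.0, 40.0]})
        pre, post = window_split(t, 38.0)
        assert 38.0 in post["pma"].values
        assert 38.0 not in pre["pma"].values

    def test_partition(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame({"pma": rng.uniform(25, 47, 100)})
        pre, post = window_split(t, 38.0)
        assert len(pre) + len(post) == 100

    def test_empty_window_warns(self, caplog):
        t = pd.DataFrame({"pma": [39.0, 40.0, 41.0]})
        pre, post = window_split(t, 39.0)
        assert len(pre) == 0


class TestFitBiphasic:
    def test_noiseless_kink_recovered_exactly(self):
        pma = np.linspace(30, 46, 60)
        y = np.where(pma < 38.0, -(pma - 38.0), 2.0 * (pma - 38.0)) + 5.0
        fit = fit_biphasic(pma, y, search_lo=35.0, search_hi=42.0, grid_step=0.1)
        assert fit.breakpoint == pytest.approx(38.0, abs=1e-9)
        assert fit.preferred == "biphasic"
        assert fit.slope_pre == pytest.approx(-1.0, abs=1e-8)
        assert fit.slope_post == pytest.approx(2.0, abs=1e-8)

    def test_noiseless_line_prefers_monophasic(self):
        pma = np.linspace(30, 46, 50)
        y = 0.3 * pma - 2.0
        fit = fit_biphasic(pma, y, search_lo=35.0, search_hi=42.0)
        assert fit.preferred == "monophasic"

    def test_affine_invariance_of_breakpoint(self, rng):
        pma = rng.uniform(28, 46, 80)
        y = np.where(pma < 37.0, -0.5 * (pma - 37.0), 0.8 * (pma - 37.0))
        y = y + rng.normal(0, 0.3, 80)
        f1 = fit_biphasic(pma, y)
        f2 = fit_biphasic(pma, 1000.0 * y - 77.0)
        assert f1.breakpoint == f2.breakpoint
        assert f1.preferred == f2.preferred

    def test_quartile_default_search_bounds(self, rng):
        pma = rng.uniform(25, 47, 100)
        y = rng.normal(size=100)
        fit = fit_biphasic(pma, y)
        q1, q3 = np.percentile(pma, [25, 75])
        assert q1 - 1e-9 <= fit.breakpoint <= q3 + 1e-9

    def test_too_few_points_per_side(self):
        pma = np.array([30.0, 44, 45, 46, 47, 48, 49, 50])  # one point pre-window
        with pytest.raises(ValueError):
            fit_biphasic(pma, np.arange(8.0), search_lo=37.0, search_hi=39.0)

    def test_discontinuous_variant_fits_jump(self):
        pma = np.linspace(30, 46, 60)
        y = np.where(pma < 38.0, 1.0, 5.0)  # pure level shift
        fit = fit_biphasic(pma, y, search_lo=35.0, search_hi=42.0,
                           continuous=False)
        assert fit.preferred == "biphasic"
        assert fit.breakpoint == pytest.approx(38.0, abs=0.1 + 1e-9)

    def test_selection_type_one_error_bounded(self):
        """Under a true single line, the extra flexibility of the broken line
        wins the AICc comparison in fewer than 30% of simulated nulls."""
        rng = np.random.default_rng(42)
        chosen = 0
        n_sim = 300
        for _ in range(n_sim):
            pma = rng.uniform(25, 47, 99)
            y = 0.01 * pma + rng.normal(0, 0.03, 99)
            fit = fit_biphasic(pma, y)
            chosen += fit.preferred == "biphasic"
        assert chosen / n_sim < 0.30


class TestFdrAdjust:
    def test_textbook_example_all_tied(self):
        p_adj, sig = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(p_adj, 0.04)
        assert sig.all()

    def test_single_p_identity(self):
        p_adj, sig = fdr_adjust(np.array([0.04]))
        assert p_adj[0] == pytest.approx(0.04)
        assert sig[0]

    def test_all_ones_nothing_significant(self):
        _, sig = fdr_adjust(np.ones(10))
        assert not sig.any()

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            p_adj, _ = fdr_adjust(p)
            assert np.array_equal(p_adj, bh_oracle(p))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            p_adj, flags = fdr_adjust(p)
            reject, p_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.allclose(p_adj, p_sm, atol=1e-12)
            assert np.array_equal(flags, reject)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.2]))


def _coupled_cohort(seed=0, linear=False):
    """ODI and curvature share the same latent PMA trend with no coupling
    beyond age (linear=True makes the shared trend a straight line, so a
    linear age control removes it completely)."""
    post = 0.012 if linear else 0.0
    traj = {
        "ODI": MetricTrajectory(0.45, 0.012, post, 0.01),
        "curvature": MetricTrajectory(0.35, 0.012, post, 0.01),
    }
    return simulate_cohort(SyntheticCohortSpec(trajectories=traj, n_regions=2,
                                               seed=seed))


class TestMicroMacro:
    def test_shared_trend_gives_strong_rho(self):
        t = _coupled_cohort()
        out = micro_macro_association(t, "ODI", "curvature", window="pre38",
                                      control_pma=False)
        assert out["cortex"].rho > 0.5

    def test_pma_control_removes_shared_trend(self):
        """Controlling for age, two metrics coupled only through age
        decorrelate: across seeds the null is rejected at roughly alpha."""
        rejections = 0
        n = 25
        for seed in range(n):
            t = _coupled_cohort(seed, linear=True)
            out = micro_macro_association(t, "ODI", "curvature", window="full",
                                          control_pma=True)
            rejections += out["cortex"].p <= 0.05
        assert rejections / n <= 0.2

    def test_constant_macro_rejected(self):
        t = _coupled_cohort()
        t["curvature__cortex"] = 1.0
        with pytest.raises(ValueError):
            micro_macro_association(t, "ODI", "curvature", window="full",
                                    control_pma=False, regions=["cortex"])


class TestRunCohortAnalysis:
    @pytest.fixture(scope="class")
    def results(self):
        t = simulate_cohort(SyntheticCohortSpec(n_regions=2, seed=4))
        return run_cohort_analysis(t, StatsConfig(regions=("r00", "r01")))

    def test_tidy_tables_complete(self, results):
        tr = results.trajectories
        assert {"region", "metric", "window", "rho", "p", "p_fdr", "significant"} <= set(tr.columns)
        assert set(tr["window"]) == {"full", "pre38", "post38"}
        assert "cortex" in set(tr["region"])

    def test_fdr_within_contrast(self, results):
        tr = results.trajectories
        grp = tr[(tr.region != "cortex") & (tr.metric == "ODI") & (tr.window == "full")]
        assert np.allclose(np.sort(grp["p_fdr"]), np.sort(bh_oracle(grp["p"].to_numpy())))

    def test_biphasic_table_has_model_choice(self, results):
        bi = results.biphasic
        assert set(bi["preferred"]) <= {"biphasic", "monophasic"}
        assert (bi["breakpoint"] >= 25).all() and (bi["breakpoint"] <= 47).all()

    def test_missing_region_column_skipped(self):
        t = simulate_cohort(SyntheticCohortSpec(n_regions=1, seed=4))
        t["FA__r00"] = 1.0  # constant column: correlation undefined, skipped
        res = run_cohort_analysis(t, StatsConfig())
        tr = res.trajectories
        assert not ((tr.region == "r00") & (tr.metric == "FA")).any()
        assert ((tr.region == "r00") & (tr.metric == "ODI")).any()

    def test_manifest_records_run(self, results):
        m = results.manifest
        assert m["n_subjects"] == 99
        assert m["split_week"] == 38.0
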