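import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from veogblink._reml import SingularFitError, fit_reml
from veogblink.stats_models import (
    fit_random_intercept,
    fit_type_interaction,
    mediation,
    pearson_matrix,
    welch_t,
)

CONDITIONS = ["negative1", "negative2", "negative3", "positive1", "positive2", "neutral"]


def simulate_lmm(rng, n_subjects=46, n_obs=18, beta1=0.0, u_sd=1.0, e_sd=1.0,
                 slopes_by_type=None, type_offsets=None):
    stai = rng.normal(40.0, 10.0, n_subjects)
    u = rng.normal(0.0, u_sd, n_subjects)
    rows = []
    for j in range(n_subjects):
        for i in range(n_obs):
            cond = CONDITIONS[i % len(CONDITIONS)]
            slope = beta1 if slopes_by_type is None else slopes_by_type[cond]
            offset = 0.0 if type_offsets is None else type_offsets[cond]
            rows.append(
                {
                    "subject": j,
                    "stai_s": stai[j],
                    "condition": cond,
                    "y": 1.0 + slope * stai[j] + offset + u[j] + rng.normal(0, e_sd),
                }
            )
    return pd.DataFrame(rows)


class TestPearsonMatrix:
    def test_perfect_linearity(self):
        x = np.arange(30.0)
        table = pd.DataFrame({"x": x, "y": 2 * x + 1})
        corr = pearson_matrix(table)
        assert corr.r.loc["x", "y"] == pytest.approx(1.0)
        assert corr.p.loc["x", "y"] < 1e-12
        assert corr.df.loc["x", "y"] == 28

    def test_independent_null(self, rng):
        table = pd.DataFrame(
            {"x": rng.normal(size=10_000), "y": rng.normal(size=10_000)}
        )
        assert abs(pearson_matrix(table).r.loc["x", "y"]) < 0.05

    def test_matches_direct_formula_fuzz(self, rng):
        # independent oracle: covariance / (sd_x * sd_y) plus the t transform
        for _ in range(25):
            n = int(rng.integers(5, 40))
            table = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
            corr = pearson_matrix(table)
            for i, u in enumerate("abcd"):
                for v in "abcd"[i + 1 :]:
                    x, y = table[u].to_numpy(), table[v].to_numpy()
                    r = (
                        ((x - x.mean()) * (y - y.mean())).sum()
                        / math.sqrt(((x - x.mean()) ** 2).sum())
                        / math.sqrt(((y - y.mean()) ** 2).sum())
                    )
                    t = r * math.sqrt((n - 2) / (1 - r * r))
                    p = 2 * sstats.t.sf(abs(t), n - 2)
                    assert corr.r.loc[u, v] == pytest.approx(r, abs=1e-10)
                    assert corr.p.loc[u, v] == pytest.approx(p, abs=1e-10)

    def test_symmetry_and_diagonal(self, rng):
        table = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("xyz"))
        corr = pearson_matrix(table)
        np.testing.assert_allclose(corr.r.values, corr.r.values.T)
        np.testing.assert_allclose(np.diag(corr.r.values), 1.0)

    def test_zero_variance_flagged_not_raised(self):
        table = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0, 4.0]})
        corr = pearson_matrix(table)
        assert math.isnan(corr.r.loc["x", "y"])

    def test_pairwise_complete(self):
        table = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0, np.nan], "y": [2.0, 4.0, 6.0, 8.0, 10.0]}
        )
        corr = pearson_matrix(table)
        assert corr.df.loc["x", "y"] == 2

    def test_long_format_upper_triangle(self, rng):
        table = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("xyz"))
        frame = pearson_matrix(table).to_frame()
        assert len(frame) == 3
        assert set(frame.columns) == {"var_a", "var_b", "r", "p", "df"}


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, df, p = welch_t(a, b)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_oracle = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_oracle = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert df == pytest.approx(df_oracle, abs=1e-10)
        assert p == pytest.approx(2 * sstats.t.sf(abs(t_oracle), df_oracle), abs=1e-10)

    def test_converges_to_pooled_t(self, rng):
        a = rng.normal(0.0, 1.0, 2000)
        b = rng.normal(0.2, 1.0, 2000)
        t_w, _, _ = welch_t(a, b)
        t_p = sstats.ttest_ind(a, b, equal_var=True).statistic
        assert t_w == pytest.approx(t_p, abs=1e-3)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestMediation:
    def test_sobel_plugin_arithmetic(self):
        # z = ab / sqrt(a^2 se_b^2 + b^2 se_a^2) with a=b=1, se=0.1 each
        from veogblink.stats_models import _sobel

        z, p = _sobel(1.0, 0.1, 1.0, 0.1)
        assert z == pytest.approx(1.0 / math.sqrt(0.02), abs=1e-10)
        assert p == pytest.approx(2 * sstats.norm.sf(z), abs=1e-12)

    def test_full_mediation_large_n(self, rng):
        n = 5000
        x = rng.normal(size=n)
        m = 0.7 * x + rng.normal(size=n) * math.sqrt(1 - 0.49)
        y = 0.6 * m + rng.normal(size=n) * math.sqrt(1 - 0.36)
        res = mediation(x, m, y, n_boot=500, seed=1)
        assert res.sobel_p < 1e-6
        assert res.c_prime_p > 0.05
        assert res.a_path == pytest.approx(0.7, abs=0.05)
        assert res.b_path == pytest.approx(0.6, abs=0.05)
        assert res.indirect == pytest.approx(res.a_path * res.b_path, abs=1e-12)
        assert res.ci_low < res.indirect < res.ci_high

    def test_bootstrap_is_seeded(self, rng):
        n = 200
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.5 * m + rng.normal(size=n)
        r1 = mediation(x, m, y, n_boot=200, seed=7)
        r2 = mediation(x, m, y, n_boot=200, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_sobel_and_bootstrap_agree_in_significance(self, rng):
        n = 1000
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.5 * m + rng.normal(size=n)
        res = mediation(x, m, y, n_boot=1000, seed=3)
        assert res.sobel_p < 0.05
        assert res.ci_low > 0  # CI excludes zero: same conclusion

    def test_collinear_error(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError, match="collinear"):
            mediation(x, 2 * x, x + 1)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            mediation([1.0] * 5, [1.0] * 5, [1.0] * 5)


class TestRandomInterceptModel:
    def test_matches_statsmodels_reml(self, rng):
        statsmodels = pytest.importorskip("statsmodels.formula.api")
        data = simulate_lmm(rng, n_subjects=30, beta1=0.05)
        fit = fit_random_intercept(data, "y", "stai_s")
        oracle = statsmodels.mixedlm(
            "y ~ stai_s", data, groups=data["subject"]
        ).fit(reml=True)
        assert fit.params["stai_s"] == pytest.approx(oracle.params["stai_s"], abs=1e-5)
        assert fit.params["intercept"] == pytest.approx(oracle.params["Intercept"], abs=1e-4)
        assert fit.u0_var == pytest.approx(float(oracle.cov_re.iloc[0, 0]), rel=1e-2)
        assert fit.resid_var == pytest.approx(float(oracle.scale), rel=1e-2)

    def test_between_subject_df_is_44_at_design_size(self, rng):
        data = simulate_lmm(rng, n_subjects=46, n_obs=18, beta1=0.05)
        fit = fit_random_intercept(data, "y", "stai_s")
        assert fit.f_tests["stai_s"].df_den == pytest.approx(44.0, abs=0.5)

    def test_zero_cluster_variance_matches_pooled_ols(self, rng):
        data = simulate_lmm(rng, n_subjects=30, beta1=0.1, u_sd=0.0)
        fit = fit_random_intercept(data, "y", "stai_s")
        slope = np.polyfit(data["stai_s"], data["y"], 1)[0]
        assert fit.params["stai_s"] == pytest.approx(slope, abs=1e-3)

    def test_r2_marginal_range_and_direction(self, rng):
        null = simulate_lmm(rng, beta1=0.0)
        strong = simulate_lmm(rng, beta1=0.3)
        r2_null = fit_random_intercept(null, "y", "stai_s").r2_marginal
        r2_strong = fit_random_intercept(strong, "y", "stai_s").r2_marginal
        assert 0.0 <= r2_null <= 1.0 and 0.0 <= r2_strong <= 1.0
        assert r2_strong > r2_null

    def test_type_one_error_small_monte_carlo(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 200
        for _ in range(reps):
            data = simulate_lmm(rng, beta1=0.0)
            fit = fit_random_intercept(data, "y", "stai_s")
            rejections += fit.f_tests["stai_s"].pvalue < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_singular_designs_rejected(self, rng):
        one_subject = pd.DataFrame(
            {"subject": [0] * 10, "stai_s": range(10), "y": range(10)}
        )
        with pytest.raises(SingularFitError):
            fit_random_intercept(one_subject, "y", "stai_s")

    def test_fit_reml_input_validation(self):
        with pytest.raises(SingularFitError):
            fit_reml(np.zeros(4), np.ones((4, 2)), np.array([0, 0, 1, 1]))


class TestTypeInteractionModel:
    def test_null_interaction_rarely_significant(self):
        rng = np.random.default_rng(7)
        reps, hits = 60, 0
        for _ in range(reps):
            data = simulate_lmm(rng, beta1=0.03)
            fit = fit_type_interaction(data, "y", "stai_s")
            hits += fit.f_tests["condition:stai_s"].pvalue < 0.05
        assert hits / reps <= 0.15

    def test_type_offset_detected(self):
        rng = np.random.default_rng(8)
        offsets = {c: (0.8 if c == "neutral" else 0.0) for c in CONDITIONS}
        hits = 0
        for _ in range(20):
            data = simulate_lmm(rng, beta1=0.03, type_offsets=offsets)
            fit = fit_type_interaction(data, "y", "stai_s")
            hits += fit.f_tests["condition"].pvalue < 0.05
        assert hits >= 18

    def test_interaction_detected_when_slopes_differ(self):
        rng = np.random.default_rng(9)
        slopes = {c: (0.10 if c.startswith("neg") else 0.0) for c in CONDITIONS}
        data = simulate_lmm(rng, slopes_by_type=slopes)
        fit = fit_type_interaction(data, "y", "stai_s")
        assert fit.f_tests["condition:stai_s"].pvalue < 0.05

    def test_single_level_reduces_to_random_intercept(self, rng):
        data = simulate_lmm(rng, beta1=0.05)
        neutral = data[data["condition"] == "neutral"]
        a = fit_type_interaction(neutral, "y", "stai_s")
        b = fit_random_intercept(neutral, "y", "stai_s")
        assert a.params["stai_s"] == pytest.approx(b.params["stai_s"], abs=1e-12)

    def test_empty_declared_level_is_design_error(self, rng):
        data = simulate_lmm(rng)
        data = data[data["condition"] != "neutral"]
        with pytest.raises(ValueError, match="neutral"):
            fit_type_interaction(data, "y", "stai_s", levels=CONDITIONS)

    def test_interaction_df_structure(self, rng):
        data = simulate_lmm(rng, beta1=0.05)
        fit = fit_type_interaction(data, "y", "stai_s")
        assert fit.f_tests["condition"].df_num == 5.0
        assert fit.f_tests["condition:stai_s"].df_num == 5.0
        # within-subject terms get large denominator df (order N - G)
        assert fit.f_tests["condition"].df_den > 500
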