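import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from absp.robust_stats import (
    adjust_pvalues,
    bootstrap_posthoc,
    boruta_select,
    counts_to_coded_samples,
    huber_regression,
    kruskal_wallis,
    mixed_anova_2way,
    pearson_chi2,
    robust_cohens_d,
    trimmed_anova_1way,
    wald_test,
    yuen_t,
)

# printed contingency tables of the cohort's clinical comparisons
RBD_TABLE = [[24, 15], [6, 18]]
HYPOSMIA_TABLE = [[20, 19], [7, 17]]
SEX_COUNTS = [(17, 15), (17, 22), (14, 10)]


class TestCategorical:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (RBD_TABLE, 7.95),
            (HYPOSMIA_TABLE, 2.97),
            ([[2, 37], [4, 20]], 2.30),
            ([[22, 17], [16, 8]], 0.65),
            ([[18, 20, 1], [14, 9, 1]], 1.17),
        ],
    )
    def test_chi2_worked_examples(self, table, expected):
        assert pearson_chi2(table).statistic == pytest.approx(expected, abs=0.005)

    def test_equal_proportions_give_zero(self):
        assert pearson_chi2([[10, 20], [5, 10]]).statistic == pytest.approx(0.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [3, 4]])

    def test_kruskal_wallis_worked_example_sex(self):
        h = kruskal_wallis(counts_to_coded_samples(SEX_COUNTS)).statistic
        assert h == pytest.approx(1.41, abs=0.005)

    def test_kruskal_wallis_identical_samples(self):
        res = kruskal_wallis([np.ones(5), np.ones(6), np.ones(7)])
        assert res.statistic == 0.0
        assert "all_identical" in res.flags

    def test_binary_kw_equals_scaled_chi2(self, rng):
        """Tie-corrected H on binary data is ((N-1)/N) x Pearson chi2."""
        for _ in range(100):
            counts = rng.integers(1, 40, size=(3, 2))
            h = kruskal_wallis(
                counts_to_coded_samples([tuple(r) for r in counts])
            ).statistic
            chi = pearson_chi2(counts).statistic
            n = counts.sum()
            assert h == pytest.approx((n - 1) / n * chi, abs=1e-9)


class TestTrimmedAnova:
    def test_identical_group_populations_give_zero_f(self):
        s = [np.arange(20.0)] * 3
        assert trimmed_anova_1way(s).statistic == pytest.approx(0.0, abs=1e-12)

    def test_gamma_zero_equals_welch(self, rng):
        import pingouin as pg

        samples = [rng.normal(0, 1, 25), rng.normal(0.4, 2, 31), rng.normal(1, 1.5, 19)]
        res = trimmed_anova_1way(samples, trim=0.0)
        df = pd.DataFrame(
            {
                "y": np.concatenate(samples),
                "g": np.repeat([0, 1, 2], [len(s) for s in samples]),
            }
        )
        welch = pg.welch_anova(data=df, dv="y", between="g")
        assert res.statistic == pytest.approx(float(welch["F"][0]), abs=1e-8)
        assert res.df[1] == pytest.approx(float(welch["ddof2"][0]), abs=1e-8)
        assert res.p == pytest.approx(float(welch["p_unc"][0]), abs=1e-8)

    def test_group_relabeling_invariance(self, rng):
        samples = [rng.normal(0, 1, 20), rng.normal(1, 1, 25), rng.normal(2, 2, 30)]
        f1 = trimmed_anova_1way(samples).statistic
        f2 = trimmed_anova_1way(samples[::-1]).statistic
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            trimmed_anova_1way([np.ones(3), np.arange(20.0)])

    def test_yuen_detects_shift(self, rng):
        res = yuen_t(rng.normal(3, 1, 40), rng.normal(0, 1, 40))
        assert res.p < 1e-6


class TestMixedAnova:
    @staticmethod
    def _frame(rng, n=30, group_shift=0.0, within_shift=0.0, interaction=0.0):
        rows = []
        for g, gname in enumerate(("HC", "PD")):
            for i in range(n):
                base = rng.normal(g * group_shift, 1)
                for w, wname in enumerate(("SNc", "SNr")):
                    rows.append(
                        {
                            "subject_id": f"{gname}{i}",
                            "group": gname,
                            "within": wname,
                            "value": base
                            + w * within_shift
                            + g * w * interaction
                            + rng.normal(0, 0.3),
                        }
                    )
        return pd.DataFrame(rows)

    def test_zero_within_difference_gives_zero_f(self, rng):
        rows = []
        for gname in ("a", "b"):
            for i in range(25):
                v = rng.normal(0, 1)
                for w in ("L", "R"):
                    rows.append({"subject_id": f"{gname}{i}", "group": gname,
                                 "within": w, "value": v})
        out = mixed_anova_2way(pd.DataFrame(rows))
        assert out["within"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_region_offset_detected_with_power(self, rng):
        hits = 0
        for _ in range(10):
            out = mixed_anova_2way(self._frame(rng, within_shift=1.0))
            hits += out["within"].p < 0.05
            assert out["within"].statistic > out["interaction"].statistic
        assert hits >= 9

    def test_permuting_group_labels_kills_group_effect(self, rng):
        rej = 0
        reps = 100
        for _ in range(reps):
            df = self._frame(rng, n=20, group_shift=1.0)
            perm = df.copy()
            mapping = {
                s: rng.permutation(["HC", "PD"])[0]
                for s in df["subject_id"].unique()
            }
            perm["group"] = perm["subject_id"].map(mapping)
            out = mixed_anova_2way(perm)
            rej += out["group"].p < 0.05
        assert sps.binomtest(rej, reps, 0.05).pvalue > 0.005

    def test_incomplete_subjects_dropped(self, rng):
        df = self._frame(rng)
        df = df.drop(df.index[0])  # one subject loses a within level
        out = mixed_anova_2way(df)
        assert out["group"].extra["n_dropped"] == 1


class TestBootstrapPosthocAndEffectSize:
    def test_identical_samples_high_p_ci_covers_zero(self, rng):
        x = rng.normal(0, 1, 50)
        res = bootstrap_posthoc(x, x.copy(), seed=3)
        assert res.p > 0.5
        assert res.ci[0] <= 0 <= res.ci[1]

    def test_three_sd_shift_detected(self, rng):
        detected = 0
        for seed in range(10):
            x = rng.normal(3, 1, 40)
            y = rng.normal(0, 1, 40)
            detected += bootstrap_posthoc(x, y, seed=seed).p < 0.01
        assert detected == 10

    def test_fixed_seed_is_deterministic(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        a = bootstrap_posthoc(x, y, seed=11)
        b = bootstrap_posthoc(x, y, seed=11)
        assert a.p == b.p and a.ci == b.ci

    def test_small_b_warns_via_flag(self, rng):
        res = bootstrap_posthoc(rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                                n_boot=50, seed=0)
        assert "few_bootstrap" in res.flags

    def test_robust_d_zero_and_antisymmetric(self, rng):
        x = rng.normal(0, 1, 50)
        assert robust_cohens_d(x, x.copy()) == pytest.approx(0.0)
        y = rng.normal(1, 1, 50)
        assert robust_cohens_d(x, y) == pytest.approx(-robust_cohens_d(y, x))

    def test_robust_d_consistent_for_normal_shift(self, rng):
        x = rng.normal(1.2, 1, 100_000)
        y = rng.normal(0.0, 1, 100_000)
        assert robust_cohens_d(x, y) == pytest.approx(1.20, abs=0.02)

    def test_small_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            robust_cohens_d(rng.normal(0, 1, 5), rng.normal(0, 1, 50))


class TestPAdjust:
    def test_bonferroni_definition(self):
        out = adjust_pvalues(np.array([0.01] * 5), "bonferroni")
        np.testing.assert_allclose(out, 0.05)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.random(20)
        for method in ("bonferroni", "hochberg"):
            adj = adjust_pvalues(p, method)
            assert (adj >= p - 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()

    @staticmethod
    def _hochberg_oracle(p):
        """Direct enumeration of the step-up definition: the adjusted value
        of the k-th smallest p is min over j >= k of (m - j) * p_(j)."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        sorted_p = p[order]
        adj_sorted = np.empty(m)
        for k in range(m):
            adj_sorted[k] = min(
                min((m - j) * sorted_p[j] for j in range(k, m)), 1.0
            )
        out = np.empty(m)
        out[order] = adj_sorted
        return out

    def test_hochberg_matches_stepup_enumeration_on_four_hypotheses(self, rng):
        for _ in range(30):
            p = np.round(rng.random(4), 3)
            adj = adjust_pvalues(p, "hochberg")
            np.testing.assert_allclose(adj, self._hochberg_oracle(p), atol=1e-9)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues(np.array([0.5, 1.2]), "bonferroni")


class TestHuberRegression:
    def test_noiseless_linear_data_exact(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 100), "b": rng.normal(0, 1, 100)})
        y = 1.0 + 2.0 * X["a"] - 3.0 * X["b"]
        fit = huber_regression(y, X)
        assert fit.params["a"] == pytest.approx(2.0, abs=1e-6)
        assert fit.params["b"] == pytest.approx(-3.0, abs=1e-6)

    def test_outlier_resistance_vs_ols(self, rng):
        """10% gross y-outliers: Huber slope error stays near the clean-data
        error while OLS degrades badly."""
        import statsmodels.api as sm

        huber_errs, clean_errs, ols_errs = [], [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = pd.DataFrame({"x": r.normal(0, 1, 200)})
            y = 2.0 * X["x"].to_numpy() + r.normal(0, 0.5, 200)
            clean_errs.append(abs(huber_regression(y, X).params["x"] - 2.0))
            y_cont = y.copy()
            y_cont[:20] += 40.0 * (1 + r.random(20))  # gross one-sided outliers
            huber_errs.append(abs(huber_regression(y_cont, X).params["x"] - 2.0))
            ols = sm.OLS(y_cont, sm.add_constant(X.to_numpy())).fit()
            ols_errs.append(abs(ols.params[1] - 2.0))
        # robust slope barely degrades; least squares degrades far more
        assert np.median(huber_errs) < 3 * max(np.median(clean_errs), 0.02)
        assert np.median(ols_errs) > 3 * np.median(huber_errs)

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 50)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="b"):
            huber_regression(rng.normal(0, 1, 50), X)

    def test_wald_null_block_rejection_near_alpha(self):
        rej = 0
        reps = 200
        for seed in range(reps):
            r = np.random.default_rng(seed)
            X = pd.DataFrame({"a": r.normal(0, 1, 120), "b": r.normal(0, 1, 120)})
            y = 1.0 + 0.8 * X["a"].to_numpy() + r.normal(0, 1, 120)  # b is null
            fit = huber_regression(y, X)
            rej += fit.wald["b"].p < 0.05
        assert sps.binomtest(rej, reps, 0.05).pvalue > 0.005


class TestBorutaSelection:
    def test_planted_signal_recovered_over_algorithm_seeds(self):
        rng = np.random.default_rng(100)
        X = pd.DataFrame(
            rng.normal(0, 1, (500, 5)), columns=[f"x{i}" for i in range(5)]
        )
        y = 3 * X["x0"] + rng.normal(0, 1, 500)
        exact = 0
        for seed in range(5):
            st = boruta_select(y, X, seed=seed)
            assert st["x0"] == "confirmed"
            exact += all(st[f"x{i}"] == "rejected" for i in range(1, 5))
        assert exact >= 4

    def test_null_confirmation_rate_bounded(self):
        confirmed = 0
        total = 0
        for seed in range(4):
            rng = np.random.default_rng(300 + seed)
            X = pd.DataFrame(
                rng.normal(0, 1, (400, 5)), columns=[f"x{i}" for i in range(5)]
            )
            y = rng.normal(0, 1, 400)
            st = boruta_select(y, X, seed=seed)
            confirmed += sum(v == "confirmed" for v in st.values())
            total += len(st)
        # a 5% per-feature false-confirmation rate admits up to ~3/20
        assert sps.binomtest(confirmed, total, 0.05).pvalue > 0.005

    def test_duplicated_feature_treated_symmetrically(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"a": rng.normal(0, 1, 400)})
        X["b"] = X["a"]
        X["c"] = rng.normal(0, 1, 400)
        y = 2 * X["a"] + rng.normal(0, 1, 400)
        st = boruta_select(y, X, seed=1)
        assert {st["a"], st["b"]} <= {"confirmed", "tentative"}

    def test_constant_features_rejected(self, rng):
        X = pd.DataFrame({"a": np.ones(100), "b": rng.normal(0, 1, 100)})
        st = boruta_select(rng.normal(0, 1, 100), X, seed=0)
        assert st["a"] == "rejected"


class TestWald:
    def test_wald_detects_nonzero_block(self, rng):
        params = pd.Series({"a": 2.0, "b": 0.0})
        cov = pd.DataFrame(np.eye(2) * 0.01, index=["a", "b"], columns=["a", "b"])
        assert wald_test(params, cov, ["a"]).p < 1e-6
        assert wald_test(params, cov, ["b"]).p == pytest.approx(1.0)
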