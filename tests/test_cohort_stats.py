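"""Covariate-adjusted correlations, AIC model comparison, and the
group-pair hypothesis battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tridem.cohort_stats import (
    DEFAULT_HYPOTHESES,
    GROUP_PAIR_DEFINITIONS,
    compare_models_aic,
    comparison_results_frame,
    define_group_pairs,
    group_pair_tests,
    partial_correlation,
    residualize,
)
from tridem.trichotomy import TrichotomyLabel as L


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        y = rng.standard_normal(50) + 3.0
        r = residualize(y)
        np.testing.assert_allclose(r, y - y.mean(), atol=1e-12)

    def test_exact_linear_relation_gives_zero_residuals(self, rng):
        x = rng.standard_normal(40)
        cov = pd.DataFrame({"x": x})
        r = residualize(2.0 * x - 1.0, cov)
        assert np.max(np.abs(r)) < 1e-10

    def test_matches_normal_equations_hand_solution(self):
        # n = 6 bivariate case solved via the closed-form slope/intercept
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1, 5.8])
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        expected = y - (intercept + slope * x)
        np.testing.assert_allclose(
            residualize(y, pd.DataFrame({"x": x})), expected, atol=1e-12
        )

    def test_residuals_orthogonal_to_design(self, rng):
        cov = pd.DataFrame(
            {
                "age": rng.normal(70, 7, 80),
                "sex": rng.choice(["male", "female"], 80),
                "education": rng.normal(16, 2, 80),
            }
        )
        y = rng.standard_normal(80) + 0.1 * cov["age"]
        r = residualize(y, cov)
        assert abs(r.mean()) < 1e-10
        assert abs(np.dot(r, cov["age"])) < 1e-7
        assert abs(np.dot(r, (cov["sex"] == "male").astype(float))) < 1e-8

    def test_collinear_columns_dropped_with_warning(self, rng):
        x = rng.standard_normal(30)
        cov = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.warns(RuntimeWarning, match="collinear"):
            r = residualize(rng.standard_normal(30), cov)
        assert np.isfinite(r).all()


class TestPartialCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(60)
        assert partial_correlation(x, x.copy()).r_partial == pytest.approx(1.0)

    def test_orthogonalized_pair_is_zero(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        y = y - (np.dot(y - y.mean(), x - x.mean()) /
                 np.sum((x - x.mean()) ** 2)) * (x - x.mean())
        assert abs(partial_correlation(x, y).r_partial) < 1e-10

    def test_no_covariates_equals_pearson(self, rng):
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        res = partial_correlation(x, y)
        pearson = stats.pearsonr(x, y)
        assert res.r_partial == pytest.approx(pearson.statistic, abs=1e-12)
        assert res.p == pytest.approx(pearson.pvalue, rel=1e-6)

    def test_known_population_partial_correlation(self):
        # x and y share a confounder z plus a direct link of partial r = 0.3
        rng = np.random.default_rng(78)
        n = 5000
        z = rng.standard_normal(n)
        rho = 0.3
        ex = rng.standard_normal(n)
        ey = rho * ex + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        x = z + ex
        y = z + ey
        res = partial_correlation(x, y, pd.DataFrame({"z": z}))
        assert res.r_partial == pytest.approx(0.30, abs=0.03)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(80)
        y = 0.4 * x + rng.standard_normal(80)
        cov = pd.DataFrame({"c": rng.standard_normal(80)})
        base = partial_correlation(x, y, cov).r_partial
        scaled = partial_correlation(
            5.0 * x - 2.0, -0.1 * y + 7.0, cov * 100 + 3
        ).r_partial
        assert abs(abs(scaled) - abs(base)) < 1e-12

    def test_matches_residual_pearson_oracle(self, rng):
        """Dual route: the reported r equals the Pearson correlation of
        independently computed OLS residuals."""
        for _ in range(20):
            n = 60
            cov = pd.DataFrame(
                {"a": rng.standard_normal(n), "b": rng.standard_normal(n)}
            )
            x = rng.standard_normal(n) + cov["a"]
            y = rng.standard_normal(n) - cov["b"]
            res = partial_correlation(x, y, cov)
            X = np.column_stack([np.ones(n), cov["a"], cov["b"]])
            hat = X @ np.linalg.solve(X.T @ X, X.T)
            rx = x - hat @ x
            ry = y - hat @ y
            oracle = stats.pearsonr(rx, ry).statistic
            assert res.r_partial == pytest.approx(oracle, abs=1e-10)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            partial_correlation(np.ones(30), rng.standard_normal(30))


class TestCompareModelsAic:
    def test_nested_model_r2_never_decreases(self, rng):
        n = 100
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        y = a + rng.standard_normal(n)
        out = compare_models_aic(
            y, {"A": pd.DataFrame({"a": a}), "AB": pd.DataFrame({"a": a, "b": b})}
        )
        assert out.loc["AB", "r_squared"] >= out.loc["A", "r_squared"]

    def test_equal_rss_models_differ_by_two(self):
        # duplicate predictor: identical fit, one extra parameter -> ΔAIC = 2
        rng = np.random.default_rng(4)
        n = 50
        a = rng.standard_normal(n)
        y = a + rng.standard_normal(n)
        out = compare_models_aic(
            y,
            {"A": pd.DataFrame({"a": a}), "AA": pd.DataFrame({"a": a, "a2": a})},
        )
        assert out.loc["AA", "aic"] - out.loc["A", "aic"] == pytest.approx(2.0, abs=1e-6)

    def test_aic_prefers_true_model_at_theoretical_rate(self):
        """Adding a spurious predictor is selected only when its chi-squared
        deviance gain exceeds the 2-point penalty, which happens with
        asymptotic probability P(chi2_1 > 2) ~ 0.157; the true model should
        therefore win in roughly 84% of replicates."""
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            n = 500
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            y = 0.8 * a + rng.standard_normal(n)
            out = compare_models_aic(
                y,
                {"A": pd.DataFrame({"a": a}), "AB": pd.DataFrame({"a": a, "b": b})},
            )
            wins += int(out.index[0] == "A")
        assert 0.70 * n_rep <= wins <= 0.95 * n_rep

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            compare_models_aic(
                np.arange(4.0), {"m": pd.DataFrame({"a": np.arange(4.0),
                                                    "b": np.arange(4.0) ** 2})}
            )


class TestGroupPairs:
    @pytest.fixture()
    def labels(self, rng):
        return rng.choice([l.value for l in L], size=400).tolist()

    def test_nine_pairs_defined(self, labels):
        pairs = define_group_pairs(labels)
        assert sorted(pairs) == [f"G{i}" for i in range(1, 10)]

    def test_g1_partitions_cohort(self, labels):
        idx1, idx2 = define_group_pairs(labels)["G1"]
        assert len(idx1) + len(idx2) == len(labels)
        assert set(idx1).isdisjoint(idx2)

    def test_g4_membership(self):
        labels = [L.bVD, L.bMX, L.bCN_VD, L.bCN_MX, L.bCN, L.bAD]
        idx1, idx2 = define_group_pairs(labels)["G4"]
        assert idx1.tolist() == [0, 1]
        assert idx2.tolist() == [2, 3]

    def test_all_pairs_disjoint(self, labels):
        for idx1, idx2 in define_group_pairs(labels).values():
            assert set(idx1).isdisjoint(idx2)

    def test_pair_unions_match_definitions(self, labels):
        arr = np.asarray(labels, dtype=object)
        pairs = define_group_pairs(labels)
        for pid, (_d, u1, u2) in GROUP_PAIR_DEFINITIONS.items():
            idx1, _ = pairs[pid]
            assert set(arr[idx1]) <= {l.value for l in u1}


class TestGroupPairTests:
    @pytest.fixture()
    def cohort_with_labels(self, default_cohort):
        from tridem.cli_io import PipelineConfig, run_pipeline

        cohort, _ = default_cohort
        res = run_pipeline(PipelineConfig(), cohort)
        mask = res["scores"]["label"].notna().to_numpy()
        return (
            cohort.loc[mask].reset_index(drop=True),
            res["scores"].loc[mask, "label"].tolist(),
        )

    def test_battery_size_and_correction_factor(self, cohort_with_labels):
        data, labels = cohort_with_labels
        results = group_pair_tests(data, labels)
        assert len(results) == 81
        testable = [r for r in results if r.testable]
        for r in testable:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 81))

    def test_correction_cap(self, cohort_with_labels):
        data, labels = cohort_with_labels
        results = group_pair_tests(data, labels)
        r = next(r for r in results if r.testable and r.p_raw > 0.05)
        assert r.p_adjusted == 1.0

    def test_chi2_statistic_matches_hand_computation(self):
        # 2x2 table {{10,20},{20,10}}: chi2 = sum (O-E)^2/E with E = 15
        table = np.array([[10, 20], [20, 10]], dtype=float)
        expected = ((table - 15.0) ** 2 / 15.0).sum()
        stat, _, _, _ = stats.chi2_contingency(table, correction=False)
        data = pd.DataFrame(
            {"sex": ["male"] * 10 + ["female"] * 20 + ["male"] * 20 + ["female"] * 10}
        )
        labels = [L.bAD] * 30 + [L.bCL] * 30
        results = group_pair_tests(data, labels, hypotheses=DEFAULT_HYPOTHESES[:1])
        g8 = next(r for r in results if r.pair_id == "G8")
        assert g8.statistic == pytest.approx(expected)
        assert stat == pytest.approx(expected)

    def test_zero_cell_reported_untestable(self):
        data = pd.DataFrame({"sex": ["male"] * 40})
        labels = [L.bAD] * 20 + [L.bCL] * 20
        with pytest.warns(RuntimeWarning, match="zero cell"):
            results = group_pair_tests(data, labels, hypotheses=DEFAULT_HYPOTHESES[:1])
        g8 = next(r for r in results if r.pair_id == "G8")
        assert not g8.testable
        assert np.isnan(g8.p_raw)

    def test_familywise_error_under_null(self):
        """With labels independent of every variable, the Bonferroni-corrected
        battery should produce any significance in at most ~5% of replicates."""
        n_rep = 120
        n = 160
        false_positive_runs = 0
        for seed in range(n_rep):
            rng = np.random.default_rng(20_000 + seed)
            labels = rng.choice([l.value for l in L], size=n).tolist()
            data = pd.DataFrame(
                {
                    "sex": rng.choice(["male", "female"], n),
                    "apoe4": rng.integers(0, 3, n),
                    "cdrsb": rng.integers(0, 6, n) / 2,
                    "delta_cdrsb": rng.normal(0.3, 0.5, n),
                    "hv": rng.normal(7000, 600, n),
                    "ba": rng.normal(0, 1, n),
                }
            )
            results = group_pair_tests(data, labels)
            if any(r.testable and r.p_adjusted < 0.05 for r in results):
                false_positive_runs += 1
        rate = false_positive_runs / n_rep
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_results_frame_shape(self, cohort_with_labels):
        data, labels = cohort_with_labels
        frame = comparison_results_frame(group_pair_tests(data, labels))
        assert frame.shape[0] == 81
        assert {"pair_id", "hypothesis_id", "p_adjusted"} <= set(frame.columns)
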