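"""Epoch-association statistics and report generation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scalphfo.core import (
    ICTAL_ACTIVE,
    INTERICTAL_ACTIVE,
    INTERICTAL_SEIZURE_FREE,
)
from scalphfo.stats import (
    StatsError,
    build_contingency,
    chi_square_test,
    cross_product_ratio,
    epoch_association_report,
    feature_regression_report,
    format_p,
    make_reports,
    multinomial_logit,
    ols_regression,
    table_from_counts,
    tukey_kramer_hsd,
)

PUBLISHED_COUNTS = [[23, 13, 29], [10, 53, 7], [2, 5, 21]]


def labels_from_counts(counts):
    table = table_from_counts(counts)
    cl, ep = [], []
    for i, row in enumerate(table.counts.index):
        for j, col in enumerate(table.counts.columns):
            n = int(table.counts.iloc[i, j])
            cl += [i + 1] * n
            ep += [col] * n
    return cl, ep


class TestContingency:
    def test_cross_tabulation_reproduces_counts(self):
        cl, ep = labels_from_counts(PUBLISHED_COUNTS)
        table = build_contingency(cl, ep)
        assert table.counts.to_numpy().tolist() == PUBLISHED_COUNTS

    def test_empty_inputs_rejected(self):
        with pytest.raises(StatsError):
            build_contingency([], [])

    def test_single_event(self):
        table = build_contingency([2], [ICTAL_ACTIVE])
        assert table.grand_total == 1
        assert int(table.counts.loc["Cluster 2", ICTAL_ACTIVE]) == 1


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        res = chi_square_test(table_from_counts([[10, 20, 30]] * 3))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_by_two_matches_hand_formula(self):
        obs = np.array([[10, 20], [20, 10]])
        res = chi_square_test(table_from_counts(obs))
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        exp = row * col / obs.sum()
        assert res.statistic == pytest.approx(((obs - exp) ** 2 / exp).sum())
        assert res.df == 1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 40), min_size=9, max_size=9))
    def test_matches_brute_force_on_random_tables(self, cells):
        obs = np.array(cells).reshape(3, 3)
        res = chi_square_test(table_from_counts(obs))
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        exp = row * col / obs.sum()
        assert res.statistic == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            chi_square_test(table_from_counts([[0, 0, 0], [1, 2, 3], [4, 5, 6]]))


class TestMultinomial:
    def test_saturated_fit_equals_cross_product_ratios(self):
        cl, ep = labels_from_counts(PUBLISHED_COUNTS)
        fit = multinomial_logit(ep, cl)
        table = table_from_counts(PUBLISHED_COUNTS)
        for _, r in fit.table.iterrows():
            oracle = cross_product_ratio(table, int(r["predictor"]), r["outcome"])
            assert r["odds_ratio"] == pytest.approx(oracle, rel=1e-4)

    def test_fitted_cell_probabilities_are_empirical_proportions(self):
        cl, ep = labels_from_counts(PUBLISHED_COUNTS)
        fit = multinomial_logit(ep, cl)
        table = table_from_counts(PUBLISHED_COUNTS)
        emp = table.counts.div(table.counts.sum(axis=1), axis=0)
        for i, lev in enumerate(fit.cell_probs.index):
            for col in emp.columns:
                assert fit.cell_probs.loc[lev, col] == pytest.approx(
                    emp.iloc[i][col], abs=1e-6
                )

    def test_proportional_rows_give_unit_odds_ratios(self):
        cl, ep = labels_from_counts([[10, 20, 30], [20, 40, 60], [5, 10, 15]])
        fit = multinomial_logit(ep, cl)
        assert np.allclose(fit.table["odds_ratio"], 1.0, atol=1e-4)

    def test_zero_cell_flagged_separable(self):
        cl, ep = labels_from_counts([[10, 5, 8], [4, 0, 9], [3, 7, 6]])
        fit = multinomial_logit(ep, cl)
        assert fit.separable

    def test_wald_interval_brackets_or(self):
        cl, ep = labels_from_counts(PUBLISHED_COUNTS)
        fit = multinomial_logit(ep, cl)
        assert (fit.table["ci_low"] < fit.table["odds_ratio"]).all()
        assert (fit.table["odds_ratio"] < fit.table["ci_high"]).all()


class TestTukeyKramer:
    def test_identical_group_means_give_p_one(self):
        v = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        g = np.repeat(["a", "b", "c"], 4)
        res = tukey_kramer_hsd(v, g)
        assert np.allclose(res.table["p_adjusted"], 1.0, atol=1e-6)

    def test_extreme_separation(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 1, 30), rng.normal(20, 1, 30)])
        g = np.repeat(["a", "b"], 30)
        res = tukey_kramer_hsd(v, g)
        assert res.table["p_adjusted"].iloc[0] < 1e-6

    def test_balanced_q_matches_hand_computation(self):
        groups = {"a": [4.0, 5.0, 6.0], "b": [7.0, 8.0, 9.0], "c": [1.0, 2.0, 3.0]}
        v = np.concatenate(list(groups.values()))
        g = np.repeat(list(groups), 3)
        res = tukey_kramer_hsd(v, g)
        mse = 1.0  # each group variance 1.0 with ddof adjustment: SSE=6, df=6
        for _, r in res.table.iterrows():
            se = np.sqrt(mse / 2 * (1 / 3 + 1 / 3))
            expected_q = abs(
                np.mean(groups[r["group_b"]]) - np.mean(groups[r["group_a"]])
            ) / se
            assert r["q"] == pytest.approx(expected_q)

    def test_matches_statsmodels_on_unbalanced_groups(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(1)
        v = np.concatenate(
            [rng.normal(0, 1, 12), rng.normal(0.8, 1, 20), rng.normal(1.5, 1, 7)]
        )
        g = np.repeat(["a", "b", "c"], [12, 20, 7])
        ours = tukey_kramer_hsd(v, g)
        ref = pairwise_tukeyhsd(v, g)
        assert np.allclose(
            ours.table["mean_diff"].to_numpy(), ref.meandiffs, rtol=1e-9
        )
        assert np.allclose(
            ours.table["p_adjusted"].to_numpy(), ref.pvalues, atol=2e-3
        )

    def test_tiny_group_rejected(self):
        with pytest.raises(StatsError):
            tukey_kramer_hsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestOls:
    def _epochs(self, n1=35, n2=71, n3=57):
        return np.repeat(
            [INTERICTAL_SEIZURE_FREE, INTERICTAL_ACTIVE, ICTAL_ACTIVE], [n1, n2, n3]
        )

    def test_group_means_model_exact(self):
        ep = self._epochs(5, 6, 7)
        means = {INTERICTAL_SEIZURE_FREE: 10.0, INTERICTAL_ACTIVE: 13.0,
                 ICTAL_ACTIVE: 8.0}
        y = np.array([means[e] for e in ep])
        fit = ols_regression(y, ep)
        b = dict(zip(fit.table["term"], fit.table["beta"]))
        assert b[INTERICTAL_ACTIVE] == pytest.approx(3.0)
        assert b[ICTAL_ACTIVE] == pytest.approx(-2.0)

    def test_location_invariance_of_dummy_coefficients(self):
        rng = np.random.default_rng(3)
        ep = self._epochs(10, 10, 10)
        y = rng.normal(0, 1, 30)
        b1 = ols_regression(y, ep).table["beta"].to_numpy()
        b2 = ols_regression(y + 100.0, ep).table["beta"].to_numpy()
        assert np.allclose(b1, b2, atol=1e-9)

    def test_standardized_beta_identity(self):
        rng = np.random.default_rng(4)
        ep = self._epochs(20, 20, 20)
        y = rng.normal(0, 1, 60) + (ep == ICTAL_ACTIVE) * 0.8
        fit = ols_regression(y, ep)
        for _, r in fit.table.iterrows():
            x = (ep == r["term"]).astype(float)
            assert r["std_beta"] == pytest.approx(
                r["beta"] * x.std() / y.std(), rel=1e-9
            )

    def test_recovers_generating_effects_at_study_scale(self):
        """Simulated frequency shifts at the published effect sizes are
        recovered within 2 SE at n = 163."""
        rng = np.random.default_rng(0)
        ep = self._epochs()
        effects = {INTERICTAL_SEIZURE_FREE: 0.0, INTERICTAL_ACTIVE: -16.19,
                   ICTAL_ACTIVE: 14.43}
        y = 138.8 + np.array([effects[e] for e in ep]) + rng.normal(0, 9.0, 163)
        fit = ols_regression(y, ep)
        for _, r in fit.table.iterrows():
            se = (r["ci_high"] - r["ci_low"]) / (2 * 1.96)
            assert abs(r["beta"] - effects[r["term"]]) < 2 * se

    def test_age_adjustment_adds_term(self):
        rng = np.random.default_rng(8)
        ep = self._epochs(10, 10, 10)
        age = rng.uniform(6, 17, 30)
        y = rng.normal(0, 1, 30) + 0.1 * age
        fit = ols_regression(y, ep, age=age)
        assert fit.adjusted
        assert "age" in set(fit.table["term"])

    def test_rank_deficiency_rejected(self):
        ep = np.repeat([INTERICTAL_ACTIVE], 10)
        age = np.ones(10)
        with pytest.raises(StatsError):
            ols_regression(np.arange(10.0), ep, age=age)


class TestReports:
    def test_row_percentages_match_published_table(self):
        report = epoch_association_report(table_from_counts(PUBLISHED_COUNTS))
        c2 = report[report["cluster"] == "Cluster 2"].iloc[0]
        assert c2[f"{INTERICTAL_SEIZURE_FREE}_pct"] == 14.3
        assert c2[f"{INTERICTAL_ACTIVE}_pct"] == 75.7
        assert c2[f"{ICTAL_ACTIVE}_pct"] == 10.0
        assert c2[f"{INTERICTAL_ACTIVE}_n"] == 53

    def test_empty_cluster_row_flagged(self):
        report = epoch_association_report(
            table_from_counts([[5, 5, 5], [0, 0, 0], [1, 2, 3]])
        )
        assert report.loc[report["cluster"] == "Cluster 2", "warning"].iloc[0] == (
            "empty cluster"
        )

    def test_report_regeneration_is_byte_identical(self, tmp_path):
        cl, ep = labels_from_counts(PUBLISHED_COUNTS)
        table = build_contingency(cl, ep)
        chi2 = chi_square_test(table)
        fit = multinomial_logit(ep, cl)
        a = make_reports(table, fit, chi2, None, tmp_path / "a")
        b = make_reports(table, fit, chi2, None, tmp_path / "b")
        for key in a:
            assert open(a[key], "rb").read() == open(b[key], "rb").read()

    def test_p_value_formatting(self):
        assert format_p(0.0004) == "<0.001"
        assert format_p(0.0092) == "0.009"
        assert format_p(0.67) == "0.670"

    def test_feature_regression_report_layout(self):
        rng = np.random.default_rng(9)
        n = 60
        df = pd.DataFrame(
            {
                "avg_frequency_hz": rng.normal(130, 15, n),
                "duration_ms": rng.normal(45, 10, n),
                "amplitude_z": rng.lognormal(2, 0.3, n),
                "n_cycles": rng.lognormal(1.7, 0.2, n),
                "epoch": np.repeat(
                    [INTERICTAL_SEIZURE_FREE, INTERICTAL_ACTIVE, ICTAL_ACTIVE], 20
                ),
            }
        )
        report = feature_regression_report(df)
        assert set(report["feature"]) == {
            "average_frequency", "duration", "log_amplitude", "log_n_cycles"
        }
        assert set(report["model"]) == {"crude"}
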