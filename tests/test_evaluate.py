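"""Discrimination metrics, bootstrap machinery, stratified report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afhorizon.evaluate import (average_precision, bootstrap_ci,
                                burden_stratum, f1_score,
                                operating_point_at_sensitivity,
                                paired_bootstrap_test, roc_auc,
                                stratified_report)


def brute_force_auc(scores, labels):
    """Explicit enumeration over all positive-negative pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    wins = np.sum(pos > neg) + 0.5 * np.sum(pos == neg)
    return float(wins / (pos.shape[0] * neg.shape[1]))


def stepwise_ap_oracle(scores, labels):
    """Direct enumeration of precision at each distinct threshold."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    n_pos = y.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(s), reverse=True):
        pred = s >= t
        tp = np.sum(pred & (y == 1))
        prec = tp / pred.sum()
        recall = tp / n_pos
        ap += prec * (recall - prev_recall)
        prev_recall = recall
    return ap


class TestAUC:
    def test_textbook_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_and_degenerate(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(4, 201)
            s = np.round(rng.random(n), 2)  # many ties
            y = rng.integers(0, 2, n)
            if 0 < y.sum() < n:
                assert roc_auc(s, y) == pytest.approx(
                    brute_force_auc(s, y), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        for _ in range(50):
            s = rng.random(80)
            y = rng.integers(0, 2, 80)
            if 0 < y.sum() < 80:
                assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.random(60)
        y = rng.integers(0, 2, 60)
        if not 0 < y.sum() < 60:
            return
        assert roc_auc(np.exp(3 * s), y) == pytest.approx(roc_auc(s, y),
                                                          abs=1e-12)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_single_positive_ranked_first(self):
        assert average_precision([0.9, 0.5, 0.1], [1, 0, 0]) == 1.0

    def test_hand_enumerated_example(self):
        assert average_precision([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(
            (1 + 2 / 3) / 2)

    def test_all_label_patterns_up_to_n6_match_oracle(self):
        for n in range(2, 7):
            s = np.linspace(1.0, 0.5, n)  # distinct, decreasing
            for bits in range(1, 2 ** n):
                y = np.array([(bits >> i) & 1 for i in range(n)], float)
                assert average_precision(s, y) == pytest.approx(
                    stepwise_ap_oracle(s, y), abs=1e-12)
        # tied-score pattern
        s = np.array([0.9, 0.9, 0.5, 0.5, 0.1])
        y = np.array([1, 0, 1, 0, 1], float)
        assert average_precision(s, y) == pytest.approx(
            stepwise_ap_oracle(s, y), abs=1e-12)

    def test_no_positive_raises(self):
        with pytest.raises(ValueError):
            average_precision([0.5, 0.4], [0, 0])

    def test_worst_case_ranking_closed_form(self):
        # with all positives ranked last, AP has the closed form
        # mean_k k / (N - P + k); the step-wise sum must match it exactly
        for n, p in [(50, 29), (10, 3), (7, 7), (20, 1)]:
            s = np.linspace(1.0, 0.0, n)
            y = np.zeros(n)
            y[-p:] = 1
            oracle = np.mean([k / (n - p + k) for k in range(1, p + 1)])
            assert average_precision(s, y) == pytest.approx(oracle,
                                                            abs=1e-12)

    def test_random_ranking_averages_at_least_prevalence(self):
        aps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            s = rng.random(60)
            y = np.zeros(60)
            y[:18] = 1
            aps.append(average_precision(rng.permutation(s), y))
        assert 0.30 <= np.mean(aps) <= 0.40


class TestOperatingPoint:
    def test_f1_arithmetic(self):
        assert f1_score(0.80, 0.04) == pytest.approx(0.0762, abs=5e-4)
        assert round(f1_score(0.80, 0.04), 2) == 0.08

    def test_perfectly_separated(self):
        op = operating_point_at_sensitivity(
            [0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.8)
        assert op.specificity == 1.0 and op.precision == 1.0
        assert op.target_met

    def test_threshold_rule_reaches_at_least_target(self):
        rng = np.random.default_rng(2)
        s = rng.random(500)
        y = (rng.random(500) < 0.3).astype(int)
        op = operating_point_at_sensitivity(s, y, 0.8)
        assert op.sensitivity >= 0.8
        # the next-larger threshold would undershoot
        above = np.unique(s)[np.unique(s) > op.threshold]
        if above.size:
            sens_above = np.mean(s[y == 1] >= above.min())
            assert sens_above < 0.8

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            operating_point_at_sensitivity([0.5, 0.4], [1, 0], 1.5)


class TestBootstrap:
    def test_same_seed_identical_interval(self):
        rng = np.random.default_rng(0)
        s = rng.random(60)
        y = rng.integers(0, 2, 60)
        a = bootstrap_ci(roc_auc, s, y, n_boot=300, seed=5)
        b = bootstrap_ci(roc_auc, s, y, n_boot=300, seed=5)
        assert (a.low, a.high) == (b.low, b.high)

    def test_degenerate_metric_zero_width(self):
        prevalence = lambda s, y: float(np.mean(y))  # noqa: E731
        s = np.linspace(0, 1, 40)
        y = np.array([0, 1] * 20)
        # resampling changes prevalence; use a truly constant statistic
        const = lambda s, y: 0.42  # noqa: E731
        r = bootstrap_ci(const, s, y, n_boot=200, seed=0)
        assert r.low == r.high == r.point == 0.42

    def test_small_samples_refused(self):
        with pytest.raises(ValueError):
            bootstrap_ci(roc_auc, [0.1, 0.9], [0, 1], n_boot=100, seed=0)


class TestPairedBootstrap:
    def _data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < 0.3).astype(float)
        good = y + 0.2 * rng.standard_normal(n)   # separating model
        rand = rng.random(n)                      # uninformative model
        return good, rand, y

    def test_identical_models_give_p_one(self):
        good, _, y = self._data()
        r = paired_bootstrap_test(roc_auc, good, good, y, n_boot=400, seed=1)
        assert r.delta == 0.0
        assert r.p_value > 0.95

    def test_separable_vs_random_is_significant(self):
        good, rand, y = self._data(seed=3)
        r = paired_bootstrap_test(roc_auc, good, rand, y, n_boot=1000,
                                  seed=2)
        assert r.delta > 0.3
        assert r.p_value < 0.01

    def test_swapping_models_negates_delta_keeps_p(self):
        good, rand, y = self._data(seed=4)
        ab = paired_bootstrap_test(roc_auc, good, rand, y, n_boot=500, seed=7)
        ba = paired_bootstrap_test(roc_auc, rand, good, y, n_boot=500, seed=7)
        assert ab.delta == pytest.approx(-ba.delta)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_marginal_cis_match_unpaired_bootstrap(self):
        good, rand, y = self._data(seed=5)
        paired = paired_bootstrap_test(roc_auc, good, rand, y, n_boot=400,
                                       seed=9)
        solo_a = bootstrap_ci(roc_auc, good, y, n_boot=400, seed=9)
        solo_b = bootstrap_ci(roc_auc, rand, y, n_boot=400, seed=9)
        assert (paired.a_low, paired.a_high) == (solo_a.low, solo_a.high)
        assert (paired.b_low, paired.b_high) == (solo_b.low, solo_b.high)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_bootstrap_test(roc_auc, [0.1] * 5, [0.2] * 6,
                                  [0, 1, 0, 1, 0], n_boot=100, seed=0)


class TestStratifiedReport:
    def _inputs(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < 0.2).astype(float)
        scores = {"ag": rng.random(n),
                  "all_features": y + 0.5 * rng.standard_normal(n)}
        meta = pd.DataFrame({
            "age": rng.uniform(20, 95, n),
            "burden": np.where(y == 1, rng.choice(
                [0.005, 0.05, 0.2], n), 0.0)})
        return scores, y, meta

    def test_burden_bins(self):
        assert burden_stratum(0.005) == "low"
        assert burden_stratum(0.05) == "medium"
        assert burden_stratum(0.2) == "high"

    def test_pooled_prevalence_identity(self):
        scores, y, meta = self._inputs()
        rep = stratified_report(scores, y, meta, n_boot=120, seed=0)
        ag = rep[rep["feature_set"] == "ag"].set_index("stratum")
        lhs = ag.loc["overall", "prevalence"] * ag.loc["overall", "n"]
        rhs = (ag.loc["age<65", "prevalence"] * ag.loc["age<65", "n"]
               + ag.loc["age>=65", "prevalence"] * ag.loc["age>=65", "n"])
        assert lhs == pytest.approx(rhs)

    def test_burden_strata_share_all_negatives(self):
        scores, y, meta = self._inputs()
        rep = stratified_report(scores, y, meta, n_boot=120, seed=0)
        ag = rep[rep["feature_set"] == "ag"].set_index("stratum")
        n_neg = int((y == 0).sum())
        for name in ("low", "medium", "high"):
            n_pos_stratum = sum(
                1 for b, yy in zip(meta["burden"], y)
                if yy == 1 and burden_stratum(b) == name)
            assert ag.loc[f"burden_{name}", "n"] == n_neg + n_pos_stratum

    def test_paired_comparison_column(self):
        scores, y, meta = self._inputs(seed=2)
        rep = stratified_report(scores, y, meta, n_boot=200, seed=0,
                                compare_to="ag")
        row = rep[(rep["feature_set"] == "all_features")
                  & (rep["stratum"] == "overall")].iloc[0]
        assert row["delta_auc_vs_ref"] > 0.1
        assert row["p_vs_ref"] < 0.05
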