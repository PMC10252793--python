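import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from hbpkit.evaluate import (
    ConfusionCounts,
    confusion,
    independent_test,
    is_undefined,
    kfold_cv,
    pr_curve_and_auprc,
    roc_curve_and_auc,
    scalar_metrics,
    self_consistency,
)
from hbpkit.model import BoostedForestConfig


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_inverse_predictions(self):
        c = confusion([1, 0], [0, 1])
        assert (c.fn, c.fp, c.tp, c.tn) == (1, 1, 0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_randomized_pairs_match_nested_loop_tally(self):
        rng = np.random.default_rng(8)
        truth = rng.integers(0, 2, 100)
        pred = rng.integers(0, 2, 100)
        c = confusion(truth, pred)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for t, p in zip(truth, pred):
            key = ("t" if t == p else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"]
        )
        assert c.total == 100


class TestScalarMetrics:
    def test_perfect_classifier(self):
        m = scalar_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert m["acc"] == m["f1"] == m["mcc"] == 1.0

    def test_completely_inverse_classifier(self):
        m = scalar_metrics(ConfusionCounts(tp=0, tn=0, fp=50, fn=50))
        assert m["acc"] == 0.0 and m["mcc"] == -1.0

    def test_symmetric_94_percent_case(self):
        m = scalar_metrics(ConfusionCounts(tp=47, fn=3, tn=47, fp=3))
        assert m["acc"] == pytest.approx(0.94)
        assert m["pre"] == pytest.approx(0.94)
        assert m["rec"] == pytest.approx(0.94)
        assert m["f1"] == pytest.approx(0.94)
        assert m["mcc"] == pytest.approx(0.88)

    def test_f1_is_harmonic_mean_and_sn_equals_rec(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 50, 4)
            m = scalar_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert m["f1"] == pytest.approx(
                2 / (1 / m["pre"] + 1 / m["rec"])
            )
            assert m["sn"] == m["rec"]
            assert m["sp"] == pytest.approx(tn / (tn + fp))
            assert -1 <= m["mcc"] <= 1

    def test_zero_denominators_yield_undefined_not_exception(self):
        m = scalar_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert is_undefined(m["pre"]) and is_undefined(m["rec"])
        assert is_undefined(m["f1"]) and is_undefined(m["mcc"])
        assert m["acc"] == 1.0  # accuracy still defined


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = roc_curve_and_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0

    def test_all_equal_scores_diagonal(self):
        points, auc = roc_curve_and_auc([1, 0, 1, 0], [0.5] * 4)
        assert auc == 0.5
        assert points == [(0.0, 0.0), (1.0, 1.0)]

    def test_hand_computed_three_quarters(self):
        _, auc = roc_curve_and_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3])
        assert auc == pytest.approx(0.75)

    def test_curve_endpoints(self):
        points, _ = roc_curve_and_auc([1, 0, 1], [0.3, 0.2, 0.9])
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_and_auc([1, 1], [0.5, 0.4])

    def test_auc_equals_normalized_mann_whitney(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            truth = rng.integers(0, 2, n)
            if truth.sum() in (0, n):
                continue
            score = np.round(rng.uniform(size=n), 1)  # force ties
            _, auc = roc_curve_and_auc(truth, score)
            pos = score[truth == 1]
            neg = score[truth == 0]
            u = sum(
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos for q in neg
            )
            assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(truth, score), abs=1e-12)


class TestPrAuprc:
    def test_perfect_ranking(self):
        _, auprc = pr_curve_and_auprc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert auprc == 1.0

    def test_single_positive_ranked_first(self):
        truth = [1] + [0] * 9
        score = np.linspace(1, 0.1, 10)
        points, _ = pr_curve_and_auprc(truth, score)
        assert (1.0, 1.0) in points  # precision 1 at recall 1

    def test_worst_case_ranking_matches_exhaustive_oracle(self):
        truth = np.array([0, 0, 0, 1, 1, 1])
        score = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        points, auprc = pr_curve_and_auprc(truth, score)
        # exhaustive: at each of the 6 thresholds precision = tp/pred, recall = tp/3
        expect_points = []
        for k in range(1, 7):
            tp = max(0, k - 3)
            expect_points.append((tp / 3, tp / k if k else 0))
        for pt in expect_points:
            assert pt in points
        rec = np.array([p[0] for p in points])
        pre = np.array([p[1] for p in points])
        assert auprc == pytest.approx(np.trapezoid(pre, rec))

    def test_zero_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve_and_auprc([0, 0], [0.5, 0.4])


class TestProtocols:
    def test_kfold_partitions_and_pools(self, separable_table):
        cfg = BoostedForestConfig(seed=1, n_estimators=15)
        report = kfold_cv(separable_table, cfg, k=5, seed=2)
        assert len(report.per_fold) == 5
        fold_totals = [r.counts.total for r in report.per_fold]
        assert sum(fold_totals) == len(separable_table)  # partition covers once
        pooled = report.per_fold[0].counts
        for r in report.per_fold[1:]:
            pooled = pooled + r.counts
        assert pooled == report.counts  # additivity
        assert report.fold_mean["acc"] == pytest.approx(
            np.mean([r.acc for r in report.per_fold])
        )

    def test_kfold_recovers_separable_signal(self, separable_table):
        report = kfold_cv(separable_table, BoostedForestConfig(seed=1), k=5, seed=3)
        assert report.acc >= 0.95
        assert report.auc is not None and report.auc > 0.95

    def test_k_below_two_rejected(self, separable_table):
        with pytest.raises(ValueError):
            kfold_cv(separable_table, k=1)

    def test_self_consistency_upper_bound(self, separable_table):
        report = self_consistency(separable_table, BoostedForestConfig(seed=1))
        assert report.protocol == "self-consistency"
        assert report.acc >= 0.99
        assert set(report.to_dict()) >= {"acc", "f1", "mcc", "tp"}

    def test_independent_test_and_leakage_guard(self, separable_table):
        train_t = separable_table.iloc[:96]
        test_t = separable_table.iloc[96:]
        _, report = independent_test(train_t, test_t, BoostedForestConfig(seed=1))
        assert report.protocol == "independent-test"
        assert report.acc >= 0.9
        with pytest.raises(ValueError, match="leakage"):
            independent_test(separable_table, test_t)

    def test_independent_report_invariant_to_test_row_order(self, separable_table):
        train_t = separable_table.iloc[:96]
        test_t = separable_table.iloc[96:]
        cfg = BoostedForestConfig(seed=4, n_estimators=20)
        _, r1 = independent_test(train_t, test_t, cfg)
        _, r2 = independent_test(train_t, test_t.sample(frac=1, random_state=0), cfg)
        assert r1.counts == r2.counts


def test_cv_on_permutation_null_near_chance(separable_table):
    """Label-permuted data: CV accuracy should sit near 0.5."""
    rng = np.random.default_rng(12)
    accs = []
    cfg = BoostedForestConfig(seed=1, n_estimators=25)
    for rep in range(5):
        t = separable_table.copy()
        t["label"] = rng.permutation(t["label"].to_numpy())
        t.attrs["feature_version"] = "test-sep-v1"
        accs.append(kfold_cv(t, cfg, k=5, seed=rep).acc)
    se = 0.5 / math.sqrt(len(separable_table) * len(accs))
    assert abs(np.mean(accs) - 0.5) < max(3 * se, 0.08)
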