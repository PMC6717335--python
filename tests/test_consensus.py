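"""PF/CS integration, metric suite and Pareto selection."""

import numpy as np
import pandas as pd
import pytest

from acutetox.consensus import (
    ParetoPoint,
    apply_reliability_threshold,
    integrate_classification,
    integrate_ledger,
    integrate_regression,
    pareto_front,
    pf_error_report,
)
from acutetox.metrics import (
    classification_metrics,
    confusion_matrix,
    cooper_stats,
    generalized_mcc,
    regression_metrics,
)


class TestIntegrateRegression:
    def test_pf_three_of_four(self):
        out = integrate_regression([1.0, 2.0, 3.0, 9.9], [True, True, True, False], 4)
        assert out.pf == pytest.approx(0.75)
        assert out.value == pytest.approx(2.0)

    def test_identical_values(self):
        out = integrate_regression([1.5] * 4, [True] * 4, 4)
        assert out.value == 1.5 and out.pf == 1.0

    def test_no_in_ad_abstains(self):
        out = integrate_regression([1.0, 2.0], [False, False], 4)
        assert out.abstained and out.pf == 0.0

    def test_value_within_contributing_range(self, rng):
        for _ in range(100):
            vals = rng.normal(size=4)
            in_ad = rng.random(4) < 0.7
            out = integrate_regression(vals, in_ad, 4)
            if not out.abstained:
                assert vals[in_ad].min() <= out.value <= vals[in_ad].max()


class TestIntegrateClassification:
    def test_two_positive_one_negative_cs1(self):
        out = integrate_classification(
            ["positive", "positive", "negative", "positive"],
            [True, True, True, False],
        )
        assert out.value == "positive" and out.cs == 1

    def test_unanimous_cs4(self):
        out = integrate_classification(["positive"] * 4, [True] * 4)
        assert out.cs == 4

    def test_tie_abstains(self):
        out = integrate_classification(["positive", "negative"], [True, True])
        assert out.abstained and out.cs is None

    def test_cs_parity_matches_vote_count(self, rng):
        """With two labels, cs and the number of in-AD votes share parity."""
        for _ in range(200):
            labels = rng.choice(["a", "b"], size=4).tolist()
            in_ad = (rng.random(4) < 0.8).tolist()
            out = integrate_classification(labels, in_ad)
            n = sum(in_ad)
            if not out.abstained:
                assert (out.cs - n) % 2 == 0
                assert out.cs >= 1


class TestReliabilityThreshold:
    def _preds(self):
        return [
            integrate_regression([1.0] * k + [0.0] * (4 - k), [True] * k + [False] * (4 - k), 4)
            for k in (1, 2, 3, 4)
        ]

    def test_zero_threshold_keeps_all_predicted(self):
        flags, cov = apply_reliability_threshold(self._preds(), 0.0, "pf")
        assert flags.all() and cov == 1.0

    def test_unreachable_threshold(self):
        flags, cov = apply_reliability_threshold(self._preds(), 1.1, "pf")
        assert not flags.any() and cov == 0.0

    def test_coverage_monotone_in_threshold(self):
        preds = self._preds()
        covs = [apply_reliability_threshold(preds, t, "pf")[1]
                for t in (0.25, 0.5, 0.75, 1.0)]
        assert all(a >= b for a, b in zip(covs, covs[1:]))


class TestLedgerIntegration:
    def test_roundtrip(self):
        ledger = pd.DataFrame({
            "sample_id": ["s1"] * 4 + ["s2"] * 4,
            "model_id": ["m0", "m1", "m2", "m3"] * 2,
            "prediction": [1.0, 2.0, 3.0, 4.0, 0.0, 0.0, 0.0, 8.0],
            "in_ad": [True, True, True, False, True, True, True, True],
        })
        out = integrate_ledger(ledger, mode="regression")
        assert out[0].value == pytest.approx(2.0) and out[0].pf == 0.75
        assert out[1].value == pytest.approx(2.0) and out[1].pf == 1.0


class TestPfErrorReport:
    def test_single_level_zero_error(self):
        preds = [integrate_regression([1.0] * 4, [True] * 4, 4, sample_id=str(i))
                 for i in range(10)]
        report = pf_error_report(preds, np.ones(10), levels=(1.0,))
        row = report.iloc[0]
        assert row["rmse"] == 0.0 and row["frac_abs_error_ge_1"] == 0.0 and row["n"] == 10

    def test_planted_large_errors_counted(self):
        truth = np.zeros(10)
        values = np.zeros(10)
        values[:2] = 1.5  # two samples with |error| = 1.5
        preds = [integrate_regression([v] * 4, [True] * 4, 4, sample_id=str(i))
                 for i, v in enumerate(values)]
        report = pf_error_report(preds, truth, levels=(1.0,))
        assert report.iloc[0]["frac_abs_error_ge_1"] == pytest.approx(0.2)

    def test_level_counts_sum_to_total(self, rng):
        preds = []
        truth = []
        for i in range(40):
            k = int(rng.integers(1, 5))
            preds.append(integrate_regression(
                list(rng.normal(size=4)), [True] * k + [False] * (4 - k), 4, sample_id=str(i)
            ))
            truth.append(0.0)
        report = pf_error_report(preds, np.array(truth))
        assert report["n"].sum() == 40
        assert report["fraction"].sum() == pytest.approx(1.0)


class TestRegressionMetrics:
    def test_perfect(self):
        m = regression_metrics([1.0, 2.0], [1.0, 2.0])
        assert m == {"r2": 1.0, "mae": 0.0, "rmse": 0.0}

    def test_constant_offset(self):
        m = regression_metrics([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert m["mae"] == 1.0 and m["rmse"] == 1.0

    def test_ten_pair_hand_oracle(self, rng):
        pred = rng.normal(size=10)
        truth = rng.normal(size=10)
        m = regression_metrics(pred, truth)
        resid = pred - truth
        assert m["mae"] == pytest.approx(np.abs(resid).mean())
        assert m["rmse"] == pytest.approx(np.sqrt((resid**2).mean()))
        assert m["r2"] == pytest.approx(
            1 - (resid**2).sum() / ((truth - truth.mean()) ** 2).sum()
        )

    def test_zero_variance_truth(self):
        assert np.isnan(regression_metrics([1.0, 2.0], [3.0, 3.0])["r2"])


class TestClassificationMetrics:
    def test_perfect_diagonal(self):
        cm = confusion_matrix(["a", "b", "a"], ["a", "b", "a"])
        m = classification_metrics(cm)
        assert m["ba"] == 1.0 and m["mcc"] == 1.0

    def test_binary_worked_example(self):
        """TP=80 FN=20 TN=60 FP=40 -> SEN .8, SPE .6, BA .7, MCC ~.408."""
        truth = ["pos"] * 100 + ["neg"] * 100
        pred = ["pos"] * 80 + ["neg"] * 20 + ["neg"] * 60 + ["pos"] * 40
        cm = confusion_matrix(truth, pred, classes=["pos", "neg"])
        m = classification_metrics(cm, positive="pos")
        assert m["sen"] == pytest.approx(0.8)
        assert m["spe"] == pytest.approx(0.6)
        assert m["ba"] == pytest.approx(0.7)
        assert m["mcc"] == pytest.approx(0.40825, abs=1e-4)

    def test_generalized_mcc_matches_sklearn(self, rng):
        """The confusion-matrix generalization equals sklearn's multiclass MCC."""
        from sklearn.metrics import matthews_corrcoef

        for _ in range(50):
            truth = rng.integers(0, 4, size=60)
            pred = rng.integers(0, 4, size=60)
            cm = confusion_matrix(truth.tolist(), pred.tolist(), classes=[0, 1, 2, 3])
            assert generalized_mcc(cm) == pytest.approx(
                matthews_corrcoef(truth, pred), abs=1e-12
            )

    def test_block_embedding_reduces_to_binary(self):
        """A 2x2 block embedded in 3 classes keeps its binary MCC."""
        from acutetox.metrics import ConfusionMatrix

        block = np.array([[30, 10], [5, 25]])
        cm2 = ConfusionMatrix(block, ("a", "b"))
        embedded = np.zeros((3, 3), dtype=int)
        embedded[:2, :2] = block
        cm3 = ConfusionMatrix(embedded, ("a", "b", "c"))
        assert generalized_mcc(cm3) == pytest.approx(generalized_mcc(cm2))


class TestCooper:
    def test_perfect(self):
        cm = confusion_matrix(["p", "n"], ["p", "n"], classes=["p", "n"])
        s = cooper_stats(cm, positive="p")
        assert s["sensitivity"] == 1.0 and s["specificity"] == 1.0
        assert s["accuracy"] == 1.0
        assert s["false_positive_rate"] == 0.0 and s["false_negative_rate"] == 0.0

    def test_worked_accuracy(self):
        truth = ["p"] * 100 + ["n"] * 100
        pred = ["p"] * 80 + ["n"] * 20 + ["n"] * 60 + ["p"] * 40
        s = cooper_stats(confusion_matrix(truth, pred, classes=["p", "n"]), positive="p")
        assert s["accuracy"] == pytest.approx(0.7)

    def test_fpr_specificity_identity(self, rng):
        for _ in range(50):
            truth = rng.choice(["p", "n"], size=40).tolist()
            pred = rng.choice(["p", "n"], size=40).tolist()
            cm = confusion_matrix(truth, pred, classes=["p", "n"])
            if cm.counts.sum(axis=1).min() == 0:
                continue
            s = cooper_stats(cm, positive="p")
            assert s["false_positive_rate"] + s["specificity"] == pytest.approx(1.0)


class TestParetoFront:
    def test_worked_example(self):
        pts = [ParetoPoint("a", 0.5, 0.9), ParetoPoint("b", 0.55, 0.95),
               ParetoPoint("c", 0.6, 0.85)]
        front = pareto_front(pts, minimize_performance=True)
        assert [p.tag for p in front] == ["a", "b"]

    def test_single_point(self):
        pts = [ParetoPoint("only", 1.0, 0.5)]
        assert pareto_front(pts) == pts

    def test_duplicates_retained(self):
        pts = [ParetoPoint("a", 0.5, 0.9), ParetoPoint("b", 0.5, 0.9)]
        assert len(pareto_front(pts)) == 2

    def test_matches_dominance_oracle(self, rng):
        for _ in range(100):
            pts = [ParetoPoint(str(i), float(p), float(c))
                   for i, (p, c) in enumerate(rng.random((10, 2)))]
            front = {p.tag for p in pareto_front(pts, minimize_performance=True)}
            # brute-force all-pairs dominance
            expected = set()
            for i, a in enumerate(pts):
                dominated = False
                for j, b in enumerate(pts):
                    if i == j:
                        continue
                    if (b.performance <= a.performance and b.coverage >= a.coverage
                            and (b.performance < a.performance or b.coverage > a.coverage)):
                        dominated = True
                        break
                if not dominated:
                    expected.add(a.tag)
            assert front == expected
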