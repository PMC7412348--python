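import numpy as np
import pytest

from gaitrp import (
    ClassifierSpec,
    CVScheme,
    FeatureMatrix,
    binary_metrics,
    loocv,
    multiclass_metrics,
    select_best_channel,
    youden,
)
from gaitrp.evaluation import EvalMetrics, confusion_matrix, round_display


def metrics_stub(channel, J, accuracy=0.9):
    return EvalMetrics(
        task="t", channel=channel, accuracy=accuracy, sensitivity=None,
        specificity=None, auc_balanced=None, J=J,
        confusion=np.zeros((2, 2), dtype=int), class_order=("pos", "neg"),
    )


class TestYouden:
    def test_printed_table_cells(self):
        assert round_display(youden(0.9854, 0.9825), 4) == 0.9679
        assert round_display(youden(0.9459, 0.9765), 4) == 0.9224
        assert round_display(youden(0.9574, 0.8235), 4) == 0.7809

    def test_perfect_test(self):
        assert youden(1.0, 1.0) == 1.0

    def test_chance_level(self):
        assert youden(0.5, 0.5) == 0.0

    def test_range_validation(self):
        with pytest.raises(ValueError):
            youden(1.2, 0.5)
        with pytest.raises(ValueError):
            youden(0.5, -0.1)


class TestBinaryMetrics:
    def test_published_hd_vs_hc_cell(self):
        cm = np.array([[9854, 146], [175, 9825]])
        m = binary_metrics(cm, "HD", ("HD", "HC"))
        assert m.sensitivity == pytest.approx(0.9854)
        assert m.specificity == pytest.approx(0.9825)
        # (sens+spec)/2 = 0.98395 sits exactly on the rounding boundary of
        # the printed 0.9839 cell; compare within half an ULP at 4 decimals
        assert abs(m.auc_balanced - 0.9839) <= 5e-5 + 1e-12
        assert round_display(m.J, 4) == 0.9679

    def test_perfect_classifier(self):
        m = binary_metrics(np.array([[10, 0], [0, 10]]), "pos", ("pos", "neg"))
        assert m.sensitivity == m.specificity == m.accuracy == 1.0
        assert m.auc_balanced == 1.0 and m.J == 1.0

    def test_all_predicted_positive(self):
        m = binary_metrics(np.array([[10, 0], [10, 0]]), "pos", ("pos", "neg"))
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0
        assert m.auc_balanced == 0.5
        assert m.J == 0.0

    def test_accuracy_is_trace_over_total(self):
        cm = np.array([[7, 3], [2, 8]])
        m = binary_metrics(cm, "pos", ("pos", "neg"))
        assert m.accuracy == pytest.approx(15 / 20)
        assert m.confusion.sum() == 20

    def test_no_negatives_flagged_not_zeroed(self):
        m = binary_metrics(np.array([[5, 1], [0, 0]]), "pos", ("pos", "neg"))
        assert m.specificity is None
        assert m.J is None
        assert any("specificity undefined" in f for f in m.flags)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binary_metrics(np.zeros((3, 3)), "a", ("a", "b"))
        with pytest.raises(ValueError):
            binary_metrics(np.zeros((2, 2)), "a", ("a", "b"))
        with pytest.raises(ValueError):
            binary_metrics(np.array([[1, 0], [0, 1]]), "c", ("a", "b"))


class TestJInvariants:
    def test_j_bounds_and_identities(self, rng):
        for _ in range(50):
            s, p = rng.random(2)
            j = youden(s, p)
            assert -1.0 <= j <= 1.0
        assert youden(1.0, 1.0) == 1.0
        s = rng.random()
        assert youden(s, 1.0 - s) == pytest.approx(0.0)


class TestSelectBestChannel:
    def test_published_pd_vs_als_row(self):
        ms = [metrics_stub("LF", 0.9170), metrics_stub("RF", 0.9224),
              metrics_stub("CF", 0.8873)]
        assert select_best_channel(ms) == "RF"

    def test_single_channel(self):
        assert select_best_channel([metrics_stub("CF", 0.5)]) == "CF"

    def test_tie_breaks_by_accuracy_then_fixed_order(self):
        ms = [metrics_stub("RF", 0.9, accuracy=0.95),
              metrics_stub("LF", 0.9, accuracy=0.90)]
        assert select_best_channel(ms) == "RF"
        ms = [metrics_stub("CF", 0.9), metrics_stub("LF", 0.9)]
        assert select_best_channel(ms) == "LF"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_channel([])


class TestMulticlassMetrics:
    def test_diagonal_confusion_all_perfect(self):
        cm = np.diag([5, 6, 7, 8])
        out = multiclass_metrics(cm, ("a", "b", "c", "d"))
        assert out["overall_accuracy"] == 1.0
        for m in out["per_class"].values():
            assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_single_error_hand_computed(self):
        # one 'a' sample predicted 'b'; hand one-vs-rest collapse:
        # a: TP=5 FN=1 FP=0 TN=15 ; b: TP=5 FN=0 FP=1 TN=15
        cm = np.diag([5, 5, 5, 5])
        cm[0, 1] = 1
        out = multiclass_metrics(cm, ("a", "b", "c", "d"))
        assert out["overall_accuracy"] == pytest.approx(20 / 21)
        ma, mb = out["per_class"]["a"], out["per_class"]["b"]
        assert ma.sensitivity == pytest.approx(5 / 6)
        assert ma.specificity == pytest.approx(1.0)
        assert mb.sensitivity == pytest.approx(1.0)
        assert mb.specificity == pytest.approx(15 / 16)
        for lab in ("c", "d"):
            m = out["per_class"][lab]
            assert m.sensitivity == 1.0 and m.specificity == pytest.approx(16 / 16)

    def test_class_permutation_symmetry(self):
        cm = np.array([[5, 1, 0], [0, 6, 2], [1, 0, 7]])
        out1 = multiclass_metrics(cm, ("a", "b", "c"))
        perm = [2, 0, 1]
        out2 = multiclass_metrics(cm[np.ix_(perm, perm)], ("c", "a", "b"))
        for lab in ("a", "b", "c"):
            assert (out1["per_class"][lab].sensitivity
                    == out2["per_class"][lab].sensitivity)
            assert (out1["per_class"][lab].specificity
                    == out2["per_class"][lab].specificity)

    def test_empty_class_flagged(self):
        cm = np.array([[0, 0, 0], [0, 5, 0], [0, 0, 5]])
        out = multiclass_metrics(cm, ("a", "b", "c"))
        assert out["per_class"]["a"].sensitivity is None
        assert out["per_class"]["a"].flags

    def test_requires_k_at_least_3(self):
        with pytest.raises(ValueError):
            multiclass_metrics(np.eye(2, dtype=int), ("a", "b"))


class TestLOOCV:
    def _fm(self, rng, n_per=6, sep=6.0):
        F = np.vstack([
            rng.normal([0, 0], 0.3, (n_per, 2)),
            rng.normal([sep, sep], 0.3, (n_per, 2)),
        ])
        labels = np.array(["neg"] * n_per + ["pos"] * n_per)
        groups = np.array(
            [f"n{i % 3}" for i in range(n_per)] + [f"p{i % 3}" for i in range(n_per)]
        )
        return FeatureMatrix(F, labels, groups)

    def test_window_unit_one_fold_per_sample(self, rng):
        fm = self._fm(rng)
        preds, folds = loocv(fm, CVScheme("window"), ClassifierSpec())
        assert len(np.unique(folds)) == len(fm)

    def test_subject_unit_folds_contain_whole_subjects(self, rng):
        fm = self._fm(rng)
        preds, folds = loocv(fm, CVScheme("subject"), ClassifierSpec())
        assert len(np.unique(folds)) == 6
        for unit in np.unique(folds):
            np.testing.assert_array_equal(
                fm.groups[folds == unit], [unit] * int((folds == unit).sum())
            )

    def test_separable_features_predicted_perfectly(self, rng):
        fm = self._fm(rng)
        for unit in ("window", "subject"):
            preds, _ = loocv(fm, CVScheme(unit), ClassifierSpec())
            np.testing.assert_array_equal(preds, fm.labels)

    def test_degenerate_single_subject_class_rejected(self, rng):
        F = rng.random((6, 2))
        fm = FeatureMatrix(F, ["a"] * 3 + ["b"] * 3, ["s1"] * 3 + ["s2"] * 3)
        with pytest.raises(ValueError, match="fewer than 2 subjects"):
            loocv(fm, CVScheme("subject"), ClassifierSpec())

    def test_invalid_scheme(self):
        with pytest.raises(ValueError):
            CVScheme("fold")


# --- regression over the transcribed 10-s two-class summary table --------
# (task, channel, accuracy%, sensitivity%, specificity%, printed AUC, printed J)
TWO_CLASS_10S_TABLE = [
    ("ALS_vs_HC", "LF", 100.0, 100.0, 100.0, 1.0, 1.0),
    ("ALS_vs_HC", "RF", 100.0, 100.0, 100.0, 1.0, 1.0),
    ("ALS_vs_HC", "CF", 100.0, 100.0, 100.0, 1.0, 1.0),
    ("HD_vs_HC", "LF", 98.41, 98.54, 98.25, 0.9839, 0.9679),
    ("HD_vs_HC", "RF", 98.04, 97.59, 98.60, 0.9810, 0.9619),
    ("HD_vs_HC", "CF", 97.56, 98.51, 96.41, 0.9746, 0.9492),
    ("PD_vs_HC", "LF", 100.0, 100.0, 100.0, 1.0, 1.0),
    ("PD_vs_HC", "RF", 100.0, 100.0, 100.0, 1.0, 1.0),
    ("PD_vs_HC", "CF", 100.0, 100.0, 100.0, 1.0, 1.0),
    ("ALS_vs_HD", "LF", 100.0, 100.0, 100.0, 1.0, 1.0),
    ("ALS_vs_HD", "RF", 100.0, 100.0, 100.0, 1.0, 1.0),
    ("ALS_vs_HD", "CF", 100.0, 100.0, 100.0, 1.0, 1.0),
    ("PD_vs_ALS", "LF", 95.64, 94.07, 97.63, 0.9585, 0.9170),
    ("PD_vs_ALS", "RF", 95.95, 94.59, 97.65, 0.9612, 0.9224),
    ("PD_vs_ALS", "CF", 94.21, 92.95, 95.78, 0.9437, 0.8873),
    ("HD_vs_PD", "LF", 97.11, 96.81, 97.51, 0.9711, 0.9432),  # AUC cell inconsistent
    ("HD_vs_PD", "RF", 97.25, 96.54, 98.24, 0.9739, 0.9478),
    ("HD_vs_PD", "CF", 94.98, 93.54, 97.14, 0.9534, 0.9068),
    ("NDD_vs_HC", "LF", 98.86, 99.01, 98.38, 0.9870, 0.9739),
    ("NDD_vs_HC", "RF", 98.91, 99.04, 98.53, 0.9878, 0.9757),
    ("NDD_vs_HC", "CF", 98.93, 99.44, 97.43, 0.9844, 0.9687),
]

#: one cell where the printed AUC (0.9711) equals the row's accuracy cell
#: instead of (sens+spec)/2 = 0.9716 — a table-internal inconsistency.
KNOWN_DISCREPANT = {("HD_vs_PD", "LF")}


class TestTwoClassTableRegression:
    @pytest.mark.parametrize(
        "task,channel,acc,sens,spec,auc,j", TWO_CLASS_10S_TABLE,
        ids=[f"{t}-{c}" for t, c, *_ in TWO_CLASS_10S_TABLE],
    )
    def test_auc_balanced_matches_printed_cell(self, task, channel, acc,
                                               sens, spec, auc, j):
        balanced = (sens / 100 + spec / 100) / 2
        if (task, channel) in KNOWN_DISCREPANT:
            # printed AUC equals the accuracy cell; the balanced value is 0.9716
            assert round_display(balanced, 4) == 0.9716
            assert auc == acc / 100
        else:
            # within half an ULP at 4 decimals of the printed cell
            assert abs(balanced - auc) <= 5e-5 + 1e-12

    @pytest.mark.parametrize(
        "task,channel,acc,sens,spec,auc,j", TWO_CLASS_10S_TABLE,
        ids=[f"{t}-{c}" for t, c, *_ in TWO_CLASS_10S_TABLE],
    )
    def test_youden_matches_printed_cell(self, task, channel, acc, sens,
                                         spec, auc, j):
        assert round_display(youden(sens / 100, spec / 100), 4) == pytest.approx(j)


class TestConfusionMatrix:
    def test_counts_layout(self):
        truth = np.array(["a", "a", "b", "b", "b"])
        preds = np.array(["a", "b", "b", "b", "a"])
        cm = confusion_matrix(truth, preds, ("a", "b"))
        np.testing.assert_array_equal(cm, [[1, 1], [1, 2]])
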