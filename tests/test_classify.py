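import numpy as np
import pytest
from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef

from eegfusion import (
    ClassifierConfig,
    FeatureMatrix,
    compute_metrics,
    split_train_test,
    train_and_predict,
)
from eegfusion.classify import KINDS, metrics_from_confusion
from eegfusion.errors import ConfigError, SchemaError


def blob_matrix(rng, n_per_class=50, n_features=6, sep=8.0):
    """Two well-separated gaussian blobs, ictal shifted by +sep."""
    x0 = rng.standard_normal((n_per_class, n_features))
    x1 = rng.standard_normal((n_per_class, n_features)) + sep
    values = np.vstack([x0, x1])
    labels = ["non_ictal"] * n_per_class + ["ictal"] * n_per_class
    names = [f"f{i}" for i in range(n_features)]
    return FeatureMatrix(values, names, labels)


class TestSplit:
    def test_stratified_80_20(self, rng):
        fm = blob_matrix(rng, n_per_class=50)
        train, test = split_train_test(fm, test_frac=0.2, seed=0)
        assert train.n_rows == 80 and test.n_rows == 20
        assert test.labels.count("ictal") == 10
        assert test.labels.count("non_ictal") == 10

    def test_same_seed_reproduces_split(self, rng):
        fm = blob_matrix(rng)
        t1 = split_train_test(fm, seed=42)
        t2 = split_train_test(fm, seed=42)
        np.testing.assert_array_equal(t1[0].values, t2[0].values)
        assert t1[1].labels == t2[1].labels

    def test_single_class_rejected(self, rng):
        fm = FeatureMatrix(rng.standard_normal((10, 2)), ["a", "b"], ["ictal"] * 10)
        with pytest.raises(ConfigError):
            split_train_test(fm)


class TestTrainAndPredict:
    @pytest.mark.parametrize("kind", KINDS)
    def test_separable_blobs_reach_perfect_accuracy(self, rng, kind):
        fm = blob_matrix(rng)
        train, test = split_train_test(fm, seed=1)
        cfg = ClassifierConfig(kind=kind, seed=1)
        y_pred = train_and_predict(cfg, train, test)
        assert compute_metrics(test.labels, y_pred).accuracy == 1.0

    def test_bagging_300_estimators_on_58_rows(self, rng):
        fm = blob_matrix(rng, n_per_class=29)
        train, test = split_train_test(fm, seed=2)
        y_pred = train_and_predict(ClassifierConfig("bagging", seed=2), train, test)
        assert set(y_pred) == {"ictal", "non_ictal"}

    def test_depth4_tree_memorizes_small_train_set(self, rng):
        fm = blob_matrix(rng, n_per_class=8, sep=5.0)
        cfg = ClassifierConfig("decision_tree", seed=0)
        y_pred = train_and_predict(cfg, fm, fm)
        assert compute_metrics(fm.labels, y_pred).accuracy == 1.0

    def test_schema_mismatch_rejected(self, rng):
        fm = blob_matrix(rng)
        other = FeatureMatrix(fm.values, [f"g{i}" for i in range(fm.width)], fm.labels)
        with pytest.raises(SchemaError):
            train_and_predict(ClassifierConfig("svm_linear"), fm, other)

    def test_bagging_without_seed_rejected(self):
        with pytest.raises(ConfigError):
            ClassifierConfig("bagging")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            ClassifierConfig("random_forest")


class TestMetrics:
    def test_perfect_prediction(self):
        y = ["ictal", "non_ictal", "ictal"]
        rep = compute_metrics(y, y)
        assert (rep.accuracy_pct, rep.f1_pct, rep.mcc_pct) == (100.0, 100.0, 100.0)

    def test_balanced_coin_flip_confusion(self):
        rep = metrics_from_confusion(tp=1, fp=1, fn=1, tn=1)
        assert rep.accuracy_pct == 50.0
        assert rep.mcc == 0.0

    def test_hand_computed_confusion(self):
        rep = metrics_from_confusion(tp=50, fp=5, fn=0, tn=45)
        assert rep.accuracy_pct == pytest.approx(95.0)
        assert rep.f1_pct == pytest.approx(100 * 100 / 105)
        # MCC = (50*45 - 5*0) / sqrt(55 * 50 * 50 * 45)
        assert rep.mcc_pct == pytest.approx(100 * 2250 / np.sqrt(6187500))

    def test_degenerate_marginal_gives_zero_mcc(self):
        rep = metrics_from_confusion(tp=0, fp=0, fn=5, tn=5)
        assert rep.mcc == 0.0
        assert rep.f1 == 0.0

    def test_matches_sklearn_on_random_labelings(self, rng):
        for _ in range(20):
            y_true = rng.choice(["ictal", "non_ictal"], size=40)
            y_pred = rng.choice(["ictal", "non_ictal"], size=40)
            if len(set(y_true)) < 2 or len(set(y_pred)) < 2:
                continue
            rep = compute_metrics(y_true, y_pred)
            assert rep.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
            assert rep.f1 == pytest.approx(
                f1_score(y_true, y_pred, pos_label="ictal")
            )
            assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_mcc_symmetric_under_joint_label_swap(self, rng):
        y_true = rng.choice(["ictal", "non_ictal"], size=30)
        y_pred = rng.choice(["ictal", "non_ictal"], size=30)
        swap = {"ictal": "non_ictal", "non_ictal": "ictal"}
        rep = compute_metrics(y_true, y_pred)
        rep_sw = compute_metrics([swap[v] for v in y_true], [swap[v] for v in y_pred])
        assert rep.mcc == pytest.approx(rep_sw.mcc)

    def test_metrics_consistent_with_confusion_counts(self, rng):
        y_true = rng.choice(["ictal", "non_ictal"], size=50)
        y_pred = rng.choice(["ictal", "non_ictal"], size=50)
        rep = compute_metrics(y_true, y_pred)
        again = metrics_from_confusion(rep.tp, rep.fp, rep.fn, rep.tn)
        assert (again.accuracy, again.f1, again.mcc) == (rep.accuracy, rep.f1, rep.mcc)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            compute_metrics(["ictal"], ["ictal", "ictal"])
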