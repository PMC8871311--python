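"""Classifier training and evaluation: Accuracy, F1 and MCC.

Four classifier kinds are supported with fixed hyperparameters:

* ``svm_linear`` — linear-kernel SVM, C = 1;
* ``svm_rbf``    — RBF-kernel SVM, C = 100, gamma = 'scale';
* ``decision_tree`` — CART, gini or entropy criterion, max_depth = 4;
* ``bagging``    — 300 depth-4 decision trees on 50% bootstrap subsets.

SVM kinds get a z-score standardization fitted on the training rows only
(feature magnitudes span orders of magnitude between e.g. variance and
curve-length columns); trees operate on raw features.  The evaluation
protocol is a stratified shuffle split with a fixed seed.  The positive
class for F1 and the confusion counts is ictal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, SchemaError
from .io_formats import ICTAL
from .matrix import FeatureMatrix

KINDS = ("svm_linear", "svm_rbf", "decision_tree", "bagging")


@dataclass
class ClassifierConfig:
    """One classifier kind plus the hyperparameters that apply to it."""

    kind: str
    C: float | None = None
    criterion: str = "gini"
    max_depth: int = 4
    n_estimators: int = 300
    max_samples: float = 0.5
    seed: int | None = None
    standardize: bool | None = None  # None -> on for SVM kinds, off for trees

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "bagging" and self.seed is None:
            raise ConfigError("bagging is stochastic; a seed is required")
        if self.C is None:
            self.C = 100.0 if self.kind == "svm_rbf" else 1.0

    def build(self):
        if self.kind == "svm_linear":
            est = SVC(kernel="linear", C=self.C)
        elif self.kind == "svm_rbf":
            est = SVC(kernel="rbf", C=self.C, gamma="scale")
        elif self.kind == "decision_tree":
            est = DecisionTreeClassifier(
                criterion=self.criterion, max_depth=self.max_depth,
                random_state=self.seed,
            )
        else:
            est = BaggingClassifier(
                estimator=DecisionTreeClassifier(
                    criterion=self.criterion, max_depth=self.max_depth
                ),
                n_estimators=self.n_estimators,
                max_samples=self.max_samples,
                random_state=self.seed,
            )
        standardize = self.standardize
        if standardize is None:
            standardize = self.kind in ("svm_linear", "svm_rbf")
        return make_pipeline(StandardScaler(), est) if standardize else est


@dataclass
class MetricsReport:
    """Accuracy/F1/MCC (fractions in [0,1] / [-1,1]) plus confusion counts."""

    accuracy: float
    f1: float
    mcc: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy

    @property
    def f1_pct(self) -> float:
        return 100.0 * self.f1

    @property
    def mcc_pct(self) -> float:
        return 100.0 * self.mcc

    def as_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "f1_pct": self.f1_pct,
            "mcc_pct": self.mcc_pct,
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
        }


def split_train_test(
    fm: FeatureMatrix, test_frac: float = 0.2, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified random split preserving class proportions within one row."""
    labels = np.asarray(fm.labels)
    if len(set(labels)) < 2:
        raise ConfigError("both classes must be present to split")
    idx = np.arange(fm.n_rows)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_frac, random_state=seed, stratify=labels, shuffle=True
    )

    def _take(ix):
        return FeatureMatrix(
            fm.values[ix], list(fm.names), [fm.labels[i] for i in ix],
            case_tag=fm.case_tag, dialect=fm.dialect,
        )

    return _take(train_idx), _take(test_idx)


def train_and_predict(
    cfg: ClassifierConfig, train: FeatureMatrix, test: FeatureMatrix
) -> np.ndarray:
    """Fit on the training matrix and return one predicted label per test row."""
    if train.names != test.names:
        raise SchemaError("train/test feature schemas differ")
    model = cfg.build()
    model.fit(train.values, train.labels)
    return np.asarray(model.predict(test.values))


def confusion_counts(y_true, y_pred, positive: str = ICTAL) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return tp, fp, fn, tn


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> MetricsReport:
    """Closed-form accuracy, F1 and MCC; any zero MCC marginal gives MCC = 0."""
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else 0.0
    f1_den = 2 * tp + fp + fn
    f1 = 2 * tp / f1_den if f1_den else 0.0
    marginals = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(marginals) if marginals else 0.0
    return MetricsReport(accuracy, f1, mcc, tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(y_true, y_pred, positive: str = ICTAL) -> MetricsReport:
    if len(y_true) != len(y_pred):
        raise ConfigError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    return metrics_from_confusion(*confusion_counts(y_true, y_pred, positive))


def evaluate_classifier(
    cfg: ClassifierConfig, fm: FeatureMatrix, test_frac: float = 0.2, seed: int = 0
) -> MetricsReport:
    """Split, train, predict and score one classifier on one feature matrix."""
    train, test = split_train_test(fm, test_frac=test_frac, seed=seed)
    y_pred = train_and_predict(cfg, train, test)
    return compute_metrics(test.labels, y_pred)


def evaluate_all(
    fm: FeatureMatrix, test_frac: float = 0.2, seed: int = 0
) -> dict[str, MetricsReport]:
    """Run all four classifier kinds with their fixed hyperparameters."""
    out: dict[str, MetricsReport] = {}
    for kind in KINDS:
        cfg = ClassifierConfig(kind=kind, seed=seed)
        out[kind] = evaluate_classifier(cfg, fm, test_frac=test_frac, seed=seed)
    return out
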