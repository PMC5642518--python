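"""Cross-validated evaluation of a marker panel as a case/control classifier.

A resolved marker set's probe rows become the feature matrix (samples x
features).  Four classifiers are supported — linear SVM, random forest, a
small feed-forward neural network, and a CART decision tree — each producing
a continuous decision score (signed margin for the SVM, positive-class
probability otherwise) and a hard label at its native boundary.

Under leave-one-out cross-validation every sample is held out once; the
held-out hard predictions are pooled into one confusion table and the
held-out scores into one ROC per classifier, because single-sample folds
have no per-fold measures.  The consensus ("average") record is the
arithmetic mean of each measure over the classifiers that define it.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datamodel import (
    CanesError,
    ConfusionCounts,
    DEFAULT_POSITIVE_LABEL,
    EvaluationResult,
    ExpressionDataset,
    MarkerSet,
    MeasurePanel,
    average_panel,
    resolve_markers,
)

CLASSIFIER_NAMES = ("svm", "rf", "nn", "cart")

#: documented hyperparameter defaults for the four classifiers
DEFAULT_HYPERPARAMETERS = {
    "svm": {"kernel": "linear", "C": 1.0},
    "rf": {"n_estimators": 500},
    "nn": {"hidden_layer_sizes": (8,), "max_iter": 1000},
    "cart": {"criterion": "gini", "min_samples_leaf": 2},
}

#: classifiers whose features are standardized with train-fold mean/SD
_STANDARDIZED = {"svm", "nn"}


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four named classifiers plus hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in CLASSIFIER_NAMES:
            raise CanesError(f"unknown classifier {self.name!r}; use {CLASSIFIER_NAMES}")

    def params(self) -> dict:
        return {**DEFAULT_HYPERPARAMETERS[self.name], **self.hyperparameters}

    def build(self):
        p = self.params()
        if self.name == "svm":
            return SVC(**p)
        if self.name == "rf":
            return RandomForestClassifier(random_state=self.seed, **p)
        if self.name == "nn":
            return MLPClassifier(random_state=self.seed, **p)
        return DecisionTreeClassifier(random_state=self.seed, **p)

    @property
    def standardize(self) -> bool:
        return self.name in _STANDARDIZED


def default_classifiers(seed: int = 0, names=CLASSIFIER_NAMES) -> list:
    return [ClassifierSpec(name=n, seed=seed) for n in names]


# ----------------------------------------------------------------------
# measures
# ----------------------------------------------------------------------

def confusion_measures(c: ConfusionCounts) -> dict:
    """The nine threshold measures from one confusion table.

    AC=(TP+TN)/N, SN=TP/(TP+FN), SP=TN/(FP+TN), BA=(SN+SP)/2,
    PPV=TP/(TP+FP), NPV=TN/(FN+TN), FPR=1-SP, FDR=1-PPV,
    F1=2TP/(2TP+FP+FN).  A zero denominator makes that measure (and only
    the measures depending on it) NaN.
    """
    nan = float("nan")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    total = c.total
    ac = (tp + tn) / total if total else nan
    sn = tp / (tp + fn) if tp + fn else nan
    sp = tn / (fp + tn) if fp + tn else nan
    ba = (sn + sp) / 2 if not (math.isnan(sn) or math.isnan(sp)) else nan
    ppv = tp / (tp + fp) if tp + fp else nan
    npv = tn / (fn + tn) if fn + tn else nan
    fpr = 1 - sp if not math.isnan(sp) else nan
    fdr = 1 - ppv if not math.isnan(ppv) else nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else nan
    return {"ac": ac, "sn": sn, "sp": sp, "ba": ba, "ppv": ppv,
            "npv": npv, "fpr": fpr, "fdr": fdr, "f1": f1}


def auc_from_scores(scores, labels) -> float:
    """Area under the ROC curve of continuous scores against 0/1 labels.

    Trapezoidal over all thresholds, which equals the Mann-Whitney
    concordance probability with half credit for tied score pairs.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) != 2:
        raise CanesError("AUC requires both classes among the evaluated samples")
    return float(roc_auc_score(labels, scores))


def panel_from_predictions(y_true, y_pred, scores, classifier="") -> MeasurePanel:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    counts = ConfusionCounts(
        tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        tn=int(((y_pred == 0) & (y_true == 0)).sum()),
        fp=int(((y_pred == 1) & (y_true == 0)).sum()),
        fn=int(((y_pred == 0) & (y_true == 1)).sum()),
    )
    auc = auc_from_scores(scores, y_true) if len(set(y_true.tolist())) == 2 else float("nan")
    return MeasurePanel(
        auc=auc, **confusion_measures(counts), counts=counts,
        classifier=classifier, pooled_scores=(np.asarray(scores, float), y_true),
    )


# ----------------------------------------------------------------------
# cross-validation engines
# ----------------------------------------------------------------------

def _fit_predict(spec: ClassifierSpec, X_train, y_train, X_test):
    """Fit one fold and return (scores, hard predictions) for X_test."""
    if spec.standardize:
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd[sd == 0] = 1.0
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd
    clf = spec.build().fit(X_train, y_train)
    if spec.name == "svm":
        scores = clf.decision_function(X_test)
        preds = (scores > 0).astype(int)
    else:
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        scores = clf.predict_proba(X_test)[:, pos_col]
        preds = clf.predict(X_test).astype(int)
    return scores, preds


def loocv_panel(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec):
    """Pooled leave-one-out evaluation of one classifier on raw arrays.

    Returns ``(MeasurePanel, n_skipped)`` where skipped folds are those whose
    training portion contained a single class.
    """
    n = len(y)
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    kept = np.zeros(n, dtype=bool)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        y_train = y[mask]
        if y_train.min() == y_train.max():
            mask[i] = True
            continue
        s, p = _fit_predict(spec, X[mask], y_train, X[i:i + 1])
        scores[i], preds[i] = s[0], p[0]
        kept[i] = True
        mask[i] = True
    if not kept.any():
        raise CanesError("every LOOCV fold had a single training class")
    panel = panel_from_predictions(y[kept], preds[kept], scores[kept], spec.name)
    return panel, int(n - kept.sum())


def _check_feature_matrix(X):
    if np.isnan(X).any():
        raise CanesError("marker rows contain missing values; impute first")


def _prepare(ds: ExpressionDataset, markers, positive_label):
    if not isinstance(markers, MarkerSet):
        markers = resolve_markers(markers, ds)
    X = ds.feature_matrix(markers.indices)
    _check_feature_matrix(X)
    y = ds.binary_labels(positive_label)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise CanesError("each class needs at least 2 samples")
    return markers, X, y


def evaluate_loocv(ds: ExpressionDataset, markers, classifiers=None,
                   positive_label: str = DEFAULT_POSITIVE_LABEL) -> EvaluationResult:
    """Leave-one-out evaluation of a marker panel (scheme iii).

    ``markers`` may be a :class:`MarkerSet` or a list of names to resolve.
    """
    markers, X, y = _prepare(ds, markers, positive_label)
    classifiers = classifiers or default_classifiers()
    per, skipped = {}, {}
    for spec in classifiers:
        panel, n_skip = loocv_panel(X, y, spec)
        per[spec.name] = panel
        skipped[spec.name] = n_skip
    return EvaluationResult(
        per_classifier=per, average=average_panel(per.values()),
        scheme="loocv", skipped_folds=skipped,
    )


# ----------------------------------------------------------------------
# train/test and stored models (schemes i, ii, iv)
# ----------------------------------------------------------------------

STORED_MODEL_VERSION = 1


@dataclass
class StoredModel:
    """A fitted, reusable panel model (one estimator per classifier).

    Cross-dataset portability requires a fixed feature dimension, so each
    marker *name* contributes one feature: the mean of its member probe rows
    in whichever dataset the model is applied to.
    """

    names: list
    classifiers: list            # ClassifierSpec, in fit order
    estimators: dict             # name -> fitted sklearn estimator
    scalers: dict                # name -> (mu, sd) or None
    positive_label: str
    version: int = STORED_MODEL_VERSION

    def save(self, path):
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path) -> "StoredModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, StoredModel):
            raise CanesError(f"{path} is not a stored panel model")
        return model

    def feature_matrix(self, ds: ExpressionDataset) -> np.ndarray:
        markers = resolve_markers(self.names, ds)
        if markers.unmatched:
            raise CanesError(
                f"model markers not resolvable in {ds.dataset_id or 'test set'}: "
                f"{markers.unmatched}"
            )
        cols = [ds.values[markers.by_name[n]].mean(axis=0) for n in self.names]
        X = np.column_stack(cols)
        _check_feature_matrix(X)
        return X

    def evaluate(self, test: ExpressionDataset) -> EvaluationResult:
        X = self.feature_matrix(test)
        y = test.binary_labels(self.positive_label)
        per = {}
        for spec in self.classifiers:
            Xs = X
            if self.scalers[spec.name] is not None:
                mu, sd = self.scalers[spec.name]
                Xs = (X - mu) / sd
            clf = self.estimators[spec.name]
            if spec.name == "svm":
                scores = clf.decision_function(Xs)
                preds = (scores > 0).astype(int)
            else:
                pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
                scores = clf.predict_proba(Xs)[:, pos_col]
                preds = clf.predict(Xs).astype(int)
            per[spec.name] = panel_from_predictions(y, preds, scores, spec.name)
        return EvaluationResult(
            per_classifier=per, average=average_panel(per.values()),
            scheme="stored_model",
        )


def fit_panel_model(train: ExpressionDataset, names, classifiers=None,
                    positive_label: str = DEFAULT_POSITIVE_LABEL) -> StoredModel:
    """Fit all classifiers once on the full training dataset."""
    classifiers = classifiers or default_classifiers()
    markers = resolve_markers(names, train)
    names = markers.resolved_names()
    cols = [train.values[markers.by_name[n]].mean(axis=0) for n in names]
    X = np.column_stack(cols)
    _check_feature_matrix(X)
    y = train.binary_labels(positive_label)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise CanesError("each training class needs at least 2 samples")
    estimators, scalers = {}, {}
    for spec in classifiers:
        Xs = X
        if spec.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            scalers[spec.name] = (mu, sd)
            Xs = (X - mu) / sd
        else:
            scalers[spec.name] = None
        estimators[spec.name] = spec.build().fit(Xs, y)
    return StoredModel(
        names=list(names), classifiers=list(classifiers),
        estimators=estimators, scalers=scalers, positive_label=positive_label,
    )


def evaluate_train_test(train: ExpressionDataset, test: ExpressionDataset,
                        names, classifiers=None,
                        positive_label: str = DEFAULT_POSITIVE_LABEL):
    """Scheme i/iv: fit on ``train``, measure on ``test``.

    Returns ``(EvaluationResult, StoredModel)``; the model can be re-applied
    to any dataset where every marker name resolves (scheme ii).
    """
    model = fit_panel_model(train, names, classifiers, positive_label)
    result = model.evaluate(test)
    result.scheme = "train_test"
    return result, model


# ----------------------------------------------------------------------
# fast internal path used by the empirical-null machinery
# ----------------------------------------------------------------------

def averaged_measures_loocv(X, y, classifiers) -> dict:
    """All ten measures averaged over classifiers, from raw arrays."""
    panels = [loocv_panel(X, y, spec)[0] for spec in classifiers]
    return average_panel(panels).as_dict()
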