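"""Multiclass identification: classifiers, metrics, majority voting.

Four classifiers are compared: k-nearest neighbours (Euclidean metric,
k = 5 by default), a CART-style decision tree, a random forest whose
prediction is the argmax of averaged per-tree class probabilities, and a
Gaussian naive Bayes model P(y | x_1..x_n) ~ P(y) * prod P(x_i | y).

Evaluation happens at two levels.  Per vector: accuracy, a full confusion
matrix with per-class sensitivity TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP) and F1 (harmonic mean of precision and recall;
precision and F1 are flagged undefined when TP+FP = 0), and macro
one-vs-rest ROC/AUC.  Per subject: majority voting over the subject's test
vectors, which can exceed per-vector accuracy whenever per-vector accuracy
beats chance.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .exceptions import (EvaluationError, FitError, LabelError, VotingError)
from .vectors import (DatasetSplit, FeatureVector, SCHEME_SESSION,
                      SCHEME_STRATIFIED, session_split, stratified_split)

ALGORITHMS = ("knn", "decision_tree", "random_forest", "naive_bayes")


@dataclass
class ClassifierModel:
    """A fitted classifier plus the metadata needed to evaluate it."""

    algorithm: str
    hyperparams: dict
    estimator: object
    classes: np.ndarray

    def predict(self, vectors: list[FeatureVector]) -> np.ndarray:
        return self.estimator.predict(_stack(vectors))

    def predict_proba(self, vectors: list[FeatureVector]) -> np.ndarray:
        return self.estimator.predict_proba(_stack(vectors))


def _stack(vectors: list[FeatureVector]) -> np.ndarray:
    return np.vstack([v.values for v in vectors])


def fit(algorithm: str, train: list[FeatureVector],
        hyperparams: dict | None = None, seed: int = 0) -> ClassifierModel:
    """Fit one of the four classifiers on labelled feature vectors.

    ``hyperparams``: ``k`` for knn (default 5), ``n_trees`` for the forest
    (default 100); the tree and naive Bayes take none.
    """
    hp = dict(hyperparams or {})
    if algorithm == "knn":
        est = KNeighborsClassifier(n_neighbors=hp.get("k", 5), metric="euclidean")
    elif algorithm == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed)
    elif algorithm == "random_forest":
        est = RandomForestClassifier(n_estimators=hp.get("n_trees", 100),
                                     random_state=seed)
    elif algorithm == "naive_bayes":
        est = GaussianNB()
    else:
        raise FitError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    X, y = _stack(train), np.array([v.subject_id for v in train])
    if len(np.unique(y)) < 2:
        raise FitError("training set contains a single class")
    est.fit(X, y)
    return ClassifierModel(algorithm=algorithm, hyperparams=hp,
                           estimator=est, classes=est.classes_)


def vector_accuracy(model: ClassifierModel,
                    test: list[FeatureVector]) -> float:
    """Fraction of correctly classified test vectors."""
    if not test:
        raise EvaluationError("empty test set")
    pred = model.predict(test)
    true = np.array([v.subject_id for v in test])
    return float(np.mean(pred == true))


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    labels: tuple

    def _i(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise LabelError(f"unknown label {label!r}") from None

    def tp(self, label) -> int:
        i = self._i(label)
        return int(self.counts[i, i])

    def fn(self, label) -> int:
        i = self._i(label)
        return int(self.counts[i].sum() - self.counts[i, i])

    def fp(self, label) -> int:
        i = self._i(label)
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def tn(self, label) -> int:
        i = self._i(label)
        return int(self.counts.sum() - self.counts[i].sum()
                   - self.counts[:, i].sum() + self.counts[i, i])


def confusion(true_labels, predicted_labels, labels=None) -> ConfusionMatrix:
    """Count matrix: counts[i, j] = #{true = labels[i], predicted = labels[j]}."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise EvaluationError("label lists differ in length")
    if labels is None:
        labels = sorted(set(true_labels) | set(predicted_labels))
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise LabelError(f"label {t if t not in index else p!r} not in "
                             f"{labels}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class sensitivity/specificity/precision/F1; None = undefined."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None


def class_metrics(cm: ConfusionMatrix, label) -> ClassMetrics:
    """Sensitivity, specificity, precision and F1 for one class.

    Precision (and hence F1) is undefined — returned as None — when the
    class was never predicted (TP + FP = 0).
    """
    tp, fn = cm.tp(label), cm.fn(label)
    fp, tn = cm.fp(label), cm.tn(label)
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    prec = tp / (tp + fp) if tp + fp else None
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * sens * prec / (sens + prec)
    return ClassMetrics(sensitivity=sens, specificity=spec,
                        precision=prec, f1=f1)


def macro_roc_auc(model: ClassifierModel,
                  test: list[FeatureVector]) -> tuple[dict, float]:
    """One-vs-rest ROC AUC per class and their unweighted (macro) mean.

    Classes absent from the test set are skipped with a warning since
    their ROC curve is undefined.
    """
    if not test:
        raise EvaluationError("empty test set")
    proba = model.predict_proba(test)
    true = np.array([v.subject_id for v in test])
    per_class: dict = {}
    for j, cls in enumerate(model.classes):
        pos = true == cls
        if not pos.any():
            warnings.warn(f"class {cls} absent from test set; AUC skipped")
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), proba[:, j])
        per_class[cls] = float(auc(fpr, tpr))
    if not per_class:
        raise EvaluationError("no class present in the test set")
    return per_class, float(np.mean(list(per_class.values())))


def macro_roc_curve(model: ClassifierModel, test: list[FeatureVector],
                    grid_size: int = 101):
    """Macro-average ROC curve: per-class TPR linearly interpolated onto a
    shared FPR grid and averaged."""
    proba = model.predict_proba(test)
    true = np.array([v.subject_id for v in test])
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    for j, cls in enumerate(model.classes):
        pos = true == cls
        if not pos.any():
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), proba[:, j])
        tprs.append(np.interp(grid, fpr, tpr))
    if not tprs:
        raise EvaluationError("no class present in the test set")
    return grid, np.mean(tprs, axis=0)


def majority_vote(predicted_labels) -> object:
    """Most frequent label; ties broken by the smallest label."""
    predicted_labels = list(predicted_labels)
    if not predicted_labels:
        raise VotingError("cannot vote on an empty prediction list")
    counts = Counter(predicted_labels)
    top = max(counts.values())
    return min(lab for lab, c in counts.items() if c == top)


def subject_accuracy(test: list[FeatureVector], predicted_labels,
                     expected_subjects=None) -> tuple[float, int]:
    """Majority-vote identification accuracy at the subject level.

    Returns (fraction of subjects voted correctly, count correct).
    """
    predicted_labels = list(predicted_labels)
    if len(predicted_labels) != len(test):
        raise EvaluationError("one prediction per test vector required")
    by_subject: dict = {}
    for v, p in zip(test, predicted_labels):
        by_subject.setdefault(v.subject_id, []).append(p)
    if expected_subjects is not None:
        missing = set(expected_subjects) - set(by_subject)
        if missing:
            raise EvaluationError(
                f"subjects {sorted(missing)} have no test vectors")
    correct = sum(1 for s, preds in by_subject.items()
                  if majority_vote(preds) == s)
    return correct / len(by_subject), correct


@dataclass
class SingleRun:
    """Metrics of one (algorithm, split) evaluation."""

    algorithm: str
    scheme: str
    seed: int | None
    vector_accuracy: float
    macro_auc: float
    subject_accuracy: float
    subjects_correct: int
    n_subjects: int
    mean_sensitivity: float
    mean_specificity: float
    mean_precision: float | None
    mean_f1: float | None
    n_undefined_precision: int


@dataclass
class RunReport:
    """Per-run metrics plus mean/sd aggregates over repeated splits."""

    runs: list[SingleRun]
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"runs": [vars(r) for r in self.runs], "summary": self.summary}


_AGG_FIELDS = ("vector_accuracy", "macro_auc", "subject_accuracy",
               "subjects_correct", "mean_sensitivity", "mean_specificity",
               "mean_precision", "mean_f1")


def evaluate_split(model: ClassifierModel, split: DatasetSplit) -> SingleRun:
    """All per-vector and subject-level metrics for one fitted model."""
    pred = model.predict(split.test)
    true = [v.subject_id for v in split.test]
    cm = confusion(true, pred, labels=sorted(model.classes))
    metrics = [class_metrics(cm, c) for c in cm.labels]
    undefined = sum(1 for m in metrics if m.precision is None)
    defined_p = [m.precision for m in metrics if m.precision is not None]
    defined_f = [m.f1 for m in metrics if m.f1 is not None]
    sens = [m.sensitivity for m in metrics if m.sensitivity is not None]
    spec = [m.specificity for m in metrics if m.specificity is not None]
    _, macro = macro_roc_auc(model, split.test)
    subj_frac, subj_n = subject_accuracy(split.test, pred)
    return SingleRun(
        algorithm=model.algorithm, scheme=split.scheme, seed=split.seed,
        vector_accuracy=float(np.mean(np.asarray(pred) == np.asarray(true))),
        macro_auc=macro,
        subject_accuracy=subj_frac, subjects_correct=subj_n,
        n_subjects=len({v.subject_id for v in split.test}),
        mean_sensitivity=float(np.mean(sens)),
        mean_specificity=float(np.mean(spec)),
        mean_precision=float(np.mean(defined_p)) if defined_p else None,
        mean_f1=float(np.mean(defined_f)) if defined_f else None,
        n_undefined_precision=undefined,
    )


def repeat_runs(vectors: list[FeatureVector],
                algorithms=ALGORITHMS,
                scheme: str = SCHEME_STRATIFIED,
                n_repeats: int = 10,
                seeds=None,
                train_fraction: float = 0.75,
                train_session: int = 1,
                hyperparams: dict | None = None) -> RunReport:
    """Repeat split → fit → evaluate and aggregate mean/sd per algorithm.

    Under the stratified scheme each seed draws a fresh random split; under
    the session-disjoint scheme the split is fixed and seeds only affect
    classifier randomness.
    """
    if n_repeats < 1:
        raise EvaluationError("need at least one repeat")
    if seeds is None:
        seeds = list(range(n_repeats))
    seeds = list(seeds)[:n_repeats]
    hyperparams = hyperparams or {}
    runs = []
    for seed in seeds:
        if scheme == SCHEME_STRATIFIED:
            split = stratified_split(vectors, train_fraction, seed)
        elif scheme == SCHEME_SESSION:
            split = session_split(vectors, train_session)
            split.seed = seed
        else:
            raise EvaluationError(f"unknown scheme {scheme!r}")
        for algo in algorithms:
            model = fit(algo, split.train, hyperparams.get(algo), seed=seed)
            runs.append(evaluate_split(model, split))
    summary: dict = {}
    for algo in algorithms:
        rs = [r for r in runs if r.algorithm == algo]
        agg = {}
        for name in _AGG_FIELDS:
            vals = [getattr(r, name) for r in rs if getattr(r, name) is not None]
            if vals:
                agg[name] = {"mean": float(np.mean(vals)),
                             "sd": float(np.std(vals))}
            else:
                agg[name] = {"mean": None, "sd": None}
        agg["n_undefined_precision"] = int(
            sum(r.n_undefined_precision for r in rs))
        summary[algo] = agg
    return RunReport(runs=runs, summary=summary)
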