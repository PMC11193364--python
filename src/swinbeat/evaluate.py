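"""Cross-validation fold plans, classification metrics, and aggregation.

Two 10-fold paradigms are supported:

* **intra-patient** — beats are partitioned at random regardless of origin,
  so the same subject's beats can appear in both the training and
  validation sides of a fold;
* **inter-patient** — subjects are partitioned into ten groups and fold *i*
  validates on all beats of group *i*, so no subject ever contributes to
  both sides. This is the clinically honest protocol.

Per-fold metrics are one-vs-rest precision, sensitivity (recall),
specificity and F1 per class, macro-averaged, overall accuracy
(trace/total of the confusion matrix) and macro one-vs-rest ROC AUC from
the softmax scores. Fold means carry normal-approximation 95% confidence
intervals, mean +/- 1.96 * sd / sqrt(k), clipped to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "FoldPlan", "MetricsReport", "make_folds", "confusion_matrix",
    "evaluate", "evaluate_from_confusion", "aggregate", "crossval_images",
]

_METRICS = ("accuracy", "precision", "sensitivity", "specificity", "f1", "auc")


@dataclass
class FoldPlan:
    """k disjoint validation index sets covering the dataset."""

    paradigm: str
    folds: list[np.ndarray]
    n: int
    subject_map: np.ndarray | None = None

    def train_indices(self, i: int) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[self.folds[i]] = False
        return np.flatnonzero(mask)


@dataclass
class MetricsReport:
    """Classification metrics with optional per-fold confidence intervals."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    confusion: np.ndarray
    classes: list[str]
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n: int = 0

    def as_dict(self) -> dict:
        out = {m: getattr(self, m) for m in _METRICS}
        out["n"] = self.n
        out["classes"] = list(self.classes)
        out["confusion"] = np.asarray(self.confusion).tolist()
        if self.per_class:
            out["per_class"] = self.per_class
        if self.ci:
            out["ci"] = {k: list(v) for k, v in self.ci.items()}
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def make_folds(labels: np.ndarray, paradigm: str = "intra", k: int = 10,
               seed: int = 0, subjects: np.ndarray | None = None) -> FoldPlan:
    """Deterministic k-fold plan at the beat or subject level.

    ``subjects`` is required under the inter-patient paradigm; every fold's
    validation set is the union of all beats of one subject group.
    """
    n = len(labels)
    rng = np.random.default_rng(seed)
    if paradigm == "intra":
        if n < k:
            raise ValueError(f"need at least {k} beats, have {n}")
        folds = [np.sort(f) for f in np.array_split(rng.permutation(n), k)]
        subj = None if subjects is None else np.asarray(subjects)
    elif paradigm == "inter":
        if subjects is None:
            raise ValueError("inter-patient folds require a subject per beat")
        subj = np.asarray(subjects)
        uniq = np.unique(subj)
        if len(uniq) < k:
            raise ValueError(
                f"need at least {k} subjects for inter-patient folds, "
                f"have {len(uniq)}")
        groups = np.array_split(rng.permutation(uniq), k)
        folds = [np.flatnonzero(np.isin(subj, g)) for g in groups]
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    return FoldPlan(paradigm=paradigm, folds=folds, n=n, subject_map=subj)


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """Count matrix with true class on rows, predicted on columns."""
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def evaluate_from_confusion(cm: np.ndarray, classes,
                            auc: float = float("nan")) -> MetricsReport:
    """One-vs-rest metrics from a confusion matrix (macro averages).

    Classes absent from the test set (empty row) have undefined metrics;
    they are reported as NaN per class and excluded from the macro mean.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)
    per_class: dict[str, dict[str, float]] = {}
    macro: dict[str, list[float]] = {m: [] for m in
                                     ("precision", "sensitivity",
                                      "specificity", "f1")}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:  # class absent from test set
            per_class[str(c)] = {m: float("nan") for m in macro}
            continue
        prec = tp / (tp + fp) if tp + fp else 0.0
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        vals = {"precision": prec, "sensitivity": sens,
                "specificity": spec, "f1": f1}
        per_class[str(c)] = {m: float(v) for m, v in vals.items()}
        for m, v in vals.items():
            macro[m].append(v)
    means = {m: float(np.mean(v)) for m, v in macro.items()}
    return MetricsReport(accuracy=accuracy, auc=auc, confusion=cm,
                         classes=[str(c) for c in classes],
                         per_class=per_class, n=int(total), **means)


def _macro_ovr_auc(y_true: np.ndarray, proba: np.ndarray, classes) -> float:
    """Macro one-vs-rest ROC AUC; classes without both outcomes excluded."""
    aucs = []
    for i, c in enumerate(classes):
        pos = (y_true == c)
        if pos.all() or not pos.any():
            continue
        aucs.append(roc_auc_score(pos, proba[:, i]))
    return float(np.mean(aucs)) if aucs else float("nan")


def evaluate(y_true, proba, classes) -> MetricsReport:
    """Metrics for predicted class scores ``proba`` (n, n_classes).

    The predicted label is the argmax of each row; AUC uses the scores
    directly.
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    classes = list(classes)
    y_pred = np.asarray(classes, dtype=y_true.dtype)[np.argmax(proba, axis=1)]
    cm = confusion_matrix(y_true, y_pred, classes)
    return evaluate_from_confusion(cm, classes,
                                   auc=_macro_ovr_auc(y_true, proba, classes))


def aggregate(reports: list[MetricsReport]) -> MetricsReport:
    """Fold means with 95% normal-approximation confidence intervals."""
    k = len(reports)
    if k < 2:
        raise ValueError("need at least 2 fold reports to aggregate")
    ci: dict[str, tuple[float, float]] = {}
    means: dict[str, float] = {}
    for m in _METRICS:
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        vals = vals[np.isfinite(vals)]
        mean = float(vals.mean())
        half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 \
            else 0.0
        ci[m] = (max(0.0, mean - half), min(1.0, mean + half))
        means[m] = mean
    cm = np.sum([r.confusion for r in reports], axis=0)
    return MetricsReport(confusion=cm, classes=reports[0].classes, ci=ci,
                         n=int(cm.sum()), **means)


def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    """Per-fold metric table (one row per fold)."""
    return pd.DataFrame([{m: getattr(r, m) for m in _METRICS} | {"n": r.n}
                         for r in reports])


def crossval_images(X: np.ndarray, y: np.ndarray, estimator,
                    paradigm: str = "intra", k: int = 10, seed: int = 0,
                    subjects: np.ndarray | None = None,
                    ) -> tuple[MetricsReport, list[MetricsReport]]:
    """k-fold cross-validation of a classifier on rendered images.

    Clones the estimator per fold (fresh initialization), fits on the
    training side and scores the validation side. Returns the aggregated
    report (with CIs) and the per-fold reports.
    """
    from sklearn.base import clone

    y = np.asarray(y)
    plan = make_folds(y, paradigm=paradigm, k=k, seed=seed, subjects=subjects)
    classes = np.unique(y)
    reports = []
    for i in range(k):
        tr, va = plan.train_indices(i), plan.folds[i]
        clf = clone(estimator)
        clf.fit(X[tr], y[tr])
        proba_local = clf.predict_proba(X[va])
        # re-align fold-local class order onto the global class list
        proba = np.zeros((len(va), len(classes)))
        for j, c in enumerate(clf.classes_):
            proba[:, np.flatnonzero(classes == c)[0]] = proba_local[:, j]
        reports.append(evaluate(y[va], proba, classes))
    return aggregate(reports), reports
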