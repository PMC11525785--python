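"""Leakage-controlled LOOCV classification of treatment response.

Subjects (non-remitted vs remitted) are classified from the feature table by
leave-one-out cross-validation. Inside every fold, and strictly from the
training subjects only: features are ranked by Fisher score, the top k
(k = 1..15) are kept, z-normalized with training mean and standard
deviation, and four classifiers are fitted — linear discriminant analysis,
linear-kernel SVM, k-nearest neighbours and Gaussian naive Bayes. The
held-out subject never influences selection, normalization or fitting; the
fold records keep the selected feature names and normalization statistics so
this can be asserted directly.

The non-remitted group is the positive (reference) class: sensitivity is the
fraction of non-remitted subjects correctly identified. With N subjects
every accuracy is an exact multiple of 1/N. ROC curves pool the decision
scores across folds of one (k, classifier) configuration; AUC is the
trapezoidal area. The best configuration is chosen by accuracy with ties
broken toward fewer features, then by the fixed classifier order
LDA > SVM > KNN > NB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

CLASSIFIER_ORDER = ("LDA", "SVM", "KNN", "NB")


def make_classifiers(svm_c: float = 1.0, knn_k: int = 5) -> dict:
    """Factories for the four classifiers with deterministic settings."""
    return {
        "LDA": lambda: LinearDiscriminantAnalysis(solver="lsqr",
                                                  shrinkage=None),
        "SVM": lambda: SVC(kernel="linear", C=svm_c),
        "KNN": lambda: KNeighborsClassifier(n_neighbors=knn_k,
                                            metric="euclidean"),
        "NB": lambda: GaussianNB(),
    }


def fisher_score(x: np.ndarray, y: np.ndarray,
                 variant: str = "two_class") -> np.ndarray:
    """Univariate class-separability score per feature.

    ``two_class`` (default): F = (μ₁ − μ₂)² / (σ₁² + σ₂²) with unbiased
    class variances. ``generalized``: Σ n_c (μ_c − μ)² / Σ n_c σ_c², the
    class-size-weighted form. A zero denominator yields a score of 0 (the
    feature cannot discriminate anything it does not vary on).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("Fisher score requires exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least 2 training samples")
    mus = np.array([x[y == c].mean(axis=0) for c in classes])
    var = np.array([x[y == c].var(axis=0, ddof=1) for c in classes])
    if variant == "two_class":
        num = (mus[0] - mus[1]) ** 2
        den = var[0] + var[1]
    elif variant == "generalized":
        ns = np.array([(y == c).sum() for c in classes], dtype=float)
        mu = x.mean(axis=0)
        num = (ns[:, None] * (mus - mu) ** 2).sum(axis=0)
        den = (ns[:, None] * var).sum(axis=0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return score


@dataclass
class FoldRecord:
    held_out: str
    k: int
    classifier: str
    selected: tuple[str, ...]
    train_mean: np.ndarray
    train_sd: np.ndarray
    true_label: str
    predicted: str
    score: float                # decision score toward the positive class


@dataclass
class CVResult:
    metrics: pd.DataFrame       # per (k, classifier): accuracy/sens/spec
    folds: dict                 # (k, classifier) → list[FoldRecord]
    best_k: int
    best_classifier: str
    positive: str
    roc: dict = field(default_factory=dict)  # fpr, tpr, thresholds, auc

    def fold_frame(self) -> pd.DataFrame:
        rows = []
        for (k, clf), recs in self.folds.items():
            for r in recs:
                rows.append({"k": k, "classifier": clf,
                             "held_out": r.held_out, "true": r.true_label,
                             "predicted": r.predicted, "score": r.score,
                             "selected": ";".join(r.selected)})
        return pd.DataFrame(rows)


def _score_and_predict(est, xt: np.ndarray, positive) -> tuple[float, str]:
    """Decision score toward the positive class + the implied prediction.

    For margin classifiers the binary prediction is the sign of the decision
    function (sklearn's own rule), for probabilistic ones the argmax of the
    class probabilities; deriving the label from the same call avoids a
    second pass through the estimator.
    """
    if hasattr(est, "decision_function"):
        s = float(np.atleast_1d(est.decision_function(xt))[0])
        pred = est.classes_[1] if s > 0 else est.classes_[0]
        # sklearn's decision_function is oriented toward classes_[1]
        return (s if est.classes_[1] == positive else -s), str(pred)
    proba = est.predict_proba(xt)[0]
    pos_idx = list(est.classes_).index(positive)
    return float(proba[pos_idx]), str(est.classes_[int(np.argmax(proba))])


def loocv(features: pd.DataFrame, label_col: str = "group",
          positive: str = "nrMDD", k_range: tuple[int, int] = (1, 15),
          classifiers: dict | None = None,
          fisher_variant: str = "two_class",
          k_values: list[int] | None = None) -> CVResult:
    """Leave-one-subject-out cross-validation over the (k, classifier) grid.

    ``features`` has one row per subject, named feature columns and a label
    column restricted to the two classes of interest. ``k_values`` overrides
    the dense ``k_range`` with an explicit feature-count grid (useful for
    permutation runs where a coarser grid keeps the procedure identical
    between observed and permuted data at a fraction of the cost).
    """
    import sklearn

    classifiers = classifiers or make_classifiers()
    y = features[label_col].to_numpy()
    cols = [c for c in features.columns if c != label_col]
    x = features[cols].to_numpy(dtype=float)
    subjects = features.index.to_numpy()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not present")
    if k_values is None:
        ks = list(range(k_range[0], min(k_range[1], len(cols)) + 1))
    else:
        ks = sorted(k for k in k_values if k <= len(cols))

    folds: dict = {(k, c): [] for k in ks for c in classifiers}
    estimators = {name: factory() for name, factory in classifiers.items()}
    with sklearn.config_context(assume_finite=True,
                                skip_parameter_validation=True):
        for i in range(n):
            train = np.arange(n) != i
            ytr = y[train]
            if np.unique(ytr).size < 2:
                raise ValueError("a training fold lost one class entirely")
            xtr_full = x[train]
            scores = fisher_score(xtr_full, ytr, fisher_variant)
            # stable sort: ties broken by fixed column order
            order = np.argsort(-scores, kind="stable")
            for k in ks:
                sel = order[:k]
                mu = xtr_full[:, sel].mean(axis=0)
                sd = xtr_full[:, sel].std(axis=0, ddof=1)
                sd = np.where(sd > 0, sd, 1.0)
                xtr = (xtr_full[:, sel] - mu) / sd
                xte = (x[i:i + 1, sel] - mu) / sd
                for name, est in estimators.items():
                    est.fit(xtr, ytr)
                    sc, pred = _score_and_predict(est, xte, positive)
                    folds[(k, name)].append(FoldRecord(
                        held_out=str(subjects[i]), k=k, classifier=name,
                        selected=tuple(cols[j] for j in sel),
                        train_mean=mu, train_sd=sd, true_label=str(y[i]),
                        predicted=pred, score=sc))

    rows = []
    for (k, name), recs in folds.items():
        yt = np.array([r.true_label for r in recs])
        yp = np.array([r.predicted for r in recs])
        tp = np.sum((yt == positive) & (yp == positive))
        tn = np.sum((yt != positive) & (yp != positive))
        fn = np.sum((yt == positive) & (yp != positive))
        fp = np.sum((yt != positive) & (yp == positive))
        rows.append({"k": k, "classifier": name,
                     "accuracy": (tp + tn) / n,
                     "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                     "specificity": tn / (tn + fp) if tn + fp else np.nan})
    metrics = pd.DataFrame(rows)

    clf_rank = {c: i for i, c in enumerate(CLASSIFIER_ORDER)}
    ranked = metrics.assign(
        _rank=metrics["classifier"].map(lambda c: clf_rank.get(c, 99)))
    ranked = ranked.sort_values(["accuracy", "k", "_rank"],
                                ascending=[False, True, True],
                                kind="stable")
    best = ranked.iloc[0]
    best_k, best_clf = int(best["k"]), str(best["classifier"])

    recs = folds[(best_k, best_clf)]
    pooled = np.array([r.score for r in recs])
    labels = np.array([r.true_label for r in recs])
    roc = roc_auc(pooled, labels, positive)
    return CVResult(metrics=metrics, folds=folds, best_k=best_k,
                    best_classifier=best_clf, positive=positive, roc=roc)


def roc_auc(scores: np.ndarray, labels: np.ndarray, positive: str) -> dict:
    """ROC by threshold sweep over pooled decision scores + trapezoidal AUC."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=float),
                              pos_label=positive)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thr,
            "auc": float(_trapezoid_auc(fpr, tpr))}
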