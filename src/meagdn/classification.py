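"""Condition classification under leave-one-well-out cross-validation.

Rows are (segment, selected time offset) observations of the selected,
baseline-normalized descriptors; the group structure is the well, so every
cross-validation fold holds out one entire well (no within-well leakage).
Per-row ("single time point") accuracy and per-well majority-voting accuracy
are both reported. The primary model is a linear discriminant with automatic
shrinkage of the pooled covariance (the rows are numerous but collinear);
an RBF-kernel SVM and a k-NN classifier with default settings serve as
comparators under the identical protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ConfigError, DataError
from .feature_selection import SelectionResult

logger = logging.getLogger(__name__)

CLASSES = ("CTRL", "VPA")
CLASSIFIER_NAMES = ("lda", "svm", "knn")


@dataclass
class SampleTable:
    """Classification-ready rows for one session."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    session: str
    offsets: list
    features: list

    def __len__(self) -> int:
        return len(self.X)

    @property
    def wells(self) -> list:
        return sorted(set(self.groups))


@dataclass
class FoldResult:
    """Predictions for one held-out well."""

    well: str
    y_true: np.ndarray
    y_pred: np.ndarray
    well_label_true: str
    well_label_pred: str
    mean_score: float = 0.0

    @property
    def n_rows(self) -> int:
        return len(self.y_true)


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the supported classifiers by name."""
    name = name.lower()
    if name == "lda":
        # lsqr + automatic shrinkage keeps the pooled covariance invertible
        # in the presence of collinear descriptor rows
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if name == "svm":
        return SVC(random_state=seed)     # RBF kernel, default settings
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    raise ConfigError(f"unknown classifier {name!r}; allowed: {CLASSIFIER_NAMES}")


def build_samples(norm_features: pd.DataFrame, selection: SelectionResult,
                  session: str | None = None) -> SampleTable:
    """Restrict the normalized feature table to the selected offsets and
    features of one session.

    The 0h session is baseline-only and cannot be requested. Rows with an
    unusable (NaN) selected feature are dropped.
    """
    if session is None:
        session = selection.session
    if session == "0h":
        raise DataError("the 0h session is consumed by normalization only")
    if not selection.offsets or not selection.features:
        raise DataError("empty selection")
    sdf = norm_features[(norm_features["session"] == session)
                        & norm_features["time_offset"].isin(selection.offsets)]
    if sdf.empty:
        raise DataError(f"no rows at the selected offsets for session {session!r}")
    missing = [f for f in selection.features if f not in sdf.columns]
    if missing:
        raise DataError(f"selected features missing from the table: {missing}")
    sdf = sdf.dropna(subset=selection.features)
    return SampleTable(X=sdf[list(selection.features)].reset_index(drop=True),
                       y=sdf["condition"].to_numpy(),
                       groups=sdf["well_id"].to_numpy(),
                       session=session, offsets=list(selection.offsets),
                       features=list(selection.features))


def majority_vote(row_predictions: np.ndarray,
                  scores: np.ndarray | None = None) -> str:
    """Modal label of a well's row predictions; an exact tie is broken by the
    sign of the mean decision score (positive favors the positive class)."""
    labels, counts = np.unique(np.asarray(row_predictions), return_counts=True)
    top = counts == counts.max()
    if top.sum() == 1:
        return str(labels[np.argmax(counts)])
    if scores is not None:
        return CLASSES[1] if float(np.mean(scores)) > 0 else CLASSES[0]
    return str(sorted(labels[top])[0])


def _decision_scores(clf, X) -> np.ndarray | None:
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=np.float64)
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
        pos = list(clf.classes_).index(CLASSES[1]) if CLASSES[1] in clf.classes_ else -1
        return proba[:, pos] - 0.5
    return None


def lowo_cv(samples: SampleTable, classifier="lda", seed: int = 0) -> list:
    """Leave-one-well-out cross-validation: one fold per well.

    A fold whose training set lacks a class is skipped with a warning.
    Returns the list of FoldResult.
    """
    wells = samples.wells
    if len(wells) < 2:
        raise DataError("at least two wells are required for LOWO")
    clf_proto = (make_classifier(classifier, seed)
                 if isinstance(classifier, str) else classifier)
    folds = []
    X = samples.X.to_numpy(dtype=np.float64)
    for well in wells:
        test = samples.groups == well
        train = ~test
        if len(set(samples.y[train])) < 2:
            logger.warning("fold %s skipped: training set lacks a class", well)
            continue
        clf = clone(clf_proto)
        clf.fit(X[train], samples.y[train])
        y_pred = np.asarray(clf.predict(X[test]))
        scores = _decision_scores(clf, X[test])
        well_pred = majority_vote(y_pred, scores)
        folds.append(FoldResult(
            well=str(well), y_true=samples.y[test], y_pred=y_pred,
            well_label_true=str(samples.y[test][0]), well_label_pred=well_pred,
            mean_score=float(np.mean(scores)) if scores is not None else 0.0))
    return folds


def pooled_accuracy(folds: list) -> float:
    """Single-time-point accuracy pooled over every row of every fold."""
    correct = sum(int(np.sum(f.y_true == f.y_pred)) for f in folds)
    total = sum(f.n_rows for f in folds)
    return correct / total


def majority_accuracy(folds: list) -> float:
    """Fraction of wells whose majority-vote label is correct."""
    return float(np.mean([f.well_label_true == f.well_label_pred for f in folds]))


def confusion_matrix(folds: list, per_well: bool = False) -> pd.DataFrame:
    """Row-true / column-predicted confusion counts (per row or per well)."""
    cm = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for f in folds:
        if per_well:
            cm.loc[f.well_label_true, f.well_label_pred] += 1
        else:
            for t, p in zip(f.y_true, f.y_pred):
                cm.loc[t, p] += 1
    return cm


def cross_session_transfer(train_samples: SampleTable,
                           test_samples: SampleTable,
                           classifier="lda", seed: int = 0) -> dict:
    """Train on every row of one session and evaluate on another session's
    rows built with the training session's selection (same features and
    offsets)."""
    if train_samples.features != test_samples.features:
        raise DataError("feature mismatch between sessions: transfer requires "
                        "the training session's selection applied to both")
    clf = (make_classifier(classifier, seed)
           if isinstance(classifier, str) else clone(classifier))
    if len(set(train_samples.y)) < 2:
        raise DataError("training session contains a single class")
    clf.fit(train_samples.X.to_numpy(dtype=np.float64), train_samples.y)
    Xte = test_samples.X.to_numpy(dtype=np.float64)
    y_pred = np.asarray(clf.predict(Xte))
    scores = _decision_scores(clf, Xte)
    folds = []
    for well in test_samples.wells:
        m = test_samples.groups == well
        folds.append(FoldResult(
            well=str(well), y_true=test_samples.y[m], y_pred=y_pred[m],
            well_label_true=str(test_samples.y[m][0]),
            well_label_pred=majority_vote(y_pred[m],
                                          scores[m] if scores is not None else None)))
    return {"train_session": train_samples.session,
            "test_session": test_samples.session,
            "folds": folds,
            "single_accuracy": pooled_accuracy(folds),
            "majority_accuracy": majority_accuracy(folds)}


def comparator_classifiers(samples: SampleTable, seed: int = 0,
                           names=CLASSIFIER_NAMES) -> pd.DataFrame:
    """All classifiers under the identical LOWO protocol and feature set."""
    rows = []
    for name in names:
        folds = lowo_cv(samples, classifier=name, seed=seed)
        rows.append({"classifier": name, "session": samples.session,
                     "single_accuracy": pooled_accuracy(folds),
                     "majority_accuracy": majority_accuracy(folds)})
    return pd.DataFrame(rows)


def permutation_null(samples: SampleTable, classifier="lda",
                     n_permutations: int = 20, seed: int = 0,
                     statistic: str = "majority") -> np.ndarray:
    """Null distribution of LOWO accuracy under well-label permutation.

    Well-to-condition assignments are shuffled (keeping the class counts),
    every row of a well inheriting its permuted label; the chosen accuracy
    statistic is recomputed per permutation.
    """
    rng = np.random.default_rng(seed)
    wells = samples.wells
    well_label = {w: samples.y[samples.groups == w][0] for w in wells}
    labels = np.array([well_label[w] for w in wells])
    out = []
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        y = np.array([perm[wells.index(g)] for g in samples.groups])
        permuted = SampleTable(X=samples.X, y=y, groups=samples.groups,
                               session=samples.session, offsets=samples.offsets,
                               features=samples.features)
        try:
            folds = lowo_cv(permuted, classifier=classifier)
        except DataError:
            continue
        out.append(majority_accuracy(folds) if statistic == "majority"
                   else pooled_accuracy(folds))
    return np.asarray(out)
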