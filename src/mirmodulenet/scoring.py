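"""Scoring of star modules by internal cross-validated classification.

Each module's member mRNAs form a sub-matrix of the training data
(``make_sub_data``); a seeded random forest is evaluated by stratified
k-fold CV on that sub-matrix, and out-of-fold predictions are pooled into
accuracy, sensitivity, specificity, precision, F-measure, Cohen's kappa and
AUC.  Modules are then ranked, AUC-first by default (the primary metric),
with accuracy and then center ID as tie-breakers; an accuracy-first mode is
available for compatibility with tables sorted by accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io_expression import PairedOmicsDataset, StarModule

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 50  # random-forest size used throughout the pipeline


def forest_case_probability(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
    rng_seed: int,
    n_trees: int = DEFAULT_N_TREES,
) -> np.ndarray:
    """Fit a seeded random forest and return case-class probabilities.

    Class predictions downstream are derived as probability > 0.5, which on
    a two-class forest coincides with majority vote.  Input validation is
    relaxed (finite data is guaranteed by the preprocessing contract), which
    matters on tiny sub-matrices where per-tree overhead dominates.
    """
    with sklearn.config_context(assume_finite=True):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=rng_seed, n_jobs=1)
        clf.fit(X_train, y_train)
        case_col = list(clf.classes_).index(1)
        return clf.predict_proba(X_eval)[:, case_col]

METRIC_FIELDS = (
    "accuracy",
    "sensitivity",
    "specificity",
    "f_measure",
    "precision",
    "cohens_kappa",
    "auc",
)


@dataclass
class GroupScoreRecord:
    module: StarModule
    accuracy: float
    sensitivity: float
    specificity: float
    f_measure: float
    precision: float
    cohens_kappa: float
    auc: float
    rank: int = 0


def make_sub_data(train: PairedOmicsDataset, module: StarModule) -> tuple[pd.DataFrame, pd.Series]:
    """samples x member-mRNA matrix plus labels, columns in member order."""
    X = train.mrna.subset_features(module.members).values.T
    return X, train.labels


def classification_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray
) -> dict[str, float]:
    """Confusion-matrix metrics plus AUC from case-class scores.

    Sensitivity is recall of the case class (1), specificity recall of the
    control class (0); F-measure is the harmonic mean of precision and
    sensitivity.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = len(y_true)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    fm = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": sens,
        "specificity": spec,
        "f_measure": fm,
        "precision": prec,
        "cohens_kappa": float(cohen_kappa_score(y_true, y_pred)) if n else 0.0,
        "auc": float(roc_auc_score(y_true, y_score)),
    }


def score_group(
    sub_data: tuple[pd.DataFrame, pd.Series],
    k: int = 5,
    rng_seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> dict[str, float]:
    """Stratified k-fold CV of a seeded random forest on one module's genes.

    Predictions are pooled out-of-fold, so every sample is predicted by a
    model that never saw it.  If the minority class cannot populate k folds,
    k is reduced (minimum 2) with a warning.
    """
    X, y = sub_data
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    minority = int(np.bincount(yv, minlength=2).min())
    if minority < 2:
        raise ValueError("score_group needs both classes with >= 2 samples")
    if minority < k:
        warnings.warn(f"reducing inner folds from {k} to {minority} (small minority class)")
        k = max(2, minority)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    score = np.empty(len(yv), dtype=float)
    seen_test: list[np.ndarray] = []
    for fold, (tr, te) in enumerate(skf.split(Xv, yv)):
        score[te] = forest_case_probability(Xv[tr], yv[tr], Xv[te], rng_seed + fold, n_trees)
        seen_test.append(te)
    covered = np.concatenate(seen_test)
    assert len(np.unique(covered)) == len(yv), "out-of-fold coverage violated"
    pred = (score > 0.5).astype(int)
    return classification_metrics(yv, pred, score)


def score_all_groups(
    train: PairedOmicsDataset,
    modules: list[StarModule],
    k: int = 5,
    rng_seed: int = 0,
    rank_by: str = "auc",
    n_trees: int = DEFAULT_N_TREES,
) -> list[GroupScoreRecord]:
    """Score every module and rank them.

    ``rank_by='auc'`` sorts by AUC desc, accuracy desc, center ID asc;
    ``rank_by='accuracy'`` swaps the first two keys.
    """
    if rank_by not in ("auc", "accuracy"):
        raise ValueError(f"unknown rank_by: {rank_by!r}")
    if not modules:
        raise ValueError("no modules to score")
    records = []
    for m in modules:
        metrics = score_group(make_sub_data(train, m), k=k, rng_seed=rng_seed, n_trees=n_trees)
        records.append(GroupScoreRecord(module=m, **metrics))
    primary, secondary = ("auc", "accuracy") if rank_by == "auc" else ("accuracy", "auc")
    records.sort(
        key=lambda r: (-getattr(r, primary), -getattr(r, secondary), r.module.center_mirna)
    )
    for i, r in enumerate(records, start=1):
        r.rank = i
    return records
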