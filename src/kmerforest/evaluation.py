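"""Classifier evaluation surfaces: ROC/AUC and precision-recall/auPR.

AUC is the trapezoid area under the threshold-swept ROC, which equals the
probability that a random positive outscores a random negative (ties 1/2).
auPR uses the interpolation-free step-wise sum Σ (R_i − R_{i−1})·P_i;
linear interpolation in PR space overestimates and is deliberately not
used, so numbers are reproducible bit-for-bit.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold

from .forest_mda import ForestConfig, train_forest, predict
from .kmer_features import FeatureMatrix


def _validate(scores, labels, need_both=True, need_positive=True):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape or scores.ndim != 1 or len(scores) == 0:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    if need_positive and labels.sum() == 0:
        raise ValueError("no positive labels")
    if need_both and len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def roc_curve(scores, labels) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(fpr, tpr, thresholds, auc) by descending-score threshold sweep."""
    scores, labels = _validate(scores, labels)
    fpr, tpr, thresholds = _skm.roc_curve(labels, scores)
    return fpr, tpr, thresholds, float(_skm.auc(fpr, tpr))


def pr_curve(scores, labels) -> Tuple[np.ndarray, np.ndarray, float]:
    """(recall, precision, auPR) with step-wise auPR summation."""
    scores, labels = _validate(scores, labels, need_both=False)
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    aupr = float(_skm.average_precision_score(labels, scores))
    return recall, precision, aupr


@dataclass
class CvResult:
    fold_auc: List[float]
    fold_aupr: List[float]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    def as_dict(self) -> Dict[str, object]:
        return {
            "fold_auc": self.fold_auc,
            "fold_aupr": self.fold_aupr,
            "mean_auc": self.mean_auc,
            "mean_aupr": self.mean_aupr,
        }


def cross_validated_auc(
    matrix: FeatureMatrix,
    config: ForestConfig,
    n_folds: int = 5,
    seed: Optional[int] = None,
) -> CvResult:
    """Stratified k-fold held-out AUC/auPR; the model is retrained per fold
    with a fold-specific training seed derived from ``config.seed``."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    seed = config.seed if seed is None else seed
    y = matrix.labels
    if min(np.bincount(y, minlength=2)) < n_folds:
        raise ValueError("each class needs at least n_folds samples")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % 2**32)
    fold_auc, fold_aupr = [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        sub = FeatureMatrix(
            [matrix.vectors[i] for i in train_idx], y[train_idx], matrix.vocab
        )
        fold_config = ForestConfig(
            n_trees=config.n_trees,
            features_per_split=config.features_per_split,
            seed=config.seed + 1000 * (fold + 1),
            n_threads=config.n_threads,
            n_repeats=config.n_repeats,
        )
        model = train_forest(sub, fold_config)
        test = FeatureMatrix(
            [matrix.vectors[i] for i in test_idx], y[test_idx], matrix.vocab
        )
        score, _ = predict(model, test)
        *_, auc = roc_curve(score, y[test_idx])
        _, _, aupr = pr_curve(score, y[test_idx])
        fold_auc.append(auc)
        fold_aupr.append(aupr)
    return CvResult(fold_auc, fold_aupr)
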