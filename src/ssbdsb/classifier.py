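"""Down-sampling voting SVM ensemble and its evaluation metrics.

The SSB/DSB problem is imbalanced (roughly 1 SSB to 3 DSBs), so a single
SVM trained on the raw table would favour the majority class. Instead, an
ensemble of 15 RBF-kernel SVMs is trained, each on every minority-class
protein plus an equal-size random draw (without replacement) from the
majority class; the predicted label is the majority vote and the fraction of
members voting SSB serves as the continuous score for the ROC/AUC. The
member count is odd, so votes cannot tie.

Evaluation uses accuracy, sensitivity, specificity, F1, the Matthews
correlation coefficient (all from the confusion counts with SSB as the
positive class) and a rank-based AUC; stratified 10-fold cross-validation
pools the held-out predictions of all folds. A uniformly random classifier
is provided as the chance baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureSubset, usable_for_training

logger = logging.getLogger(__name__)

POSITIVE = "SSB"
NEGATIVE = "DSB"
N_MEMBERS = 15


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts with SSB as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, truth, predicted) -> "ConfusionCounts":
        truth = np.asarray(truth)
        predicted = np.asarray(predicted)
        if truth.shape != predicted.shape:
            raise ValueError("truth and prediction lengths differ")
        pos_t = truth == POSITIVE
        pos_p = predicted == POSITIVE
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


@dataclass(frozen=True)
class MetricSet:
    acc: float
    sn: float
    sp: float
    f1: float
    mcc: float
    auc: float
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "sn": self.sn, "sp": self.sp,
                "f1": self.f1, "mcc": self.mcc, "auc": self.auc}


def rank_auc(scores, truth) -> float:
    """AUC via the rank (Mann-Whitney) statistic with midranks for ties."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    pos = truth == POSITIVE
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(counts: ConfusionCounts, scores=None, truth=None) -> MetricSet:
    """ACC, SN, SP, F1, MCC from the confusion counts, plus rank AUC.

    Ratios with a zero denominator come back as NaN; an MCC with a zero
    denominator is 0 by convention (logged). MCC numerator/denominator use
    exact integer arithmetic before the final square root.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = counts.total
    acc = (tp + tn) / total if total else float("nan")
    sn = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        logger.info("MCC denominator zero; reporting 0 by convention")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom2)
    if scores is not None and truth is not None:
        if len(scores) != len(truth):
            raise ValueError("scores and truth lengths differ")
        if len(truth) != total:
            raise ValueError("confusion counts inconsistent with score vector length")
        auc = rank_auc(scores, truth)
    else:
        auc = float("nan")
    return MetricSet(acc, sn, sp, f1, mcc, auc, counts)


@dataclass
class EnsembleModel:
    """15 balanced-resample RBF-SVM members with per-member scalers."""

    members: list[tuple[StandardScaler, SVC]]
    feature_subset: FeatureSubset
    seed: int
    member_indices: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) % 2 == 0:
            raise ValueError("member count must be odd (votes cannot tie)")


def _matrix(table: pd.DataFrame, subset: FeatureSubset) -> np.ndarray:
    for name in subset.names:
        if name not in table.columns:
            raise ValueError(f"feature {name!r} missing from table")
    return table.loc[:, list(subset.names)].to_numpy(float)


def train_ensemble(
    table: pd.DataFrame,
    subset: FeatureSubset | None = None,
    c: float = 1.0,
    gamma: float | str = "scale",
    seed: int = 0,
    n_members: int = N_MEMBERS,
) -> EnsembleModel:
    """Train the down-sampling voting ensemble.

    Each member sees every minority-class sample plus an equal-size uniform
    draw without replacement from the majority class, standardised by the
    member's own training statistics.
    """
    subset = subset or FeatureSubset()
    table = usable_for_training(table, subset)
    y = table["label"].to_numpy()
    classes = set(y)
    if not {POSITIVE, NEGATIVE} <= classes:
        raise ValueError(f"need both {POSITIVE} and {NEGATIVE} samples, got {sorted(classes)}")
    X = _matrix(table, subset)
    idx_pos = np.flatnonzero(y == POSITIVE)
    idx_neg = np.flatnonzero(y == NEGATIVE)
    minority, majority = (idx_pos, idx_neg) if len(idx_pos) <= len(idx_neg) else (idx_neg, idx_pos)
    if len(minority) < 2:
        raise ValueError("minority class needs at least 2 samples")

    rng = np.random.default_rng(seed)
    members = []
    member_indices = []
    for _ in range(n_members):
        draw = rng.choice(majority, size=len(minority), replace=False)
        idx = np.concatenate([minority, draw])
        n_min = (y[idx] == POSITIVE).sum()
        assert n_min == len(idx) - n_min, "member training set must be exactly balanced"
        scaler = StandardScaler().fit(X[idx])
        svm = SVC(C=c, gamma=gamma, kernel="rbf", random_state=0)
        svm.fit(scaler.transform(X[idx]), y[idx])
        members.append((scaler, svm))
        member_indices.append(np.sort(idx))
    return EnsembleModel(members, subset, seed, member_indices)


def predict(model: EnsembleModel, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels and SSB vote fractions for each row."""
    X = _matrix(table, model.feature_subset)
    if not np.isfinite(X).all():
        bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
        raise ValueError(f"non-finite features in rows {bad.tolist()}; "
                         "filter missing-tunnel proteins before prediction")
    votes = np.zeros(len(X))
    for scaler, svm in model.members:
        votes += (svm.predict(scaler.transform(X)) == POSITIVE)
    fractions = votes / len(model.members)
    labels = np.where(fractions > 0.5, POSITIVE, NEGATIVE)
    return labels, fractions


def cross_validate(
    table: pd.DataFrame,
    subset: FeatureSubset | None = None,
    c: float = 1.0,
    gamma: float | str = "scale",
    folds: int = 10,
    seed: int = 0,
) -> tuple[MetricSet, list[MetricSet]]:
    """Stratified k-fold cross-validation of the voting ensemble.

    Per fold the ensemble is retrained on the training folds and applied to
    the held-out fold; the pooled metrics aggregate every held-out
    prediction. Classes smaller than the fold count reduce it with a warning.
    """
    subset = subset or FeatureSubset()
    table = usable_for_training(table, subset).reset_index(drop=True)
    y = table["label"].to_numpy()
    min_class = min(np.sum(y == POSITIVE), np.sum(y == NEGATIVE))
    if min_class < folds:
        logger.warning("reducing folds from %d to %d (smallest class size)", folds, min_class)
        folds = max(int(min_class), 2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled_truth, pooled_pred, pooled_scores = [], [], []
    per_fold = []
    for k, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = train_ensemble(table.iloc[train_idx], subset, c, gamma,
                               seed=seed * 1009 + k)
        labels, fractions = predict(model, table.iloc[test_idx])
        truth = y[test_idx]
        per_fold.append(compute_metrics(ConfusionCounts.from_labels(truth, labels),
                                        fractions, truth))
        pooled_truth.append(truth)
        pooled_pred.append(labels)
        pooled_scores.append(fractions)
    truth = np.concatenate(pooled_truth)
    pred = np.concatenate(pooled_pred)
    scores = np.concatenate(pooled_scores)
    pooled = compute_metrics(ConfusionCounts.from_labels(truth, pred), scores, truth)
    return pooled, per_fold


def random_baseline(table: pd.DataFrame, seed: int = 0) -> MetricSet:
    """Uniformly random classifier: the chance-level reference."""
    if len(table) == 0:
        raise ValueError("empty table")
    rng = np.random.default_rng(seed)
    truth = table["label"].to_numpy()
    scores = rng.random(len(truth))
    pred = np.where(scores > 0.5, POSITIVE, NEGATIVE)
    return compute_metrics(ConfusionCounts.from_labels(truth, pred), scores, truth)


def independent_test(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    subset: FeatureSubset | None = None,
    c: float = 1.0,
    gamma: float | str = "scale",
    seed: int = 0,
) -> MetricSet:
    """Train on one table (e.g. the DNA-bound HOLO set), test on another
    (e.g. the DNA-free APO set); protein ids must be disjoint."""
    if len(test_table) == 0:
        raise ValueError("empty test table")
    overlap = sorted(set(train_table["protein_id"]) & set(test_table["protein_id"]))
    if overlap:
        raise ValueError(f"train/test protein ids overlap: {overlap[:10]}")
    subset = subset or FeatureSubset()
    model = train_ensemble(train_table, subset, c, gamma, seed=seed)
    test = usable_for_training(test_table, subset)
    labels, fractions = predict(model, test)
    truth = test["label"].to_numpy()
    return compute_metrics(ConfusionCounts.from_labels(truth, labels), fractions, truth)
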