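"""Evaluation protocols: metric suite, cross-validation, imbalance, ablation.

Threshold metrics (accuracy, sensitivity, specificity, precision, F1, MCC)
are computed directly from the confusion counts; ROC and precision-recall
curves are swept over the unique predicted scores with trapezoidal areas.
The standard protocol is stratified 10-fold cross-validation with per-fold
metrics averaged across folds ("per-fold" aggregation; a pooled-confusion
mode is available).  For imbalanced data the protocol is a stratified 70/30
split with random under-sampling applied to the training portion only, so
the test portion keeps its natural class ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .models import ClassifierSpec, train

#: the eleven feature-block combinations of the ablation protocol
DEFAULT_ABLATION_COMBOS: list[tuple[str, ...]] = [
    ("AAC",),
    ("PP",),
    ("DPC",),
    ("ITB",),
    ("AAC", "PP"),
    ("AAC", "DPC"),
    ("DPC", "ITB"),
    ("AAC", "PP", "DPC"),
    ("PP", "DPC", "ITB"),
    ("AAC", "DPC", "ITB"),
    ("AAC", "PP", "DPC", "ITB"),
]

THRESHOLD_METRICS = ("ACC", "SEN", "SP", "precision", "F1", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class MetricSet:
    """Threshold metrics, optionally with curve areas attached.

    ``degenerate`` lists metrics whose defining ratio had a zero denominator
    and were therefore reported as 0.
    """

    ACC: float
    SEN: float
    SP: float
    precision: float
    F1: float
    MCC: float
    AUC: float | None = None
    AUPRC: float | None = None
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["degenerate"] = list(self.degenerate)
        return d


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Threshold metrics from confusion counts.

    SP = TN/(TN+FP); ACC = (TN+TP)/N; SEN = TP/(TP+FN);
    precision = TP/(TP+FP); F1 = 2*precision*SEN/(precision+SEN);
    MCC = (TP*TN - FP*FN) / sqrt((FP+TP)(FN+TP)(TN+FP)(FN+TN)).
    A zero denominator yields 0 with the metric flagged as degenerate.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    flags: list[str] = []
    sp = _ratio(tn, tn + fp, "SP", flags)
    acc = _ratio(tn + tp, counts.total, "ACC", flags)
    sen = _ratio(tp, tp + fn, "SEN", flags)
    prec = _ratio(tp, tp + fp, "precision", flags)
    f1 = _ratio(2 * prec * sen, prec + sen, "F1", flags)
    mcc_den = math.sqrt((fp + tp) * (fn + tp) * (tn + fp) * (fn + tn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "MCC", flags)
    return MetricSet(ACC=acc, SEN=sen, SP=sp, precision=prec, F1=f1, MCC=mcc,
                     degenerate=tuple(flags))


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve points and trapezoidal AUC.

    Thresholds sweep the unique scores with ties grouped, so the AUC is
    invariant under strictly monotone transforms of the scores.
    Returns (fpr, tpr, auc).
    """
    y_true = np.asarray(y_true).astype(int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs at least one sample of each class")
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def pr_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall curve points and trapezoidal area (AUPRC).

    Returns (recall, precision, auprc) with recall in decreasing order.
    """
    y_true = np.asarray(y_true).astype(int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("PR curve needs at least one sample of each class")
    precision, recall, _ = precision_recall_curve(y_true, scores)
    return recall, precision, float(_trapezoid_auc(recall, precision))


@dataclass
class CVResult:
    """Per-fold metric sets plus their aggregate mean and std."""

    folds: list[MetricSet]
    mean: dict[str, float]
    std: dict[str, float]
    fold_assignments: list[np.ndarray] = field(default_factory=list)
    seed: int = 0
    pooled: MetricSet | None = None


def _aggregate(metric_sets: Sequence[MetricSet]) -> tuple[dict[str, float], dict[str, float]]:
    keys = list(THRESHOLD_METRICS) + ["AUC", "AUPRC"]
    mean, std = {}, {}
    for k in keys:
        vals = [getattr(m, k) for m in metric_sets if getattr(m, k) is not None]
        if vals:
            mean[k] = float(np.mean(vals))
            std[k] = float(np.std(vals))
    return mean, std


def _evaluate_split(model, X_test, y_test, threshold: float) -> MetricSet:
    scores = model.predict_proba(X_test)
    counts = ConfusionCounts.from_predictions(y_test, scores >= threshold)
    m = compute_metrics(counts)
    if len(np.unique(y_test)) == 2:
        *_, m.AUC = roc_points(y_test, scores)
        *_, m.AUPRC = pr_points(y_test, scores)
    return m


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec | None = None,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    pooled: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation.

    Each fold's held-out metrics are computed separately and the headline
    numbers are their across-fold average; ``pooled=True`` additionally
    reports metrics of the pooled confusion matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    spec = spec or ClassifierSpec(seed=seed)
    _, counts = np.unique(y, return_counts=True)
    if counts.size < 2 or counts.min() < k:
        raise ValueError(f"each class needs >= k={k} samples, got counts {counts}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds, assignments = [], []
    pooled_true, pooled_pred = [], []
    for train_idx, test_idx in splitter.split(X, y):
        model = train(X[train_idx], y[train_idx], spec)
        folds.append(_evaluate_split(model, X[test_idx], y[test_idx], threshold))
        assignments.append(test_idx)
        if pooled:
            pooled_true.append(y[test_idx])
            pooled_pred.append(model.predict_proba(X[test_idx]) >= threshold)
    mean, std = _aggregate(folds)
    pooled_metrics = None
    if pooled:
        pooled_metrics = compute_metrics(
            ConfusionCounts.from_predictions(np.concatenate(pooled_true),
                                             np.concatenate(pooled_pred))
        )
    return CVResult(folds=folds, mean=mean, std=std, fold_assignments=assignments,
                    seed=seed, pooled=pooled_metrics)


@dataclass
class RepeatedCVResult:
    repeats: list[CVResult]
    mean: dict[str, float]
    std: dict[str, float]  # across per-repeat means
    seeds: list[int]


def repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec | None = None,
    k: int = 10,
    repeats: int = 50,
    seed: int = 0,
    threshold: float = 0.5,
) -> RepeatedCVResult:
    """Repeat stratified k-fold CV with fresh shufflings and average.

    Repeat ``r`` uses fold seed ``seed + r``, so ``repeats=1`` reproduces
    :func:`kfold_cv` exactly.  The std is taken across per-repeat means.
    """
    runs = [
        kfold_cv(X, y, spec, k=k, seed=seed + r, threshold=threshold)
        for r in range(repeats)
    ]
    keys = runs[0].mean.keys()
    mean = {k_: float(np.mean([r.mean[k_] for r in runs])) for k_ in keys}
    std = {k_: float(np.std([r.mean[k_] for r in runs])) for k_ in keys}
    return RepeatedCVResult(repeats=runs, mean=mean, std=std,
                            seeds=[seed + r for r in range(repeats)])


def _undersample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subset (majority class down-sampled)."""
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    if len(idx_pos) == 0 or len(idx_neg) == 0:
        raise ValueError("both classes must be present for under-sampling")
    n = min(len(idx_pos), len(idx_neg))
    keep_pos = rng.choice(idx_pos, size=n, replace=False) if len(idx_pos) > n else idx_pos
    keep_neg = rng.choice(idx_neg, size=n, replace=False) if len(idx_neg) > n else idx_neg
    return np.sort(np.concatenate([keep_pos, keep_neg]))


@dataclass
class ImbalancedResult:
    metrics: MetricSet
    pr_recall: np.ndarray
    pr_precision: np.ndarray
    test_prevalence: float
    n_train_balanced: int
    n_test: int
    seed: int


def imbalanced_protocol(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec | None = None,
    split: float = 0.7,
    seed: int = 0,
    threshold: float = 0.5,
) -> ImbalancedResult:
    """Stratified split, balance the training part only, test on natural ratio.

    ``split`` is the training fraction (default 0.7).  Under-sampling is
    applied exclusively to the training portion; the held-out portion keeps
    its original imbalance, and the precision-recall curve is reported
    alongside the threshold metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=split, stratify=y, random_state=seed
    )
    rng = np.random.default_rng(seed)
    balanced = train_idx[_undersample_indices(y[train_idx], rng)]
    if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[balanced])) < 2:
        raise ValueError("a class became empty after splitting")
    model = train(X[balanced], y[balanced], spec or ClassifierSpec(seed=seed))
    metrics = _evaluate_split(model, X[test_idx], y[test_idx], threshold)
    scores = model.predict_proba(X[test_idx])
    recall, precision, auprc = pr_points(y[test_idx], scores)
    metrics.AUPRC = auprc
    return ImbalancedResult(
        metrics=metrics,
        pr_recall=recall,
        pr_precision=precision,
        test_prevalence=float(np.mean(y[test_idx])),
        n_train_balanced=int(len(balanced)),
        n_test=int(len(test_idx)),
        seed=seed,
    )


def feature_ablation(
    df: pd.DataFrame,
    spec: ClassifierSpec | None = None,
    combos: Sequence[tuple[str, ...]] | None = None,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate one model per feature-block combination.

    *df* is a full encoded feature matrix (see ``features.encode_dataset``);
    each combination keeps only the columns of its blocks.  The default list
    is the standard eleven combinations of AAC, PP, DPC and ITB.
    """
    combos = list(combos) if combos is not None else list(DEFAULT_ABLATION_COMBOS)
    if not combos or any(len(c) == 0 for c in combos):
        raise ValueError("combos must be non-empty block subsets")
    y = df["label"].to_numpy()
    rows = []
    for combo in combos:
        cols = [c for c in df.columns
                if any(c.startswith(block + "_") for block in combo)]
        if not cols:
            raise ValueError(f"no feature columns for combo {combo}")
        result = kfold_cv(df[cols].to_numpy(), y, spec, k=k, seed=seed)
        rows.append({"combo": "+".join(combo), "width": len(cols), **result.mean})
    return pd.DataFrame(rows)
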