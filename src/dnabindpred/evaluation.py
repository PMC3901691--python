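"""Performance metrics and evaluation protocols.

Quality indices are sensitivity, specificity, accuracy and the Matthews
correlation coefficient computed from a pooled confusion matrix.  The
cross-validation protocol randomly divides the chains into n equal-size
subsets; one execution of an n-fold CV is a *run*, identified by its seed,
and metrics are computed per run from the confusion counts pooled over that
run's folds, then averaged over runs.  The jackknife (leave-one-out) test is
an N-fold CV with a single deterministic run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_curve

from .gnb import GaussianNaiveBayes, gnb_fit_predict_proba

METRIC_NAMES = ("sen", "spe", "acc", "mcc")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion_from_labels(y_true, y_pred, positive=1) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    pred_pos = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and MCC from confusion counts.

    Sen = TP/(TP+FN); Spe = TN/(TN+FP); Acc = (TP+TN)/N;
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), in [-1, 1],
    with a zero MCC denominator giving 0 by convention.  An empty actual
    class (undefined Sen or Spe) is an error.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    if tp + fn == 0:
        raise ValueError("no actual positives: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no actual negatives: specificity undefined")
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return {
        "sen": tp / (tp + fn),
        "spe": tn / (tn + fp),
        "acc": (tp + tn) / counts.total,
        "mcc": mcc,
    }


@dataclass
class CVPlan:
    """Cross-validation protocol: n_folds folds, one seeded run per seed."""

    n_folds: int = 5
    seeds: tuple[int, ...] = field(default_factory=tuple)
    stratified: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        self.seeds = tuple(int(s) for s in self.seeds)
        if not self.seeds:
            raise ValueError("CVPlan needs at least one run seed")

    @property
    def n_runs(self) -> int:
        return len(self.seeds)

    @classmethod
    def from_seed(
        cls, base_seed: int, n_runs: int = 10, n_folds: int = 5, stratified: bool = False
    ) -> "CVPlan":
        run_seeds = np.random.SeedSequence(base_seed).generate_state(n_runs) % (2**31)
        return cls(n_folds=n_folds, seeds=tuple(int(s) for s in run_seeds),
                   stratified=stratified)


def make_folds(
    n_samples: int,
    plan: CVPlan,
    run_index: int,
    y: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Seeded partition of sample indices into n_folds test folds.

    Fold sizes differ by at most one.  With ``plan.stratified`` each class
    is partitioned separately so folds preserve the class ratio; ``y`` is
    then required.
    """
    if run_index >= plan.n_runs:
        raise IndexError(f"run_index {run_index} out of range for {plan.n_runs} runs")
    if n_samples < plan.n_folds:
        raise ValueError(f"cannot split {n_samples} samples into {plan.n_folds} folds")
    rng = np.random.default_rng(plan.seeds[run_index])
    if not plan.stratified:
        perm = rng.permutation(n_samples)
        return [np.sort(f) for f in np.array_split(perm, plan.n_folds)]
    if y is None:
        raise ValueError("stratified folds require y")
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(plan.n_folds)]
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        for k, part in enumerate(np.array_split(idx, plan.n_folds)):
            folds[k].extend(part.tolist())
    return [np.sort(np.asarray(f, dtype=np.intp)) for f in folds]


def _fold_posteriors(X, y, train_idx, test_idx, classifier):
    """Positive-class scores and hard predictions for one fold."""
    if classifier is None:
        scores = gnb_fit_predict_proba(X[train_idx], y[train_idx], X[test_idx])
        return scores, (scores >= 0.5).astype(int)
    est = clone(classifier)
    est.fit(X[train_idx], y[train_idx])
    if hasattr(est, "decision_function"):
        scores = np.asarray(est.decision_function(X[test_idx]), dtype=float)
    else:
        scores = est.predict_proba(X[test_idx])[:, 1]
    return scores, np.asarray(est.predict(X[test_idx]))


def run_cv(
    X,
    y,
    plan: CVPlan,
    classifier=None,
    collect_scores: bool = False,
):
    """Repeated seeded n-fold cross-validation.

    ``classifier=None`` uses the fast Gaussian-naive-Bayes path; any
    sklearn-style estimator (fit / predict / predict_proba) may be passed
    instead.  Per run, confusion counts are pooled over the folds and the
    four metrics computed once; the returned frame has one row per run.

    Returns
    -------
    per_run : DataFrame with columns sen, spe, acc, mcc (and auc when
        ``collect_scores``), indexed by run.
    summary : dict of mean/std per metric.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rows = []
    for r in range(plan.n_runs):
        folds = make_folds(X.shape[0], plan, r, y=y if plan.stratified else None)
        pooled = ConfusionCounts(0, 0, 0, 0)
        scores = np.empty(X.shape[0])
        for k, test_idx in enumerate(folds):
            train_mask = np.ones(X.shape[0], dtype=bool)
            train_mask[test_idx] = False
            train_idx = np.flatnonzero(train_mask)
            if len(np.unique(y[train_idx])) < 2:
                raise ValueError(
                    f"degenerate training split: run {r}, fold {k} leaves a "
                    "single class in training"
                )
            s, pred = _fold_posteriors(X, y, train_idx, test_idx, classifier)
            scores[test_idx] = s
            pooled = pooled + confusion_from_labels(y[test_idx], pred)
        row = metrics(pooled)
        if collect_scores:
            row["auc"] = roc_auc(y, scores).auc
        rows.append(row)
    per_run = pd.DataFrame(rows)
    per_run.index.name = "run"
    summary = {}
    for m in per_run.columns:
        summary[f"mean_{m}"] = float(per_run[m].mean())
        summary[f"std_{m}"] = float(per_run[m].std(ddof=0))
    return per_run, summary


def jackknife(X, y, classifier=None) -> dict[str, float]:
    """Leave-one-out test: N fits, one pooled confusion matrix.

    Deterministic — repeated invocations give the same result.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("jackknife needs at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("jackknife needs both classes present")
    pooled = ConfusionCounts(0, 0, 0, 0)
    for i in range(n):
        train_idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"degenerate training split leaving out sample {i}")
        _, pred = _fold_posteriors(X, y, train_idx, np.array([i]), classifier)
        pooled = pooled + confusion_from_labels(y[[i]], pred)
    assert pooled.total == n
    return metrics(pooled)


@dataclass
class ROCCurve:
    """Operating points (FPR, TPR) over all score thresholds plus the AUC."""

    points: np.ndarray
    auc: float

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


def roc_auc(y_true, scores) -> ROCCurve:
    """ROC curve from real-valued outputs; AUC by the trapezoidal rule.

    Equal scores are grouped into a single threshold step.  The curve starts
    at (0, 0) and ends at (1, 1).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=np.column_stack([fpr, tpr]), auc=auc)


def write_roc_tsv(curve: ROCCurve, path) -> None:
    pd.DataFrame(curve.points, columns=["fpr", "tpr"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
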