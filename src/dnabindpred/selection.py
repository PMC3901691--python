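"""Stage-2 wrapper feature selection: forward best-first search.

Candidate subsets are scored by the mean Matthews correlation coefficient
over repeated seeded five-fold cross-validation of the downstream
classifier (Gaussian naive Bayes by default).  The search starts from the
single pool feature with the largest mean MCC and at every later step adds
the remaining candidate that maximizes the mean MCC of the augmented set.
The search deliberately continues through temporary MCC dips and stops only
after ``patience`` consecutive steps without improvement over the best mean
MCC seen so far (or when the step budget is exhausted); the reported final
set is the trace prefix attaining the maximal mean MCC.

Ties in candidate score are broken by pool order, i.e. by the stage-1
(Gini) rank, so the whole trace is a deterministic function of
(matrix, pool, CV plan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .evaluation import (
    ConfusionCounts,
    CVPlan,
    _fold_posteriors,
    confusion_from_labels,
    make_folds,
    metrics,
)
from .io import FeatureMatrix


def _resolve_matrix(matrix, feature_names=None):
    """Accept a FeatureMatrix or (X, y); return (X array, y array, names)."""
    if isinstance(matrix, FeatureMatrix):
        return matrix.X, matrix.y, matrix.descriptor_names
    X, y = matrix
    X = np.asarray(X, dtype=float)
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    return X, np.asarray(y), names


def _plan_folds(n_samples: int, y, plan: CVPlan):
    """Precompute (train_idx, test_idx) pairs for every run and fold."""
    per_run = []
    for r in range(plan.n_runs):
        folds = make_folds(n_samples, plan, r, y=y if plan.stratified else None)
        pairs = []
        for test_idx in folds:
            mask = np.ones(n_samples, dtype=bool)
            mask[test_idx] = False
            pairs.append((np.flatnonzero(mask), test_idx))
        per_run.append(pairs)
    return per_run

def _score_columns(X_sub, y, fold_plan, classifier):
    """Per-run pooled-confusion metrics for one candidate column subset."""
    per_run = []
    for pairs in fold_plan:
        pooled = ConfusionCounts(0, 0, 0, 0)
        for train_idx, test_idx in pairs:
            _, pred = _fold_posteriors(X_sub, y, train_idx, test_idx, classifier)
            pooled = pooled + confusion_from_labels(y[test_idx], pred)
        per_run.append(metrics(pooled))
    return pd.DataFrame(per_run)


def evaluate_subset(
    matrix,
    subset: list[str],
    plan: CVPlan,
    classifier=None,
    feature_names=None,
) -> dict[str, float]:
    """Mean/std of Sen, Spe, Acc and MCC for one descriptor subset.

    Per run, metrics are computed from the confusion counts pooled over the
    run's folds; means and standard deviations are taken over the runs.
    """
    X, y, names = _resolve_matrix(matrix, feature_names)
    if not subset:
        raise ValueError("subset must be non-empty")
    name_to_col = {n: i for i, n in enumerate(names)}
    missing = [s for s in subset if s not in name_to_col]
    if missing:
        raise KeyError(f"unknown descriptor(s): {missing}")
    cols = [name_to_col[s] for s in subset]
    fold_plan = _plan_folds(X.shape[0], y, plan)
    per_run = _score_columns(np.ascontiguousarray(X[:, cols]), y, fold_plan, classifier)
    out: dict[str, float] = {}
    for m in per_run.columns:
        out[f"mean_{m}"] = float(per_run[m].mean())
        out[f"std_{m}"] = float(per_run[m].std(ddof=0))
    return out


@dataclass
class SelectionTrace:
    """Record of a forward best-first search.

    ``steps`` has one row per added descriptor (step, feature, mean/std MCC
    and mean Sen/Spe/Acc); ``final_size`` is the length of the prefix with
    maximal mean MCC, and ``selected`` that prefix's descriptor names.
    """

    steps: pd.DataFrame
    pool: list[str]
    final_size: int

    @property
    def selected(self) -> list[str]:
        return self.steps["feature"].head(self.final_size).tolist()

    @property
    def best_score(self) -> float:
        return float(self.steps["mean_mcc"].iloc[self.final_size - 1])

    def to_tsv(self, path) -> None:
        self.steps.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "SelectionTrace":
        steps = pd.read_csv(path, sep="\t")
        final_size = int(steps["mean_mcc"].idxmax()) + 1
        return cls(steps=steps, pool=steps["feature"].tolist(), final_size=final_size)


def _step_plan(plan: CVPlan, step: int) -> CVPlan:
    """Derive a step-specific CV plan from the base plan.

    Seeds are a deterministic function of (base seed, step), so each search
    step scores its candidates on freshly drawn folds.  Reusing one fixed
    fold set for every step lets candidates that happen to suit those folds
    accumulate, inflating the apparent MCC curve; re-drawing per step keeps
    the greedy comparison honest while the whole trace stays a pure
    function of (matrix, pool, plan).
    """
    seeds = tuple(
        int(np.random.SeedSequence((s, step)).generate_state(1)[0] % 2**31)
        for s in plan.seeds
    )
    return CVPlan(n_folds=plan.n_folds, seeds=seeds, stratified=plan.stratified)


def forward_best_first(
    matrix,
    pool: list[str],
    plan: CVPlan,
    classifier=None,
    budget: int | None = None,
    patience: int = 10,
    tol: float = 0.0,
    reseed_per_step: bool = True,
    feature_names=None,
) -> SelectionTrace:
    """Greedy forward best-first search over a candidate descriptor pool.

    See the module docstring for the search and stopping semantics.
    ``budget`` caps the number of steps (default: the pool size).  With
    ``reseed_per_step`` (the default) every step scores its candidates on
    folds re-drawn deterministically from the plan seeds and the step
    index; with ``False`` one fixed fold set is reused throughout.
    """
    X, y, names = _resolve_matrix(matrix, feature_names)
    if not pool:
        raise ValueError("pool must be non-empty")
    name_to_col = {n: i for i, n in enumerate(names)}
    missing = [p for p in pool if p not in name_to_col]
    if missing:
        raise KeyError(f"pool references unknown descriptor(s): {missing}")
    if budget is None:
        budget = len(pool)
    budget = min(budget, len(pool))
    if budget < 1:
        raise ValueError("budget must be >= 1")

    base_fold_plan = None if reseed_per_step else _plan_folds(X.shape[0], y, plan)
    remaining = list(pool)
    selected_cols: list[int] = []
    rows = []
    best_mcc = -np.inf
    since_improvement = 0

    for step in range(1, budget + 1):
        if reseed_per_step:
            fold_plan = _plan_folds(X.shape[0], y, _step_plan(plan, step))
        else:
            fold_plan = base_fold_plan
        best_cand = None
        best_stats = None
        for cand in remaining:  # pool order; first win keeps ties at Gini rank
            cols = selected_cols + [name_to_col[cand]]
            per_run = _score_columns(
                np.ascontiguousarray(X[:, cols]), y, fold_plan, classifier
            )
            mean_mcc = float(per_run["mcc"].mean())
            if best_stats is None or mean_mcc > best_stats[0]:
                best_stats = (mean_mcc, per_run)
                best_cand = cand
        mean_mcc, per_run = best_stats
        selected_cols.append(name_to_col[best_cand])
        remaining.remove(best_cand)
        rows.append(
            {
                "step": step,
                "feature": best_cand,
                "mean_mcc": mean_mcc,
                "std_mcc": float(per_run["mcc"].std(ddof=0)),
                "mean_acc": float(per_run["acc"].mean()),
                "mean_sen": float(per_run["sen"].mean()),
                "mean_spe": float(per_run["spe"].mean()),
            }
        )
        if mean_mcc > best_mcc + tol:
            best_mcc = mean_mcc
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= patience:
                break

    steps = pd.DataFrame(rows)
    final_size = int(steps["mean_mcc"].idxmax()) + 1
    return SelectionTrace(steps=steps, pool=list(pool), final_size=final_size)


class ForwardBestFirstSelector(BaseEstimator):
    """sklearn-style transformer wrapping :func:`forward_best_first`.

    Parameters
    ----------
    pool : list of str or None
        Candidate descriptor names (typically the stage-1 top-k); None means
        all columns.
    cv : CVPlan or None
        Scoring protocol; None builds the default ten seeded runs of
        five-fold CV from ``random_state``.
    classifier : estimator or None
        Downstream classifier; None uses the fast Gaussian-naive-Bayes path.
    """

    def __init__(
        self,
        pool: list[str] | None = None,
        cv: CVPlan | None = None,
        classifier=None,
        budget: int | None = None,
        patience: int = 10,
        tol: float = 0.0,
        reseed_per_step: bool = True,
        random_state: int = 0,
    ):
        self.pool = pool
        self.cv = cv
        self.classifier = classifier
        self.budget = budget
        self.patience = patience
        self.tol = tol
        self.reseed_per_step = reseed_per_step
        self.random_state = random_state

    def fit(self, X, y=None, feature_names: list[str] | None = None):
        if isinstance(X, FeatureMatrix):
            matrix = X
            names = X.descriptor_names
        else:
            X = np.asarray(X, dtype=float)
            names = feature_names or [f"f{i}" for i in range(X.shape[1])]
            matrix = (X, y)
        plan = self.cv or CVPlan.from_seed(self.random_state)
        pool = self.pool if self.pool is not None else list(names)
        self.trace_ = forward_best_first(
            matrix,
            pool,
            plan,
            classifier=self.classifier,
            budget=self.budget,
            patience=self.patience,
            tol=self.tol,
            reseed_per_step=self.reseed_per_step,
            feature_names=names,
        )
        self.selected_features_ = self.trace_.selected
        self.n_features_selected_ = len(self.selected_features_)
        self.best_score_ = self.trace_.best_score
        self.feature_names_ = list(names)
        return self

    def get_support(self) -> np.ndarray:
        mask = np.zeros(len(self.feature_names_), dtype=bool)
        sel = set(self.selected_features_)
        for i, n in enumerate(self.feature_names_):
            mask[i] = n in sel
        return mask

    def transform(self, X):
        if isinstance(X, FeatureMatrix):
            return X.values[self.selected_features_].to_numpy()
        if isinstance(X, pd.DataFrame):
            return X[self.selected_features_].to_numpy()
        return np.asarray(X)[:, self.get_support()]
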