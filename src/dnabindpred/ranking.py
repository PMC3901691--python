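"""Stage-1 feature ranking by random-forest Gini importance.

An ensemble of CART trees is grown on bootstrap resamples with random
feature subsets per split; a feature's importance is its mean decrease in
Gini impurity (weighted by the fraction of samples reaching each split)
averaged over trees and normalized to sum to 1.  Only the ranking is used
downstream — the forest is never the final classifier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted


class GiniImportanceRanker(BaseEstimator):
    """Rank features by random-forest Gini importance.

    Parameters follow standard random-forest defaults: 500 trees,
    sqrt(p) features per split, bootstrap resampling, unlimited depth.
    Ties in importance are broken by ascending feature index, so the
    ranking is a deterministic function of (data, random_state).

    Attributes
    ----------
    importances_ : ndarray of shape (n_features,)
        Non-negative, summing to 1 (when any split was made).
    ranking_ : DataFrame with columns (feature, importance), descending.
    """

    def __init__(
        self,
        n_trees: int = 500,
        features_per_split: str | int = "sqrt",
        bootstrap: bool = True,
        min_samples_split: int = 2,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.features_per_split = features_per_split
        self.bootstrap = bootstrap
        self.min_samples_split = min_samples_split
        self.random_state = random_state

    def fit(self, X, y, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("feature ranking needs both classes present")
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
        if len(feature_names) != X.shape[1]:
            raise ValueError("feature_names length does not match X")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            max_features=self.features_per_split,
            bootstrap=self.bootstrap,
            min_samples_split=self.min_samples_split,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, y)
        imp = self.forest_.feature_importances_.astype(float)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        self.importances_ = imp
        self.feature_names_ = list(feature_names)
        order = np.lexsort((np.arange(len(imp)), -imp))  # desc, ties by index
        self.ranking_ = pd.DataFrame(
            {
                "feature": [feature_names[i] for i in order],
                "importance": imp[order],
            }
        )
        return self

    def top_k(self, k: int) -> list[str]:
        """The k highest-importance feature names, in ranking order."""
        check_is_fitted(self, "ranking_")
        if not 1 <= k <= len(self.feature_names_):
            raise ValueError(
                f"k must be in [1, {len(self.feature_names_)}], got {k}"
            )
        return self.ranking_["feature"].head(k).tolist()

    def write_ranking(self, path) -> None:
        check_is_fitted(self, "ranking_")
        out = self.ranking_.copy()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def rank_features(
    X, y, feature_names=None, n_trees: int = 500, random_state: int | None = None
) -> pd.DataFrame:
    """Convenience wrapper: fit a ranker and return its ranking frame."""
    ranker = GiniImportanceRanker(n_trees=n_trees, random_state=random_state)
    return ranker.fit(X, y, feature_names=feature_names).ranking_
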