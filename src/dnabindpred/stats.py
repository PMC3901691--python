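"""Per-feature class-difference analysis.

For a chosen descriptor subset this module reports per-class mean and
standard deviation, a Welch (unequal-variance) two-sample t statistic with
two-sided P value from the t distribution at Welch-Satterthwaite degrees of
freedom, the descriptor's category under the naming grammar, and the count
of descriptors significant at a given level.  P values are reported raw
(no multiple-testing correction) with an optional Bonferroni adjustment.

Also ships a reference table of the 56 descriptors selected on the PDB594
benchmark (per-class means, standard deviations and printed P values), used
for taxonomy checks against the naming grammar.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import parse_descriptor_name
from .io import FeatureMatrix


@dataclass
class FeatureComparison:
    name: str
    category: str
    mean_pos: float
    std_pos: float
    mean_neg: float
    std_neg: float
    t_stat: float
    p_value: float


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and two-sided P, with degenerate-variance handling."""
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        # perfectly separated constant groups
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_features(
    matrix, subset: list[str] | None = None, feature_names=None
) -> list[FeatureComparison]:
    """Per-descriptor class comparison on a labeled feature matrix.

    ``matrix`` is a :class:`FeatureMatrix` or an ``(X, y)`` pair with
    ``feature_names``; labels 1 = DNA-binding (positive), 0 = non-binding.
    Both classes need at least 2 samples.
    """
    if isinstance(matrix, FeatureMatrix):
        X, y, names = matrix.X, matrix.y, matrix.descriptor_names
    else:
        X, y = matrix
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        names = list(feature_names)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("both classes need >= 2 samples")
    if subset is None:
        subset = names
    name_to_col = {n: i for i, n in enumerate(names)}
    out = []
    pos = X[y == 1]
    neg = X[y == 0]
    for name in subset:
        if name not in name_to_col:
            raise KeyError(f"unknown descriptor {name!r}")
        j = name_to_col[name]
        a, b = pos[:, j], neg[:, j]
        t, p = _welch(a, b)
        out.append(
            FeatureComparison(
                name=name,
                category=parse_descriptor_name(name).category,
                mean_pos=float(a.mean()),
                std_pos=float(a.std(ddof=1)),
                mean_neg=float(b.mean()),
                std_neg=float(b.std(ddof=1)),
                t_stat=t,
                p_value=p,
            )
        )
    return out


def count_significant(
    comparisons, alpha: float = 0.05, bonferroni: bool = False
) -> int:
    """Number of comparisons with P < alpha (optionally Bonferroni-adjusted)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie strictly in (0, 1), got {alpha}")
    if not len(comparisons):
        raise ValueError("no comparisons given")
    pvals = [
        c.p_value if isinstance(c, FeatureComparison) else float(c)
        for c in comparisons
    ]
    cut = alpha / len(pvals) if bonferroni else alpha
    return int(sum(p < cut for p in pvals))


def categorize(names: list[str]) -> tuple[dict[str, str], Counter]:
    """Map descriptor names to their category via the naming grammar.

    Returns (per-name category, per-category counts).  Unparseable names
    raise with the offending name.
    """
    per_name = {name: parse_descriptor_name(name).category for name in names}
    return per_name, Counter(per_name.values())


def comparisons_to_frame(comparisons: list[FeatureComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


def load_reference_selected_features() -> pd.DataFrame:
    """The 56-descriptor reference set selected on the PDB594 benchmark.

    Columns: feature (name as printed, including typographic artifacts),
    category, per-class mean/std, p_value (numeric; '<0.001' entries parsed
    as their bound) and p_censored marking those bound-only entries.
    Row order is the order in which the wrapper search added the features.
    """
    with resources.files("dnabindpred.data").joinpath(
        "reference_selected_features.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"p_value": str})
    df["p_censored"] = df["p_value"].str.startswith("<")
    df["p_value"] = df["p_value"].str.lstrip("<").astype(float)
    return df
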