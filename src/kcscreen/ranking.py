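"""Fisher-score feature ranking.

The two-class Fisher criterion F = (mu1 - mu2)^2 / (s1^2 + s2^2) (class
sample variances, divisor n-1) measures each feature's univariate
discriminative power: F near zero means the classes are not separated
relative to their spread.  F is invariant under a shared affine
transform of the feature, so ranking raw features equals ranking
normalized ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable
from .registry import ALL_FEATURES, feature_order


class InfiniteSeparationError(ValueError):
    """Both class variances are zero but the means differ: the feature
    separates the classes perfectly and F is unbounded."""


def fisher_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Fisher score of one feature for a binary class split.

    ``labels`` must take exactly two distinct values, each with >= 2
    members.  Returns 0.0 when both variances vanish with equal means;
    raises :class:`InfiniteSeparationError` when they vanish with
    unequal means.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature values must be finite")
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {len(classes)}")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 members")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va + vb == 0.0:
        if diff == 0.0:
            return 0.0
        raise InfiniteSeparationError(
            "zero within-class variance with unequal class means"
        )
    return float(diff**2 / (va + vb))


@dataclass(frozen=True)
class FisherRanking:
    """Per-feature Fisher scores for one class pair, in descending score
    order (ties broken by registry order)."""

    class_pair: tuple[str, str]
    table: pd.DataFrame  # columns: feature, score, rank

    def top(self, k: int = 5) -> list[str]:
        return self.table["feature"].head(k).tolist()

    def score_of(self, feature: str) -> float:
        return float(self.table.set_index("feature").loc[feature, "score"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_features(table: FeatureTable, class_pair: tuple[str, str],
                  features: Sequence[str] = ALL_FEATURES) -> FisherRanking:
    """Score every feature on the two named classes and rank descending."""
    sub = table.subset_classes(class_pair)
    present = set(sub.labels)
    absent = [c for c in class_pair if c not in present]
    if absent:
        raise ValueError(f"class(es) absent from table: {absent}")
    labels = sub.labels.to_numpy()
    records = [
        (f, fisher_score(sub.df[f].to_numpy(), labels), feature_order(f))
        for f in features
    ]
    df = pd.DataFrame(records, columns=["feature", "score", "_order"])
    df = df.sort_values(["score", "_order"], ascending=[False, True],
                        kind="stable").drop(columns="_order")
    df["rank"] = np.arange(1, len(df) + 1)
    return FisherRanking(class_pair=tuple(class_pair), table=df.reset_index(drop=True))
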