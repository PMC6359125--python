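"""Random-forest relevance ranking and cumulative-threshold selection.

Features are ranked by mean Gini impurity decrease across a
100-tree bootstrap forest, normalized so the relevances sum to one, and
the smallest ranked prefix whose cumulative relevance reaches the
threshold (default 80%) is selected.  A fixed-size top-k selection is
also available.  By default selection runs once on the full table,
outside any cross-validation loop; callers wanting leakage-free
selection re-run it inside each training fold (see
``classify.loocv_predict``'s ``select`` hook).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .types import FeatureTable, ValidationError

__all__ = ["RelevanceRanking", "rank_features", "select_features"]


@dataclass
class RelevanceRanking:
    """Features ordered by decreasing normalized relevance."""

    feature_ids: list[str]       # ranked order
    relevance: np.ndarray        # aligned with feature_ids, sums to 1
    n_trees: int
    seed: int
    n_rows_used: int = 0
    n_rows_dropped: int = 0

    def __post_init__(self) -> None:
        self.relevance = np.asarray(self.relevance, dtype=float)
        if np.any(self.relevance < 0):
            raise ValidationError("relevance must be non-negative")
        if abs(self.relevance.sum() - 1.0) > 1e-9:
            raise ValidationError("relevance must sum to 1")

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.relevance)


def rank_features(table: FeatureTable, n_trees: int = 100, seed: int = 0) -> RelevanceRanking:
    """Rank features by mean impurity decrease in a random forest.

    Rows with any missing feature value are dropped (with the count
    recorded on the ranking).  Ties are broken by feature-id order, so
    the ranking is deterministic given the seed.
    """
    feats = table.feature_ids
    # canonical row order so the ranking is invariant to table row order
    df = table.data.sort_values("record_id", kind="stable").reset_index(drop=True)
    mask = df[feats].notna().all(axis=1)
    dropped = int((~mask).sum())
    df = df[mask]
    y = df["label"].to_numpy()
    if np.unique(y).size < 2:
        raise ValidationError("feature ranking requires at least 2 classes")
    X = df[feats].to_numpy(dtype=float)

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        bootstrap=True,
        random_state=seed,
    )
    forest.fit(X, y)
    imp = forest.feature_importances_  # mean impurity decrease, sums to 1
    if imp.sum() <= 0:  # all-constant features: uniform fallback
        imp = np.full(len(feats), 1.0 / len(feats))
    imp = imp / imp.sum()
    # stable sort on -importance breaks ties by feature-id order
    order = np.argsort(-imp, kind="stable")
    return RelevanceRanking(
        feature_ids=[feats[i] for i in order],
        relevance=imp[order],
        n_trees=n_trees,
        seed=seed,
        n_rows_used=int(mask.sum()),
        n_rows_dropped=dropped,
    )


def select_features(
    rank: RelevanceRanking,
    cum_threshold: float = 0.80,
    fixed_k: int | None = None,
) -> list[str]:
    """Smallest ranked prefix with cumulative relevance >= threshold,
    or exactly the top ``fixed_k`` when given."""
    if fixed_k is not None:
        if not 1 <= fixed_k <= len(rank.feature_ids):
            raise ValidationError(f"fixed_k={fixed_k} out of range")
        return rank.feature_ids[:fixed_k]
    if not 0 < cum_threshold <= 1:
        raise ValidationError("cum_threshold must lie in (0, 1]")
    k = int(np.searchsorted(rank.cumulative, cum_threshold - 1e-12)) + 1
    k = min(k, len(rank.feature_ids))
    return rank.feature_ids[:k]
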