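"""Fisher-coefficient feature ranking and top-k selection.

The Fisher coefficient of a single feature is the ratio of between-class to
within-class variance,

    F = sum_k p_k (mu_k - mu)^2  /  sum_k p_k sigma_k^2,

with group weights p_k = n_k / N, group means mu_k, population group
variances sigma_k^2 and grand mean mu.  Large F marks features whose group
means are far apart relative to their spread; a feature that separates the
classes perfectly (zero within-class variance, distinct means) gets
F = +inf and is never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .table import feature_columns

__all__ = [
    "FCoefficientResult",
    "fisher_coefficient",
    "rank_features",
    "select_top_k",
    "FisherScoreSelector",
]


@dataclass(frozen=True)
class FCoefficientResult:
    """Ranking produced by `select_top_k`.

    ``ranking`` has one row per feature with columns ``feature``, ``F``,
    ``rank`` (1 = highest F) and ``selected``; ``k_selected`` is the number
    of retained features.
    """

    ranking: pd.DataFrame
    k_selected: int

    def to_csv(self, path) -> None:
        self.ranking.to_csv(path, index=False)


def _fisher_from_arrays(values: np.ndarray, labels: np.ndarray) -> float:
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("Fisher coefficient needs at least 2 groups")
    n_total = len(values)
    grand_mean = values.mean()
    between = 0.0
    within = 0.0
    for g in groups:
        v = values[labels == g]
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        p = len(v) / n_total
        between += p * (v.mean() - grand_mean) ** 2
        within += p * v.var()  # population variance
    if within == 0.0:
        return np.inf if between > 0.0 else 0.0
    return float(between / within)


def fisher_coefficient(table: pd.DataFrame, feature: str) -> float:
    """Fisher coefficient of one named feature of a labeled feature table."""
    if feature not in table.columns:
        raise KeyError(f"unknown feature {feature!r}")
    return _fisher_from_arrays(
        table[feature].to_numpy(dtype=np.float64), table["group"].to_numpy()
    )


def rank_features(table: pd.DataFrame) -> pd.DataFrame:
    """F value and rank for every feature column; ties broken by name."""
    feats = feature_columns(table)
    f_values = {f: fisher_coefficient(table, f) for f in feats}
    ranking = pd.DataFrame({"feature": feats, "F": [f_values[f] for f in feats]})
    # +inf sorts above all finite values; ties resolved by ascending name
    ranking = ranking.sort_values(
        ["F", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking


def select_top_k(
    table: pd.DataFrame, k: int = 10
) -> tuple[pd.DataFrame, FCoefficientResult]:
    """Retain the k features of highest Fisher coefficient.

    Returns the table restricted to the metadata columns plus the selected
    features (in rank order) and the full ranking.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    feats = feature_columns(table)
    if k > len(feats):
        raise ValueError(f"k={k} exceeds the {len(feats)} available features")
    ranking = rank_features(table)
    ranking["selected"] = ranking["rank"] <= k
    chosen = ranking.loc[ranking["selected"], "feature"].tolist()
    meta = [c for c in table.columns if c not in feats]
    restricted = table[meta + chosen].copy()
    return restricted, FCoefficientResult(ranking=ranking, k_selected=k)


class FisherScoreSelector(SelectorMixin, BaseEstimator):
    """Select the k features with the highest Fisher coefficient.

    scikit-learn selector: ``fit(X, y)`` scores each column by the ratio of
    between-class to within-class variance of the labels ``y``; ``transform``
    keeps the top ``k`` columns.  Ties are broken by feature name (or column
    index for plain arrays) so selection is deterministic.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Fisher coefficient per feature (may contain ``inf``).
    ranks_ : ndarray of shape (n_features,)
        Rank of each feature, 1 = highest score.
    """

    def __init__(self, k: int = 10) -> None:
        self.k = k

    def fit(self, X, y) -> "FisherScoreSelector":
        X = validate_data(self, X, ensure_min_samples=4)
        y = np.asarray(y)
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds the {X.shape[1]} available features")
        self.scores_ = np.array(
            [_fisher_from_arrays(X[:, j], y) for j in range(X.shape[1])]
        )
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = np.array([f"{j:09d}" for j in range(X.shape[1])])
        order = sorted(
            range(X.shape[1]), key=lambda j: (-self.scores_[j], str(names[j]))
        )
        self.ranks_ = np.empty(X.shape[1], dtype=np.int64)
        self.ranks_[order] = np.arange(1, X.shape[1] + 1)
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self)
        return self.ranks_ <= self.k
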