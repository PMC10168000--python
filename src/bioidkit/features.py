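"""Redundant-position removal via Pearson correlation and Gini importance.

Because every identifier is padded to the longest identifier's length, the
trailing character positions of most rows hold only the pad code and carry
little class signal.  Two criteria flag such positions: per-feature Gini
impurity decrease from a seeded random forest (low importance), and pairwise
Pearson correlation between position columns (near-duplicate information).
A feature survives when its importance reaches a configurable fraction of
the maximum importance and it is not strongly correlated with a kept,
more important feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .preprocess import EncodedMatrix

__all__ = [
    "FeatureReport",
    "correlation_matrix",
    "gini_importance",
    "select_features",
    "compute_feature_report",
    "plot_correlation_heatmap",
    "plot_importance",
]


@dataclass
class FeatureReport:
    corr: np.ndarray
    importance: np.ndarray
    kept: np.ndarray  # sorted indices of surviving features
    importance_fraction: float
    corr_threshold: float
    feature_names: list[str]

    def importance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "importance": self.importance,
                "kept": np.isin(np.arange(len(self.importance)), self.kept),
            }
        )

    def corr_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.corr, index=self.feature_names, columns=self.feature_names)


def correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Pearson correlation of feature columns (codes treated as numeric).

    Constant columns have undefined correlation; by convention they get 0
    off-diagonal (so padding columns are judged by importance alone) and 1 on
    the diagonal.
    """
    X = np.asarray(X, dtype=np.float64)
    if len(X) < 2:
        raise ValueError("correlation needs at least 2 rows")
    std = X.std(axis=0)
    varying = std > 0
    L = X.shape[1]
    corr = np.zeros((L, L))
    if varying.any():
        sub = np.corrcoef(X[:, varying], rowvar=False)
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(varying)
        corr[np.ix_(idx, idx)] = sub
    np.fill_diagonal(corr, 1.0)
    return corr


def gini_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int = 100, seed: int = 0
) -> np.ndarray:
    """Mean Gini impurity decrease per feature from a seeded random forest."""
    if len(np.unique(y)) < 2:
        raise ValueError("importance needs at least 2 classes")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(np.asarray(X), np.asarray(y))
    return forest.feature_importances_


def select_features(
    corr: np.ndarray,
    importance: np.ndarray,
    importance_fraction: float = 0.01,
    corr_threshold: float = 0.95,
) -> np.ndarray:
    """Two-stage filter; returns kept feature indices, sorted ascending.

    Stage 1 drops features with importance below ``importance_fraction`` of
    the maximum importance.  Stage 2 greedily visits survivors in decreasing
    importance and drops any feature whose |correlation| with an already-kept
    feature exceeds ``corr_threshold``.  The top-importance feature always
    survives, so the kept set is never empty; with distinct importances the
    result is invariant under feature permutation (ties break by index).
    """
    importance = np.asarray(importance, dtype=float)
    if not 0 <= importance_fraction <= 1 or not 0 <= corr_threshold <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    cutoff = importance_fraction * importance.max()
    survivors = np.flatnonzero(importance >= cutoff)
    # stable sort: descending importance, ascending index on ties
    order = survivors[np.lexsort((survivors, -importance[survivors]))]
    kept: list[int] = []
    for j in order:
        if all(abs(corr[j, k]) <= corr_threshold for k in kept):
            kept.append(int(j))
    return np.array(sorted(kept), dtype=int)


def compute_feature_report(
    data: EncodedMatrix,
    importance_fraction: float = 0.01,
    corr_threshold: float = 0.95,
    n_trees: int = 100,
    seed: int = 0,
) -> FeatureReport:
    if data.y is None:
        raise ValueError("feature report requires labelled data")
    corr = correlation_matrix(data.X)
    imp = gini_importance(data.X, data.y, n_trees=n_trees, seed=seed)
    kept = select_features(corr, imp, importance_fraction, corr_threshold)
    return FeatureReport(
        corr=corr,
        importance=imp,
        kept=kept,
        importance_fraction=importance_fraction,
        corr_threshold=corr_threshold,
        feature_names=list(data.feature_names),
    )


def plot_correlation_heatmap(report: FeatureReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(report.corr, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(report.feature_names)))
    ax.set_yticks(range(len(report.feature_names)))
    ax.set_xticklabels(report.feature_names, rotation=90, fontsize=6)
    ax.set_yticklabels(report.feature_names, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("Position-feature correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_importance(report: FeatureReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    pos = np.arange(len(report.feature_names))
    colors = ["#2a6f97" if j in set(report.kept) else "#c0c0c0" for j in pos]
    ax.barh(pos, report.importance, color=colors)
    ax.set_yticks(pos)
    ax.set_yticklabels(report.feature_names, fontsize=6)
    ax.invert_yaxis()
    ax.set_xlabel("Gini impurity decrease")
    ax.set_title("Feature importance (grey = dropped)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
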