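"""Per-class train/test splitting and SMOTE oversampling toward a common target.

The split keeps 30% of each class (by default) as held-out test rows and the
rest for training.  Training classes smaller than the target size ``T`` are
topped up with synthetic rows produced by SMOTE adapted to integer character
codes: a synthetic row is a convex combination of a real row and one of its
k nearest same-class neighbours, rounded coordinate-wise back to integer
codes.  Test rows are always original data; synthetic rows never leak into
the test side.

The train-side count per class follows a closed form.  With ``n`` original
rows, ``f`` the test fraction and ``T`` the per-class target,

    train(n)    = round_half_even((1 - f) * n)        (exact rational)
    test(n)     = n - train(n)
    balanced(n) = train(n) + max(0, T - n)

With ``T`` the ceiling of the mean class count this arithmetic reproduces,
row for row, the published balanced counts of the 39-class Ensembl-derived
reference corpus (T = 70 551).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .preprocess import EncodedMatrix

__all__ = [
    "BalanceConfig",
    "SplitDataset",
    "train_test_counts",
    "balanced_train_count",
    "default_target",
    "stratified_split",
    "smote_class",
    "balance_dataset",
    "imbalance_ratio",
]


@dataclass(frozen=True)
class BalanceConfig:
    """Balancing behaviour.

    ``target=None`` means "ceiling of the mean class count", the unique
    constant reproducing the reference corpus's published balanced counts.
    ``undersample`` optionally caps majority-class training rows at
    ``undersample_ratio * target`` by seeded random deletion (off by default:
    the reference counts correspond to plain 70% splits of majority classes).
    """

    test_fraction: float = 0.3
    target: int | None = None
    smote_k: int = 5
    undersample: bool = False
    undersample_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie strictly between 0 and 1")
        if self.target is not None and self.target < 1:
            raise ValueError("target must be >= 1")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.undersample_ratio <= 0:
            raise ValueError("undersample_ratio must be positive")


@dataclass
class SplitDataset:
    train: EncodedMatrix
    test: EncodedMatrix
    report: pd.DataFrame  # per-class counts before/after


def _round_half_even(fr: Fraction) -> int:
    floor = fr.numerator // fr.denominator
    rem = fr - floor
    half = Fraction(1, 2)
    if rem > half:
        return floor + 1
    if rem < half:
        return floor
    return floor if floor % 2 == 0 else floor + 1


def train_test_counts(n: int, test_fraction: float = 0.3) -> tuple[int, int]:
    """(train, test) row counts for a class of size ``n``.

    The train side is the banker's rounding of ``(1-f)*n`` evaluated in exact
    rational arithmetic; the test side is the remainder.
    """
    if n < 1:
        raise ValueError("class size must be >= 1")
    frac = Fraction(test_fraction).limit_denominator(10**6)
    train = _round_half_even((1 - frac) * n)
    train = min(max(train, 0), n)
    return train, n - train


def balanced_train_count(n: int, target: int, test_fraction: float = 0.3) -> int:
    """Closed-form training rows per class after splitting and SMOTE top-up."""
    train, _ = train_test_counts(n, test_fraction)
    return train + max(0, target - n)


def default_target(class_counts: Mapping[str, int]) -> int:
    """Ceiling of the mean class count."""
    return math.ceil(Fraction(sum(class_counts.values()), len(class_counts)))


def imbalance_ratio(class_counts: Mapping[str, int] | pd.Series) -> float:
    """Largest class count divided by smallest."""
    counts = pd.Series(dict(class_counts)) if isinstance(class_counts, Mapping) else class_counts
    return float(counts.max() / counts.min())


def stratified_split(
    data: EncodedMatrix, test_fraction: float = 0.3, seed: int = 0
) -> tuple[EncodedMatrix, EncodedMatrix]:
    """Seeded per-class split; test rows are sampled uniformly per class."""
    if data.y is None:
        raise ValueError("stratified split requires labelled data")
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(data), dtype=bool)
    for label in sorted(np.unique(data.y)):
        idx = np.flatnonzero(data.y == label)
        _, n_test = train_test_counts(len(idx), test_fraction)
        chosen = rng.choice(idx, size=n_test, replace=False)
        test_mask[chosen] = True
    return data.subset(~test_mask), data.subset(test_mask)


def smote_class(
    X_class: np.ndarray,
    n_synthetic: int,
    k: int = 5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Synthesize ``n_synthetic`` rows for one class by rounded interpolation.

    Each synthetic row is ``round(x + lam * (neighbour - x))`` for a random
    real row ``x``, one of its ``k`` nearest same-class neighbours (Euclidean
    on the integer codes) and ``lam ~ U[0, 1]``.  Classes with a single row
    fall back to duplication with a warning; ``k`` is clipped to class size
    minus one.
    """
    X_class = np.asarray(X_class)
    if n_synthetic < 0:
        raise ValueError("n_synthetic must be >= 0")
    if n_synthetic == 0:
        return np.empty((0, X_class.shape[1]), dtype=X_class.dtype)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(X_class)
    if n == 0:
        raise ValueError("cannot oversample an empty class")
    if n == 1:
        warnings.warn("single-row class balanced by duplication", stacklevel=2)
        return np.repeat(X_class, n_synthetic, axis=0)
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_class)
    _, neigh = nn.kneighbors(X_class)  # column 0 is the row itself
    base = rng.integers(0, n, size=n_synthetic)
    pick = rng.integers(1, k_eff + 1, size=n_synthetic)
    lam = rng.random(n_synthetic)
    x = X_class[base].astype(np.float64)
    z = X_class[neigh[base, pick]].astype(np.float64)
    synth = np.rint(x + lam[:, None] * (z - x)).astype(X_class.dtype)
    return synth


def balance_dataset(data: EncodedMatrix, config: BalanceConfig | None = None) -> SplitDataset:
    """Split and oversample an encoded, labelled dataset.

    Per class of original size n: the split follows :func:`train_test_counts`;
    classes below the target T receive T - n synthetic training rows; with
    undersampling enabled, majority classes are capped at
    ``undersample_ratio * T`` training rows.  The test side is untouched.
    """
    config = config or BalanceConfig()
    if data.y is None:
        raise ValueError("balancing requires labelled data")
    counts = pd.Series(data.y).value_counts().to_dict()
    target = config.target if config.target is not None else default_target(counts)

    train, test = stratified_split(data, config.test_fraction, config.seed)
    rng = np.random.default_rng(config.seed + 1)

    X_parts = [train.X]
    y_parts = [train.y]
    rows = []
    train_counts = pd.Series(train.y).value_counts().to_dict()
    keep_mask = np.ones(len(train), dtype=bool)
    for label in sorted(counts):
        n = counts[label]
        n_train = train_counts.get(label, 0)
        n_synth = max(0, target - n)
        if n_synth > 0:
            Xc = train.X[train.y == label]
            synth = smote_class(Xc, n_synth, k=config.smote_k, rng=rng)
            X_parts.append(synth)
            y_parts.append(np.full(n_synth, label, dtype=train.y.dtype))
        elif config.undersample:
            cap = int(round(config.undersample_ratio * target))
            if n_train > cap:
                idx = np.flatnonzero(train.y == label)
                drop = rng.choice(idx, size=n_train - cap, replace=False)
                keep_mask[drop] = False
        rows.append(
            {
                "class": label,
                "before": n,
                "test": n - n_train,
                "train_original": n_train,
                "synthetic": n_synth,
            }
        )
    if not keep_mask.all():
        X_parts[0] = train.X[keep_mask]
        y_parts[0] = train.y[keep_mask]
        kept_counts = pd.Series(y_parts[0]).value_counts().to_dict()
        for row in rows:
            row["train_original"] = kept_counts.get(row["class"], 0)

    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    report = pd.DataFrame(rows)
    report["after"] = report["train_original"] + report["synthetic"]
    report.attrs["ratio_before"] = imbalance_ratio(dict(zip(report["class"], report["before"])))
    report.attrs["ratio_after"] = imbalance_ratio(dict(zip(report["class"], report["after"])))
    balanced_train = EncodedMatrix(X, y, data.encoding, list(data.feature_names))
    return SplitDataset(train=balanced_train, test=test, report=report)
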