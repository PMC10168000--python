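"""Unifying the four learners: majority voting with a scoring fallback.

With four voters a 2-2 or 2-1-1 split has no majority.  A label backed by at
least three of the four models wins directly; otherwise each model's vote is
scored and the vote of the highest-scoring model is returned.  Model N
predicting class x scores

    N_score = F1_x^N * prod over other models R (voting y) of
              (c + (1 - c) * P_R(y | x))

where F1_x^N is N's held-out F1 for class x, P_R(y|x) is the row-normalized
held-out confusion entry of model R (the estimated chance that a true-x
sample is predicted y by R), and the constant c in [0, 1] sets how much the
other models' compatibility influences the score: at c = 1 the score
collapses to N's F1 and the others have no effect; the score is affine and
non-decreasing in each P_R(y|x) with slope proportional to (1 - c).

Score ties break toward the model with higher held-out macro-F1, then by the
fixed model order rf, xgb, mlp, cart, so predictions are deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .learners import ModelBundle
from .preprocess import CharEncoding, encode_table

__all__ = [
    "MODEL_ORDER",
    "ScoreContext",
    "EnsemblePrediction",
    "score_model",
    "ensemble_predict",
    "EnsembleModel",
    "predict_batch",
]

#: Fixed tie-break order.
MODEL_ORDER = ("rf", "xgb", "mlp", "cart")


@dataclass
class ScoreContext:
    """Per-model F1 tables and misclassification matrices driving the score."""

    c: float
    f1: dict[str, pd.Series]  # model -> per-class F1
    misclass: dict[str, pd.DataFrame]  # model -> P(pred | true) matrix
    macro_f1: dict[str, float]

    def __post_init__(self) -> None:
        if not 0 <= self.c <= 1:
            raise ValueError("c must lie in [0, 1]")

    @classmethod
    def from_bundles(cls, bundles: dict[str, ModelBundle], c: float = 0.5) -> "ScoreContext":
        """Build a context; classes absent from a model's test partition get
        uniform misclassification rows (with a warning)."""
        f1 = {}
        mis = {}
        macro = {}
        for kind, b in bundles.items():
            m = b.misclass.copy()
            nan_rows = m.isna().all(axis=1)
            if nan_rows.any():
                warnings.warn(
                    f"{kind}: classes absent from test partition get uniform "
                    f"misclassification rows: {list(m.index[nan_rows])}",
                    stacklevel=2,
                )
                m.loc[nan_rows] = 1.0 / len(m.columns)
            mis[kind] = m
            f1[kind] = b.f1
            macro[kind] = b.macro_f1
        return cls(c=c, f1=f1, misclass=mis, macro_f1=macro)


@dataclass
class EnsemblePrediction:
    votes: dict[str, str]
    path: str  # "majority" or "scored"
    scores: dict[str, float] | None
    label: str


def score_model(
    model: str, x: str, others: list[tuple[str, str]], ctx: ScoreContext
) -> float:
    """Score of ``model`` predicting class ``x`` given the other votes."""
    try:
        score = float(ctx.f1[model].loc[x])
    except KeyError as exc:
        raise KeyError(f"class {x!r} missing from F1 table of {model!r}") from exc
    for other, y in others:
        mis = ctx.misclass[other]
        if x not in mis.index or y not in mis.columns:
            raise KeyError(f"class pair ({y!r}|{x!r}) missing from misclass table of {other!r}")
        p = float(mis.loc[x, y])
        score *= ctx.c + (1.0 - ctx.c) * p
    return score


def ensemble_predict(votes: dict[str, str], ctx: ScoreContext) -> EnsemblePrediction:
    """Resolve one sample's per-model votes into a final label.

    A label voted by >= 3 of the 4 models wins outright; otherwise every
    model's vote is scored and the highest-scoring model's vote is returned.
    """
    if set(votes) != set(ctx.f1):
        raise ValueError("vote set does not match the trained model set")
    labels = pd.Series(list(votes.values()))
    top = labels.value_counts()
    if top.iloc[0] >= 3:
        return EnsemblePrediction(votes=dict(votes), path="majority", scores=None, label=top.index[0])
    scores = {m: score_model(m, x, [(o, votes[o]) for o in votes if o != m], ctx)
              for m, x in votes.items()}
    order = {m: i for i, m in enumerate(MODEL_ORDER)}
    winner = max(
        scores,
        key=lambda m: (scores[m], ctx.macro_f1.get(m, 0.0), -order.get(m, len(order))),
    )
    return EnsemblePrediction(votes=dict(votes), path="scored", scores=scores, label=votes[winner])


@dataclass
class EnsembleModel:
    """Four model bundles plus everything needed to predict raw id strings."""

    bundles: dict[str, ModelBundle]
    c: float
    encoding: CharEncoding
    pad_len: int
    kept_features: np.ndarray
    context: ScoreContext = field(init=False)

    def __post_init__(self) -> None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.context = ScoreContext.from_bundles(self.bundles, c=self.c)

    @property
    def classes(self) -> list[str]:
        return next(iter(self.bundles.values())).classes

    def predict_encoded(self, X: np.ndarray) -> pd.DataFrame:
        """Votes and resolved labels for already-encoded, feature-selected rows."""
        n = len(X)
        vote_mat = {kind: b.model.predict(X) for kind, b in self.bundles.items()}
        rows = []
        for i in range(n):
            votes = {kind: str(vote_mat[kind][i]) for kind in self.bundles}
            pred = ensemble_predict(votes, self.context)
            rows.append(
                {
                    "class": pred.label,
                    "path": pred.path,
                    "score": max(pred.scores.values()) if pred.scores else np.nan,
                    **{f"vote_{k}": v for k, v in votes.items()},
                }
            )
        return pd.DataFrame(rows, index=range(n))

    def save(self, path) -> None:
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        model = joblib.load(Path(path))
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not hold an ensemble model")
        return model


def predict_batch(ids: pd.DataFrame, model: EnsembleModel) -> pd.DataFrame:
    """Predict a table of bare id strings; one output row per input row.

    Ids longer than the training pad length are truncated and characters
    outside the training inventory map to the pad code (both warned, rows
    still predicted).  Output preserves input order.
    """
    if len(ids) == 0:
        cols = ["id", "class", "path", "score"] + [f"vote_{k}" for k in model.bundles]
        return pd.DataFrame(columns=cols)
    table = ids[["id"]].copy()
    enc = encode_table(table, encoding=model.encoding, L=model.pad_len, on_unknown="pad")
    X = enc.X[:, model.kept_features]
    out = model.predict_encoded(X)
    out.insert(0, "id", table["id"].to_numpy())
    return out
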