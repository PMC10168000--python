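"""The four classifiers: configuration, hyperband tuning, training, evaluation.

Learner kinds
-------------
``cart``
    Single classification tree (cost-complexity pruned).
``rf``
    Random forest, Gini split criterion.
``xgb``
    Gradient-boosted trees (XGBoost, ``gbtree`` booster, softprob objective).
``mlp``
    Fully connected network with two hidden layers of 40 ReLU units, softmax
    output, Adam optimizer and minibatch training (categorical cross-entropy
    is the native multinomial loss).  Inputs are standardized before the net;
    tree learners consume the raw integer codes.

Default hyperparameters are the reference configuration (see
``docs/methods.md``); :func:`hyperband_tune` re-derives them for the three
tree-based learners by racing sampled configurations on growing fractions of
the training data and keeping the lowest-loss third at each stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .evaluation import confusion, prf_metrics

__all__ = [
    "LEARNER_KINDS",
    "LearnerSpec",
    "default_spec",
    "build_estimator",
    "FittedModel",
    "train_learner",
    "evaluate",
    "ModelBundle",
    "HyperbandSchedule",
    "hyperband",
    "hyperband_tune",
    "DEFAULT_SPACES",
]

LEARNER_KINDS = ("cart", "rf", "xgb", "mlp")


@dataclass(frozen=True)
class LearnerSpec:
    """A learner kind plus its hyperparameters."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}")

    def with_params(self, **updates) -> "LearnerSpec":
        return replace(self, params={**self.params, **updates})


_DEFAULT_PARAMS: dict[str, dict] = {
    # cp maps to sklearn's cost-complexity alpha; min_node to min_samples_split.
    "cart": {"cp": 0.00053, "max_depth": 24, "min_node": 4},
    # minprop belongs to the maximally-selected-rank split rule and is inert
    # under the gini criterion; it is carried in the spec but not mapped.
    "rf": {
        "n_trees": 385,
        "max_depth": 368,
        "criterion": "gini",
        "minprop": 0.017,
        "oob": True,
    },
    "xgb": {
        "eta": 0.29,
        "max_depth": 8,
        "subsample": 0.84,
        "booster": "gbtree",
        "gamma": 0.0,
        "reg_lambda": 0.92,
        "reg_alpha": 0.014,
        "n_rounds": 10,
        "colsample_bytree": 0.99,
    },
    "mlp": {
        "epochs": 64,
        "batch_size": 128,
        "hidden": (40, 40),
        "activation": "relu",
        "optimizer": "adam",
    },
}


def default_spec(kind: str) -> LearnerSpec:
    """Reference hyperparameter configuration for a learner kind."""
    if kind not in _DEFAULT_PARAMS:
        raise ValueError(f"unknown learner kind {kind!r}")
    return LearnerSpec(kind, dict(_DEFAULT_PARAMS[kind]))


def build_estimator(spec: LearnerSpec, seed: int = 0):
    """Materialize a scikit-learn-compatible estimator from a spec."""
    p = spec.params
    if spec.kind == "cart":
        return DecisionTreeClassifier(
            ccp_alpha=p.get("cp", 0.0),
            max_depth=p.get("max_depth"),
            min_samples_split=p.get("min_node", 2),
            random_state=seed,
        )
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=p.get("n_trees", 100),
            max_depth=p.get("max_depth"),
            criterion=p.get("criterion", "gini"),
            oob_score=bool(p.get("oob", False)),
            random_state=seed,
            n_jobs=1,
        )
    if spec.kind == "xgb":
        return XGBClassifier(
            learning_rate=p.get("eta", 0.3),
            max_depth=p.get("max_depth", 6),
            subsample=p.get("subsample", 1.0),
            booster=p.get("booster", "gbtree"),
            gamma=p.get("gamma", 0.0),
            reg_lambda=p.get("reg_lambda", 1.0),
            reg_alpha=p.get("reg_alpha", 0.0),
            n_estimators=p.get("n_rounds", 10),
            colsample_bytree=p.get("colsample_bytree", 1.0),
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    if spec.kind == "mlp":
        net = MLPClassifier(
            hidden_layer_sizes=tuple(p.get("hidden", (40, 40))),
            activation=p.get("activation", "relu"),
            solver=p.get("optimizer", "adam"),
            batch_size=p.get("batch_size", 128),
            max_iter=p.get("epochs", 64),
            shuffle=True,
            random_state=seed,
        )
        return make_pipeline(StandardScaler(), net)
    raise ValueError(f"unknown learner kind {spec.kind!r}")


@dataclass
class FittedModel:
    """A fitted estimator plus the label vocabulary it was trained with.

    Labels are encoded to integer codes internally (XGBoost requires it);
    predictions are mapped back to the original labels.
    """

    spec: LearnerSpec
    estimator: object
    classes: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        codes = np.asarray(self.estimator.predict(np.asarray(X)))
        return self.classes[codes.astype(int)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict_proba(np.asarray(X)))


def train_learner(spec: LearnerSpec, X: np.ndarray, y: np.ndarray, seed: int = 0) -> FittedModel:
    """Fit one learner; deterministic given the seed (single-threaded)."""
    X = np.asarray(X)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty training data")
    classes, codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    est = build_estimator(spec, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, codes)
    return FittedModel(spec=spec, estimator=est, classes=classes)


@dataclass
class ModelBundle:
    """A fitted learner plus its held-out evaluation artifacts."""

    spec: LearnerSpec
    model: FittedModel
    classes: list[str]
    cm: pd.DataFrame  # true x predicted counts
    f1: pd.Series  # per-class F1
    misclass: pd.DataFrame  # row-normalized cm; NaN rows for absent classes
    accuracy: float
    macro_f1: float


def evaluate(model: FittedModel, X_test: np.ndarray, y_test: np.ndarray) -> ModelBundle:
    """Confusion matrix, per-class F1 and misclassification probabilities.

    ``misclass[x][y]`` estimates the probability that a sample of true class
    x is predicted y; rows for classes absent from the test set are NaN and
    flagged downstream.
    """
    y_test = np.asarray(y_test)
    unseen = set(np.unique(y_test)) - set(model.classes)
    if unseen:
        raise ValueError(f"test classes unseen in training: {sorted(unseen)}")
    y_pred = model.predict(X_test)
    class_order = list(model.classes)
    cm = confusion(y_test, y_pred, class_order)
    metrics = prf_metrics(cm)
    row_sums = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mis = cm.div(row_sums, axis=0)
    mis[row_sums == 0] = np.nan
    return ModelBundle(
        spec=model.spec,
        model=model,
        classes=class_order,
        cm=cm,
        f1=metrics.per_class["F1"],
        misclass=mis,
        accuracy=metrics.accuracy,
        macro_f1=metrics.macro_f1,
    )


# ---------------------------------------------------------------------------
# Hyperband
# ---------------------------------------------------------------------------


@dataclass
class HyperbandSchedule:
    """Record of every bracket/stage of a hyperband run."""

    eta: int
    stages: int
    R: int
    records: pd.DataFrame  # bracket, stage, config_id, resource, loss

    @property
    def n_sampled(self) -> int:
        """Distinct configurations sampled (evaluated at their first stage)."""
        return self.records["config_id"].nunique()

    def stage_sizes(self) -> pd.DataFrame:
        return (
            self.records.groupby(["bracket", "stage"])
            .agg(n_configs=("config_id", "nunique"), resource=("resource", "first"))
            .reset_index()
        )


def hyperband(
    sample_config: Callable[[np.random.Generator], dict],
    objective: Callable[[dict, float], float],
    eta: int = 3,
    stages: int = 4,
    seed: int = 0,
) -> tuple[dict, float, HyperbandSchedule]:
    """Generic hyperband over an arbitrary configuration sampler.

    ``stages`` is the number of successive-halving stages in the largest
    bracket (s_max + 1); the maximum resource is ``R = eta**(stages-1)`` and
    ``objective(config, resource_fraction)`` returns the validation loss when
    a configuration is trained with ``resource_fraction`` in (0, 1] of the
    full budget.  Within every bracket only the lowest-loss third (1/eta)
    advances, at eta-fold larger resource; ties break by sampling order.
    Returns the lowest-loss configuration over all evaluations.
    """
    if eta < 2:
        raise ValueError("eta must be >= 2")
    if stages < 1:
        raise ValueError("stages must be >= 1")
    rng = np.random.default_rng(seed)
    s_max = stages - 1
    R = eta**s_max
    records = []
    best: tuple[float, int, dict] | None = None
    next_id = 0
    for bracket in range(s_max, -1, -1):
        n = math.ceil((s_max + 1) / (bracket + 1) * eta**bracket)
        r = R * eta ** (-bracket)
        configs = []
        for _ in range(n):
            configs.append((next_id, sample_config(rng)))
            next_id += 1
        for stage in range(bracket + 1):
            n_i = math.floor(n * eta ** (-stage))
            r_i = r * eta**stage
            configs = configs[:n_i]
            scored = []
            for cid, cfg in configs:
                loss = float(objective(cfg, r_i / R))
                records.append(
                    {
                        "bracket": bracket,
                        "stage": stage,
                        "config_id": cid,
                        "resource": r_i / R,
                        "loss": loss,
                    }
                )
                scored.append((loss, cid, cfg))
                if best is None or loss < best[0]:
                    best = (loss, cid, cfg)
            # stable sort keeps sampling order on ties
            scored.sort(key=lambda t: t[0])
            configs = [(cid, cfg) for _, cid, cfg in scored]
    assert best is not None
    schedule = HyperbandSchedule(eta=eta, stages=stages, R=R, records=pd.DataFrame(records))
    return best[2], best[0], schedule


#: Bounded search boxes around the reference configuration.  Each entry is
#: (sampler kind, low, high) or ("choice", values).
DEFAULT_SPACES: dict[str, dict[str, tuple]] = {
    "cart": {
        "cp": ("logfloat", 1e-5, 1e-2),
        "max_depth": ("int", 8, 30),
        "min_node": ("int", 2, 16),
    },
    "rf": {
        "n_trees": ("int", 100, 500),
        "max_depth": ("int", 50, 400),
    },
    "xgb": {
        "eta": ("float", 0.05, 0.5),
        "max_depth": ("int", 3, 10),
        "subsample": ("float", 0.5, 1.0),
        "colsample_bytree": ("float", 0.5, 1.0),
        "reg_lambda": ("logfloat", 0.1, 2.0),
    },
}


def _make_sampler(space: dict[str, tuple]) -> Callable[[np.random.Generator], dict]:
    if not space:
        raise ValueError("empty search space")

    def sample(rng: np.random.Generator) -> dict:
        cfg = {}
        for name, rule in space.items():
            kind = rule[0]
            if kind == "float":
                cfg[name] = float(rng.uniform(rule[1], rule[2]))
            elif kind == "logfloat":
                cfg[name] = float(np.exp(rng.uniform(np.log(rule[1]), np.log(rule[2]))))
            elif kind == "int":
                cfg[name] = int(rng.integers(rule[1], rule[2] + 1))
            elif kind == "choice":
                cfg[name] = rule[1][int(rng.integers(len(rule[1])))]
            else:
                raise ValueError(f"unknown sampler {kind!r} for {name!r}")
        return cfg

    return sample


def hyperband_tune(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    eta: int = 3,
    stages: int = 4,
    seed: int = 0,
    space: dict[str, tuple] | None = None,
) -> tuple[LearnerSpec, HyperbandSchedule]:
    """Tune one tree-based learner with hyperband.

    The resource is the fraction of training rows: a configuration evaluated
    at resource ``f`` is trained on a seeded ``f``-fraction subsample of an
    80% tranche of the data and scored by classification error on the fixed
    remaining 20%.  Returns the best spec (reference defaults overridden by
    the winning configuration) and the full schedule.
    """
    if kind not in DEFAULT_SPACES:
        raise ValueError(f"no tuning space for learner kind {kind!r}")
    space = space if space is not None else DEFAULT_SPACES[kind]
    X = np.asarray(X)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(X))
    n_val = max(1, int(0.2 * len(X)))
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    base = default_spec(kind)
    n_classes = len(np.unique(y))

    def objective(cfg: dict, fraction: float) -> float:
        m = max(2 * n_classes, int(round(fraction * len(fit_idx))))
        sub = fit_idx[:m]
        if len(np.unique(y[sub])) < 2:
            return 1.0
        model = train_learner(base.with_params(**cfg), X[sub], y[sub], seed=seed)
        pred = model.predict(X[val_idx])
        return float(np.mean(pred != y[val_idx]))

    best_cfg, _, schedule = hyperband(
        _make_sampler(space), objective, eta=eta, stages=stages, seed=seed + 1
    )
    return base.with_params(**best_cfg), schedule


def plot_tuning_stages(schedule: HyperbandSchedule, path, title: str = "") -> None:
    """Loss-vs-stage trajectories, one line per surviving configuration."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cid, grp in schedule.records.groupby("config_id"):
        ax.plot(grp["stage"], grp["loss"], marker="o", ms=3, lw=0.8, alpha=0.7)
    ax.set_xlabel("successive-halving stage")
    ax.set_ylabel("validation loss")
    ax.set_title(title or "Hyperband tuning stages")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
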