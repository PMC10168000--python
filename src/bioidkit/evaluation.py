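"""Confusion matrices, per-class metrics and report export.

Per-class metrics are one-vs-rest reductions of the confusion matrix:

    Acc = (TP + TN) / (TP + FN + FP + TN)
    Pre = TP / (TP + FP)
    Rec = TP / (TP + FN)
    F1  = 2 TP / (2 TP + FN + FP)

Undefined ratios (0/0, e.g. a class never predicted and never present) are
reported as 0 and flagged in the ``undefined`` column so tables stay
rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["MetricsTable", "confusion", "prf_metrics", "plot_confusion_heatmap", "export_report"]


@dataclass
class MetricsTable:
    per_class: pd.DataFrame  # Acc, Pre, Rec, F1, undefined
    accuracy: float  # trace(cm) / total
    macro_f1: float


def confusion(y_true, y_pred, class_order: list[str]) -> pd.DataFrame:
    """Count matrix: ``cm.loc[x, y]`` = samples of true class x predicted y."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    known = set(class_order)
    stray = (set(y_true) | set(y_pred)) - known
    if stray:
        raise ValueError(f"labels outside class order: {sorted(stray)}")
    cm = _sk_confusion(y_true, y_pred, labels=class_order)
    return pd.DataFrame(cm, index=class_order, columns=class_order)


def prf_metrics(cm: pd.DataFrame) -> MetricsTable:
    """One-vs-rest accuracy/precision/recall/F1 per class plus aggregates."""
    if cm.size == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.to_numpy(dtype=np.int64)
    total = counts.sum()
    tp = np.diag(counts).astype(float)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def safe_div(num, den):
        und = den == 0
        out = np.divide(num, den, out=np.zeros_like(num, dtype=float), where=~und)
        return out, und

    acc = (tp + tn) / total
    pre, pre_und = safe_div(tp, tp + fp)
    rec, rec_und = safe_div(tp, tp + fn)
    f1, f1_und = safe_div(2 * tp, 2 * tp + fn + fp)
    per_class = pd.DataFrame(
        {
            "Acc": acc,
            "Pre": pre,
            "Rec": rec,
            "F1": f1,
            "undefined": pre_und | rec_und | f1_und,
        },
        index=cm.index,
    )
    return MetricsTable(
        per_class=per_class,
        accuracy=float(tp.sum() / total),
        macro_f1=float(f1.mean()),
    )


def plot_confusion_heatmap(cm: pd.DataFrame, path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    with np.errstate(divide="ignore"):
        shade = np.log10(cm.to_numpy() + 1)
    im = ax.imshow(shade, cmap="viridis")
    ax.set_xticks(range(len(cm.columns)))
    ax.set_yticks(range(len(cm.index)))
    ax.set_xticklabels(cm.columns, rotation=90, fontsize=5)
    ax.set_yticklabels(cm.index, fontsize=5)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax, label="log10(count + 1)")
    ax.set_title(title or "Confusion matrix")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_report(bundles: dict, ensemble_metrics: MetricsTable | None, out_dir) -> list[Path]:
    """Write per-model and ensemble metric tables, confusion TSVs and heatmaps.

    Deterministic and idempotent: identical inputs yield byte-identical TSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def dump(df: pd.DataFrame, name: str, index_label: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", float_format="%.6f", index_label=index_label)
        written.append(path)

    for kind, bundle in bundles.items():
        metrics = prf_metrics(bundle.cm)
        dump(metrics.per_class, f"{kind}_metrics.tsv", "class")
        dump(bundle.cm, f"{kind}_confusion.tsv", "class")
        heat = out / f"{kind}_confusion.png"
        plot_confusion_heatmap(bundle.cm, heat, title=f"{kind} confusion matrix")
        written.append(heat)
    if ensemble_metrics is not None:
        dump(ensemble_metrics.per_class, "ensemble_metrics.tsv", "class")
    return written
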