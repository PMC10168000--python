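"""End-to-end workflow: generate -> clean -> encode -> balance -> filter ->
(tune) -> train x4 -> evaluate -> ensemble -> report.

A run is fully reproducible from (config, seed): the global seed fans out to
per-stage seeds via stable hashing of stage names, so any stage re-run in
isolation from persisted artifacts sees the same randomness.  Every stage
writes its artifact into the run directory; a failure aborts with the stage
name while earlier artifacts remain on disk.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balance import BalanceConfig, balance_dataset
from .ensemble import EnsembleModel
from .evaluation import confusion, export_report, prf_metrics
from .features import (
    compute_feature_report,
    plot_correlation_heatmap,
    plot_importance,
)
from .learners import (
    LEARNER_KINDS,
    default_spec,
    evaluate,
    hyperband_tune,
    plot_tuning_stages,
    train_learner,
)
from .preprocess import clean_table, default_char_encoding, encode_table, write_id_table
from .registry import Registry, default_registry, validate_profile

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "PipelineError"]

log = logging.getLogger("bioidkit")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from the global seed."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything a run needs; serializable to/from YAML."""

    profile: dict[str, int] | None = None  # None: every registry class
    ids_per_class: int = 1000  # used when profile is None
    registry_path: str | None = None  # None: built-in registry
    dataset_path: str | None = None  # pre-made ID table; skips generation
    test_fraction: float = 0.3
    target: int | None = None
    smote_k: int = 5
    undersample: bool = False
    importance_fraction: float = 0.01
    corr_threshold: float = 0.95
    feature_trees: int = 50
    tune: bool = False
    eta: int = 3
    stages: int = 4
    learner_overrides: dict[str, dict] = field(default_factory=dict)
    c: float = 0.5
    seed: int = 42
    out_dir: str = "runs/run"

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        stray = set(payload) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        return cls(**payload)


def _load_registry(config: RunConfig) -> Registry:
    if config.registry_path:
        return Registry.load(config.registry_path)
    return default_registry()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "timings_s": {},
    }
    config.to_yaml(out / "config.yaml")

    def run_stage(name, fn):
        start = time.time()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["timings_s"][name] = round(time.time() - start, 3)
        log.info("stage %s done in %.1fs", name, manifest["timings_s"][name])
        return result

    registry = _load_registry(config)

    # -- generate ----------------------------------------------------------
    def _generate():
        if config.dataset_path:
            from .preprocess import read_id_table

            table = read_id_table(config.dataset_path)
        else:
            profile = config.profile or {
                name: config.ids_per_class for name in registry.names
            }
            validate_profile(profile, registry)
            table = registry.generate_dataset(profile, seed=stage_seed(config.seed, "generate"))
        write_id_table(table, out / "dataset.tsv")
        return table

    raw = run_stage("generate", _generate)

    # -- clean + encode ----------------------------------------------------
    def _encode():
        table = clean_table(raw)
        encoding = default_char_encoding()
        enc = encode_table(table, encoding=encoding)
        encoding.to_json(out / "encoding.json")
        counts = table["class"].value_counts()
        manifest["stages"]["encode"] = {
            "rows": len(table),
            "classes": int(counts.size),
            "pad_len": enc.n_features,
        }
        return enc

    encoded = run_stage("encode", _encode)

    # -- balance -----------------------------------------------------------
    def _balance():
        bconf = BalanceConfig(
            test_fraction=config.test_fraction,
            target=config.target,
            smote_k=config.smote_k,
            undersample=config.undersample,
            seed=stage_seed(config.seed, "balance"),
        )
        split = balance_dataset(encoded, bconf)
        split.report.to_csv(out / "balance_report.tsv", sep="\t", index=False)
        manifest["stages"]["balance"] = {
            "train_rows": len(split.train),
            "test_rows": len(split.test),
            "ratio_before": split.report.attrs["ratio_before"],
            "ratio_after": split.report.attrs["ratio_after"],
        }
        return split

    split = run_stage("balance", _balance)

    # -- feature filtering --------------------------------------------------
    def _features():
        report = compute_feature_report(
            split.train,
            importance_fraction=config.importance_fraction,
            corr_threshold=config.corr_threshold,
            n_trees=config.feature_trees,
            seed=stage_seed(config.seed, "features"),
        )
        report.importance_table().to_csv(out / "feature_importance.tsv", sep="\t", index=False)
        report.corr_table().to_csv(out / "feature_correlation.tsv", sep="\t")
        plot_correlation_heatmap(report, out / "feature_correlation.png")
        plot_importance(report, out / "feature_importance.png")
        manifest["stages"]["features"] = {
            "kept": [report.feature_names[j] for j in report.kept],
        }
        return report

    feat = run_stage("features", _features)
    kept = feat.kept
    X_train = split.train.X[:, kept]
    y_train = split.train.y
    X_test = split.test.X[:, kept]
    y_test = split.test.y

    # -- tune / specs --------------------------------------------------------
    def _specs():
        specs = {}
        for kind in LEARNER_KINDS:
            spec = default_spec(kind)
            if config.tune and kind != "mlp":
                spec, schedule = hyperband_tune(
                    kind,
                    X_train,
                    y_train,
                    eta=config.eta,
                    stages=config.stages,
                    seed=stage_seed(config.seed, f"tune-{kind}"),
                )
                schedule.records.to_csv(out / f"tuning_{kind}.tsv", sep="\t", index=False)
                plot_tuning_stages(schedule, out / f"tuning_{kind}.png", title=f"{kind} tuning")
            if kind in config.learner_overrides:
                spec = spec.with_params(**config.learner_overrides[kind])
            specs[kind] = spec
        return specs

    specs = run_stage("tune" if config.tune else "specs", _specs)

    # -- train + evaluate ----------------------------------------------------
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)

    def _train():
        bundles = {}
        for kind in LEARNER_KINDS:
            seed = stage_seed(config.seed, f"train-{kind}")
            model = train_learner(specs[kind], X_train, y_train, seed=seed)
            bundle = evaluate(model, X_test, y_test)
            bundles[kind] = bundle
            joblib.dump(model, models_dir / f"{kind}.joblib")
            bundle.cm.to_csv(models_dir / f"{kind}_cm.tsv", sep="\t", index_label="class")
            bundle.f1.to_frame("F1").to_csv(models_dir / f"{kind}_f1.tsv", sep="\t", index_label="class")
            bundle.misclass.to_csv(
                models_dir / f"{kind}_misclass.tsv", sep="\t", index_label="class", float_format="%.6f"
            )
            manifest["stages"][f"train-{kind}"] = {
                "accuracy": bundle.accuracy,
                "macro_f1": bundle.macro_f1,
                "params": {k: str(v) for k, v in specs[kind].params.items()},
            }
            log.info("%s held-out accuracy %.4f macro-F1 %.4f", kind, bundle.accuracy, bundle.macro_f1)
        return bundles

    bundles = run_stage("train", _train)

    # -- ensemble ------------------------------------------------------------
    def _ensemble():
        model = EnsembleModel(
            bundles=bundles,
            c=config.c,
            encoding=encoded.encoding,
            pad_len=encoded.n_features,
            kept_features=kept,
        )
        model.save(models_dir / "ensemble.joblib")
        preds = model.predict_encoded(X_test)
        preds.insert(0, "true_class", y_test)
        preds.to_csv(out / "predictions.tsv", sep="\t", index=False, float_format="%.6f")
        cm = confusion(y_test, preds["class"].to_numpy(), model.classes)
        metrics = prf_metrics(cm)
        manifest["stages"]["ensemble"] = {
            "accuracy": metrics.accuracy,
            "macro_f1": metrics.macro_f1,
            "scored_rows": int((preds["path"] == "scored").sum()),
        }
        log.info("ensemble held-out accuracy %.4f macro-F1 %.4f", metrics.accuracy, metrics.macro_f1)
        return cm, metrics

    ensemble_cm, ensemble_metrics = run_stage("ensemble", _ensemble)

    # -- report --------------------------------------------------------------
    def _report():
        paths = export_report(bundles, ensemble_metrics, out / "report")
        ensemble_cm.to_csv(out / "report" / "ensemble_confusion.tsv", sep="\t", index_label="class")
        from .evaluation import plot_confusion_heatmap

        plot_confusion_heatmap(ensemble_cm, out / "report" / "ensemble_confusion.png", "ensemble")
        return paths

    run_stage("report", _report)

    manifest["total_s"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def _setup_logging(logfile: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(stream)
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
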