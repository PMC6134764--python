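"""End-to-end pipeline: simulate/ingest -> gate -> vectorize -> club ->
split -> anomaly screen -> model comparison -> reports.

A single flat YAML config drives the run; every source of randomness is a
named substream of one top-level seed, so a completed run is fully
reproducible from the resolved config written into its run directory.
Unknown config keys are errors (typo guard).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import autoencoder as ae
from . import evaluation as ev
from . import models as md
from .fingerprint import (
    DEFAULT_CLUBBING,
    build_dataset,
    club_labels,
    split_train_test,
)
from .io_fcs import GateConfig
from .synthetic import StudyDesign, default_classes, make_anomaly_class, simulate_study

logger = logging.getLogger("cytofingerprint")


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG: dict[str, Any] = {
    "mode": "synthetic",  # synthetic | manifest
    "seed": 0,
    "output_dir": "runs",
    "run_name": None,
    "log_level": "INFO",
    "manifest": None,  # path, manifest mode only
    "synthetic": {
        # Desk-scale default: the full-study geometry (3 replicates x
        # 5 time points x 4 classes) at a reduced per-sample event count.
        "events_per_sample": 5000,
        "replicates": 3,
        "timepoints": 5,
        "format": "csv",
        "anomaly_shift": None,  # e.g. [12000, 12000, 3000]
        "anomaly_base": "ACET",
        "anomaly_label": "PERT",
    },
    "gate": {"lower_bounds": {}, "fsc_upper_bound": None},
    "chunk_size": 1000,
    "clubbing": "none",  # none | default | explicit map
    "split": {"train_fraction": 0.75, "by_replicate": False},
    "autoencoder": {
        "enabled": True,
        "hidden_nodes": 2000,
        "epochs": 10,
        "activation": "tanh",
        "learning_rate": 1e-3,
        "batch_size": 32,
        "threshold": None,  # None -> percentile of training-sample scores
        "threshold_percentile": 95.0,
        "aggregate": "mean",
        "holdout_labels": [],  # excluded from autoencoder training
    },
    "models": {
        "algorithms": ["GB", "NB", "DRF", "DL"],
        "hyperparameters": {},  # per-algorithm overrides
        "nested_cv": False,
        "grids": {},  # per-algorithm hyperparameter grids
        "kfold_stability": 0,  # k; 0 disables
    },
    "evaluation": {"plots": True},
}


def _merge_validate(defaults: Mapping, given: Mapping, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in given.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path + key!r}")
        if (
            isinstance(defaults[key], Mapping)
            and key not in ("hyperparameters", "grids", "lower_bounds")
        ):
            if not isinstance(value, Mapping):
                raise ConfigError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge_validate(defaults[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def resolve_config(cfg: Mapping | None = None) -> dict:
    """Fill in defaults and reject unknown keys."""
    cfg = cfg or {}
    resolved = _merge_validate(DEFAULT_CONFIG, cfg)
    if resolved["mode"] not in ("synthetic", "manifest"):
        raise ConfigError(f"mode must be 'synthetic' or 'manifest', got {resolved['mode']!r}")
    if resolved["mode"] == "manifest" and not resolved["manifest"]:
        raise ConfigError("manifest mode requires the 'manifest' path")
    if resolved["chunk_size"] < 1:
        raise ConfigError("chunk_size must be >= 1")
    return resolved


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must hold a mapping")
    return resolve_config(data)


def _substream(seed: int, stage: str) -> int:
    """Named, stable substream of the top-level seed for one stage."""
    h = np.random.SeedSequence(
        [seed, int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "big")]
    )
    return int(h.generate_state(1)[0] % (2**31))


def run_pipeline(cfg: Mapping | None = None, out_dir: str | Path | None = None) -> Path:
    """Run every stage; returns the run directory.

    On a stage failure, partial outputs are kept and a FAILED marker names
    the stage; the exception is re-raised as :class:`StageError`.
    """
    cfg = resolve_config(cfg)
    seed = int(cfg["seed"])
    run_name = cfg["run_name"] or time.strftime("run-%Y%m%d-%H%M%S")
    run_dir = Path(out_dir) if out_dir is not None else Path(cfg["output_dir"]) / run_name
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    with open(run_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    run_log: dict[str, Any] = {"stages": {}}
    stage = "setup"
    try:
        # -- input ----------------------------------------------------------
        stage = "input"
        if cfg["mode"] == "synthetic":
            sc = cfg["synthetic"]
            classes = list(default_classes())
            if sc["anomaly_shift"] is not None:
                base = {c.class_label: c for c in classes}[sc["anomaly_base"]]
                classes.append(
                    make_anomaly_class(base, sc["anomaly_shift"], sc["anomaly_label"])
                )
            design = StudyDesign(
                classes=tuple(classes),
                replicates=int(sc["replicates"]),
                timepoints=int(sc["timepoints"]),
                events_per_sample=int(sc["events_per_sample"]),
                seed=_substream(seed, "simulate"),
            )
            data_dir = run_dir / "data" / "events"
            manifest = simulate_study(design, data_dir, format=sc["format"])
        else:
            manifest = Path(cfg["manifest"])
        run_log["stages"]["input"] = {"manifest": str(manifest)}

        # -- gate + vectorize -----------------------------------------------
        stage = "vectorize"
        gate_cfg = cfg["gate"]
        gate = GateConfig(
            lower_bounds=dict(gate_cfg["lower_bounds"] or {}),
            fsc_upper_bound=(
                float(gate_cfg["fsc_upper_bound"])
                if gate_cfg["fsc_upper_bound"] is not None
                else float("inf")
            ),
        )
        ds = build_dataset(manifest, gate=gate, chunk_size=int(cfg["chunk_size"]))
        (run_dir / "data").mkdir(exist_ok=True)
        ds.to_csv(run_dir / "data" / "dataset.csv")
        run_log["stages"]["vectorize"] = {
            "n_vectors": len(ds),
            "n_features": ds.n_features,
            "labels": {l: int(np.sum(ds.labels == l)) for l in ds.label_set},
        }

        # -- clubbing ---------------------------------------------------------
        stage = "club"
        clubbing = cfg["clubbing"]
        anomaly_labels = set(cfg["autoencoder"]["holdout_labels"])
        if clubbing == "default":
            mapping = dict(DEFAULT_CLUBBING)
            for lab in set(ds.labels) - set(mapping):
                if lab in anomaly_labels:
                    mapping[lab] = lab  # anomaly classes keep their own label
            ds = club_labels(ds, mapping)
        elif isinstance(clubbing, Mapping):
            ds = club_labels(ds, clubbing)
        elif clubbing != "none":
            raise ConfigError(f"clubbing must be 'none', 'default' or a map, got {clubbing!r}")
        run_log["stages"]["club"] = {"labels": ds.label_set}

        # -- split ------------------------------------------------------------
        stage = "split"
        train_ds, test_ds = split_train_test(
            ds,
            train_fraction=float(cfg["split"]["train_fraction"]),
            seed=_substream(seed, "split"),
            by_replicate=bool(cfg["split"]["by_replicate"]),
        )
        train_ds.to_csv(run_dir / "data" / "train.csv")
        test_ds.to_csv(run_dir / "data" / "test.csv")
        run_log["stages"]["split"] = {"n_train": len(train_ds), "n_test": len(test_ds)}

        # -- anomaly screen ---------------------------------------------------
        stage = "anomaly"
        if cfg["autoencoder"]["enabled"]:
            ac = cfg["autoencoder"]
            keep = ~np.isin(train_ds.labels.astype(str), sorted(anomaly_labels))
            ae_train = train_ds.subset(np.flatnonzero(keep))
            ae_cfg = ae.AutoencoderConfig(
                hidden_nodes=int(ac["hidden_nodes"]),
                epochs=int(ac["epochs"]),
                activation=ac["activation"],
                learning_rate=float(ac["learning_rate"]),
                batch_size=int(ac["batch_size"]),
                seed=_substream(seed, "autoencoder"),
            )
            model = ae.train_autoencoder(ae_train, ae_cfg)
            threshold = (
                float(ac["threshold"])
                if ac["threshold"] is not None
                else ae.threshold_from_training(
                    model, ae_train, percentile=float(ac["threshold_percentile"]),
                    aggregate=ac["aggregate"],
                )
            )
            report = ae.score_samples(model, ds, threshold, aggregate=ac["aggregate"])
            anomaly_dir = run_dir / "anomaly"
            anomaly_dir.mkdir(exist_ok=True)
            report.to_csv(anomaly_dir / "anomaly.csv")
            model.save(anomaly_dir / "autoencoder.npz")
            if cfg["evaluation"]["plots"]:
                report.plot(anomaly_dir / "mse_by_sample.png")
            run_log["stages"]["anomaly"] = {
                "threshold": threshold,
                "n_outliers": int(report.per_sample["is_outlier"].sum()),
                "final_training_mse": model.loss_history[-1],
            }

        # -- supervised comparison -------------------------------------------
        stage = "models"
        mc = cfg["models"]
        cls_train = train_ds
        cls_test = test_ds
        if anomaly_labels:
            keep_tr = ~np.isin(cls_train.labels.astype(str), sorted(anomaly_labels))
            keep_te = ~np.isin(cls_test.labels.astype(str), sorted(anomaly_labels))
            cls_train = cls_train.subset(np.flatnonzero(keep_tr))
            cls_test = cls_test.subset(np.flatnonzero(keep_te))
        per_model_acc: dict[str, tuple[float, dict[str, float]]] = {}
        per_model_roc: dict[str, dict[str, ev.ROCResult]] = {}
        reports_dir = run_dir / "reports"
        reports_dir.mkdir(exist_ok=True)
        models_dir = run_dir / "models"
        models_dir.mkdir(exist_ok=True)
        model_log: dict[str, Any] = {}
        for algo in mc["algorithms"]:
            algo_seed = _substream(seed, f"model-{algo}")
            overrides = dict(mc["hyperparameters"].get(algo, {}))
            if mc["nested_cv"] and algo in mc["grids"]:
                spec, cv = md.nested_cv_grid_search(
                    algo, mc["grids"][algo], cls_train,
                    seed=_substream(seed, f"cv-{algo}"),
                )
                spec = md.ModelSpec(algo, {**spec.hyperparameters, **overrides}, seed=algo_seed)
                model_log[f"{algo}_nested_cv"] = {
                    "outer_fold_accuracies": cv.fold_accuracies,
                    "best_params": cv.best_params,
                }
            else:
                spec = md.ModelSpec(algo, overrides, seed=algo_seed)
            clf = md.train(spec, cls_train)
            clf.save(models_dir / f"{algo}.pkl")
            overall, per_class = md.accuracy(clf, cls_test)
            per_model_acc[algo] = (overall, per_class)
            probs = clf.predict_proba(cls_test)
            classes = list(clf.classes_)
            per_model_roc[algo] = ev.all_roc(probs, cls_test.labels, classes)
            ev.confusion_matrix(clf.predict(cls_test), cls_test.labels).to_csv(
                reports_dir / f"confusion_{algo}.csv"
            )
            ev.class_probability_summary(probs, cls_test.labels, classes).to_csv(
                reports_dir / f"probability_summary_{algo}.csv", index=False
            )
            if algo == "DL":
                imp = ev.gedeon_importance(clf, chunk_size=int(cfg["chunk_size"]))
                imp.to_frame().to_csv(reports_dir / "importance_DL.csv", index=False)
                with open(reports_dir / "importance_DL_blocks.json", "w") as fh:
                    json.dump(imp.per_block, fh, indent=2)
            if mc["kfold_stability"]:
                cv = md.kfold_stability(
                    spec, cls_train, k=int(mc["kfold_stability"]),
                    seed=_substream(seed, f"kfold-{algo}"),
                )
                model_log[f"{algo}_kfold"] = {
                    "fold_accuracies": cv.fold_accuracies,
                    "mean": cv.mean,
                    "sd": cv.sd,
                }
            model_log[algo] = {"overall_accuracy": overall, "per_class": per_class}
        run_log["stages"]["models"] = model_log

        # -- report tables ----------------------------------------------------
        stage = "report"
        ev.accuracy_table(per_model_acc).to_csv(reports_dir / "accuracy.csv")
        ev.auc_table(per_model_roc).to_csv(reports_dir / "auc.csv")
        for algo, rocs in per_model_roc.items():
            frames = [r.to_frame() for r in rocs.values()]
            if frames:
                import pandas as pd

                pd.concat(frames, ignore_index=True).to_csv(
                    reports_dir / f"roc_{algo}.csv", index=False
                )
        if cfg["evaluation"]["plots"]:
            ev.plot_roc(per_model_roc, reports_dir / "roc_curves.png")
    except Exception as exc:
        (run_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        with open(run_dir / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=2, default=str)
        raise StageError(stage, exc) from exc

    with open(run_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    return run_dir
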