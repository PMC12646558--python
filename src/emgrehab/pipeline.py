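"""Run configuration and the staged end-to-end analysis pipeline.

Stage order: simulate -> preprocess -> features -> classify -> correlate ->
clinical -> report. Every persisted artifact carries the hash of the run
configuration; a stage refuses to consume intermediates produced under a
different hash. Stages are idempotent: re-running with an unchanged
configuration reuses (and reproduces) existing intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .classify import (ClassifierSpec, CvSpec, classifier_mean_summary,
                       crossval_accuracy, progression_table, reports_frame)
from .clinical import (McidThresholds, StatsConfig, correlation_table,
                       outcome_summary, summarize_patient_features)
from .core import ConfigurationError, DataError
from .features import FeatureSpec, build_feature_table
from .preprocess import PreprocessConfig, extract_epochs, make_windows, preprocess
from .synth import (AcquisitionProtocol, ClinicalLink, CohortConfig,
                    RecoveryModel, generate_dataset, make_cohort)

log = logging.getLogger(__name__)


def _build(cls, data: dict | None):
    data = dict(data or {})
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one analysis run (round-trips through YAML)."""

    seed: int = 0
    dataset_dir: str = "dataset"
    out_dir: str = "out"
    log_level: str = "INFO"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureSpec = field(default_factory=FeatureSpec)
    classifiers: tuple[str, ...] = ("knn", "random_forest", "svm")
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    cv: CvSpec = field(default_factory=lambda: CvSpec(folds=3))
    stats: StatsConfig = field(default_factory=StatsConfig)
    mcid: McidThresholds = field(default_factory=McidThresholds)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        seed = int(data.get("seed", 0))
        cohort_d = dict(data.get("cohort", {}))
        cohort_d.setdefault("seed", seed)
        rates_d = cohort_d.pop("rates", None)
        if rates_d is not None:
            cohort_d["rates"] = {g: _build(RecoveryModel, r) for g, r in rates_d.items()}
        clin_d = cohort_d.pop("clinical", None)
        if clin_d is not None:
            cohort_d["clinical"] = _build(ClinicalLink, clin_d)
        clf_d = dict(data.get("classifier", {}))
        clf_d.setdefault("seed", seed)
        cv_d = dict(data.get("cv", {"folds": 3}))
        cv_d.setdefault("seed", seed)
        return cls(
            seed=seed,
            dataset_dir=data.get("dataset_dir", "dataset"),
            out_dir=data.get("out_dir", "out"),
            log_level=data.get("log_level", "INFO"),
            cohort=_build(CohortConfig, cohort_d),
            protocol=_build(AcquisitionProtocol, data.get("protocol")),
            preprocess=_build(PreprocessConfig, data.get("preprocess")),
            features=_build(FeatureSpec, data.get("features")),
            classifiers=tuple(data.get("classifiers", ("knn", "random_forest", "svm"))),
            classifier=_build(ClassifierSpec, clf_d),
            cv=_build(CvSpec, cv_d),
            stats=_build(StatsConfig, data.get("stats")),
            mcid=_build(McidThresholds, data.get("mcid")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return {
            "seed": self.seed,
            "dataset_dir": self.dataset_dir,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "cohort": clean(self.cohort),
            "protocol": clean(self.protocol),
            "preprocess": clean(self.preprocess),
            "features": clean(self.features),
            "classifiers": list(self.classifiers),
            "classifier": clean(self.classifier),
            "cv": clean(self.cv),
            "stats": clean(self.stats),
            "mcid": clean(self.mcid),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _meta_path(out: Path, stage: str) -> Path:
    return out / f"{stage}.meta.json"


def _write_meta(out: Path, stage: str, cfg_hash: str, **extra: Any) -> None:
    with open(_meta_path(out, stage), "w") as fh:
        json.dump({"stage": stage, "config_hash": cfg_hash, **extra}, fh,
                  indent=1, sort_keys=True)


def _check_meta(out: Path, stage: str, cfg_hash: str) -> bool:
    """True if the stage already ran under this exact configuration."""
    path = _meta_path(out, stage)
    if not path.exists():
        return False
    with open(path) as fh:
        meta = json.load(fh)
    if meta.get("config_hash") != cfg_hash:
        raise ConfigurationError(
            f"stage {stage!r} artifacts were produced under config hash "
            f"{meta.get('config_hash')} but the current config hashes to "
            f"{cfg_hash}; refusing to mix runs")
    return True


def stage_simulate(config: RunConfig, force: bool = False) -> dict:
    out = Path(config.dataset_dir)
    h = config.config_hash()
    if not force and _check_meta(out, "simulate", h) and (out / "manifest.json").exists():
        log.info("simulate: reusing existing dataset under %s", out)
        return eio.read_manifest(out / "manifest.json", verify=False)
    t0 = time.perf_counter()
    cohort = make_cohort(config.cohort, config.protocol)
    manifest = generate_dataset(cohort, config.protocol, out)
    _write_meta(out, "simulate", h, n_recordings=manifest["n_recordings"],
                wall_s=round(time.perf_counter() - t0, 3))
    log.info("simulate: %d recordings in %.1fs", manifest["n_recordings"],
             time.perf_counter() - t0)
    return manifest


def _iter_recordings(config: RunConfig):
    data_dir = Path(config.dataset_dir)
    manifest = eio.read_manifest(data_dir / "manifest.json", verify=False)
    for entry in manifest["files"]:
        if entry["role"] != "emg":
            continue
        csv_path = data_dir / entry["path"]
        sidecar = csv_path.with_suffix(".json")
        yield eio.read_emg(csv_path, sidecar)


def stage_preprocess(config: RunConfig) -> dict:
    """Validation pass: filter every recording and reconcile record counts.

    Windows are an in-memory product; the persisted artifact of this stage is
    the count reconciliation in its metadata (no silent record drops).
    """
    h = config.config_hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    n_rec = n_epochs = n_windows = 0
    for rec in _iter_recordings(config):
        clean = preprocess(rec, config.preprocess)
        epochs = extract_epochs(clean, config.protocol, config.preprocess.guard_ms)
        n_rec += 1
        n_epochs += len(epochs)
        n_windows += sum(
            make_windows(e, config.preprocess, rec.fs).n_windows for e in epochs)
    counts = {"recordings": n_rec, "epochs": n_epochs, "windows": n_windows}
    _write_meta(out, "preprocess", h, counts=counts,
                wall_s=round(time.perf_counter() - t0, 3))
    return counts


def stage_features(config: RunConfig, force: bool = False) -> pd.DataFrame:
    h = config.config_hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "features.csv"
    if not force and _check_meta(out, "features", h) and path.exists():
        log.info("features: reusing %s", path)
        return pd.read_csv(path)
    t0 = time.perf_counter()
    window_sets = []
    for rec in _iter_recordings(config):
        clean = preprocess(rec, config.preprocess)
        for epoch in extract_epochs(clean, config.protocol, config.preprocess.guard_ms):
            window_sets.append(make_windows(epoch, config.preprocess, rec.fs))
    table = build_feature_table(window_sets, config.protocol.fs_hz, config.features)
    table.to_csv(path, index=False)
    _write_meta(out, "features", h, n_rows=len(table),
                wall_s=round(time.perf_counter() - t0, 3))
    log.info("features: %d windows in %.1fs", len(table), time.perf_counter() - t0)
    return table


def stage_classify(config: RunConfig, force: bool = False) -> dict:
    h = config.config_hash()
    out = Path(config.out_dir)
    acc_path = out / "accuracy.csv"
    prog_path = out / "progression.csv"
    reports_path = out / "classifier_reports.json"
    if not force and _check_meta(out, "classify", h) and acc_path.exists():
        return {"accuracy": pd.read_csv(acc_path),
                "progression": pd.read_csv(prog_path),
                "summary": pd.read_csv(out / "summary.csv")}
    t0 = time.perf_counter()
    table = stage_features(config)
    reports = []
    rows = []
    for (pid, week), sub in table.groupby(["patient_id", "week"]):
        group = sub["group"].iloc[0]
        for kind in config.classifiers:
            spec = dataclasses.replace(config.classifier, kind=kind)
            rep = crossval_accuracy(sub, spec, config.cv)
            reports.append(rep)
            rows.append({"patient_id": pid, "group": group, "week": week,
                         "classifier": kind, "accuracy": rep.accuracy})
    acc = pd.DataFrame(rows)
    acc.to_csv(acc_path, index=False)
    with open(reports_path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1)
    weeks = sorted(acc["week"].unique())
    prog = progression_table(acc, weeks, list(config.cohort.groups)) if len(
        weeks) >= 2 else pd.DataFrame()
    prog.to_csv(prog_path, index=False)
    summary = classifier_mean_summary(acc)
    summary.to_csv(out / "summary.csv", index=False)
    _write_meta(out, "classify", h, n_reports=len(reports),
                wall_s=round(time.perf_counter() - t0, 3))
    log.info("classify: %d reports in %.1fs", len(reports), time.perf_counter() - t0)
    return {"accuracy": acc, "progression": prog, "summary": summary}


def stage_correlate(config: RunConfig, force: bool = False) -> pd.DataFrame:
    h = config.config_hash()
    out = Path(config.out_dir)
    path = out / "correlations.csv"
    if not force and _check_meta(out, "correlate", h) and path.exists():
        return pd.read_csv(path)
    t0 = time.perf_counter()
    table = stage_features(config)
    clinical = eio.read_clinical(Path(config.dataset_dir) / "clinical_scores.csv")
    weeks = sorted(table["week"].unique())
    summaries = {w: summarize_patient_features(table, w) for w in weeks}
    corr = correlation_table(summaries, clinical, weeks, config.stats)
    corr.to_csv(path, index=False)
    _write_meta(out, "correlate", h, n_rows=len(corr),
                wall_s=round(time.perf_counter() - t0, 3))
    return corr


def stage_clinical(config: RunConfig, force: bool = False) -> pd.DataFrame:
    h = config.config_hash()
    out = Path(config.out_dir)
    path = out / "outcomes.csv"
    if not force and _check_meta(out, "clinical", h) and path.exists():
        return pd.read_csv(path)
    clinical = eio.read_clinical(Path(config.dataset_dir) / "clinical_scores.csv")
    summary = outcome_summary(clinical, config.mcid, config.stats,
                              groups=config.cohort.groups)
    summary.to_csv(path, index=False)
    _write_meta(out, "clinical", config.config_hash(), n_rows=len(summary))
    return summary


def stage_report(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    classify = stage_classify(config)
    corr = stage_correlate(config)
    outcomes = stage_clinical(config)
    bundle = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "summary": classify["summary"].to_dict(orient="records"),
        "progression": classify["progression"].to_dict(orient="records"),
        "correlations": corr.to_dict(orient="records"),
        "outcomes": outcomes.to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True)
    return bundle


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the final report bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log.info("run config hash %s", config.config_hash())
    stage_simulate(config)
    stage_preprocess(config)
    stage_features(config)
    return stage_report(config)
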