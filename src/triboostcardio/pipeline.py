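"""End-to-end orchestration: simulate -> preprocess -> select -> train -> evaluate.

Every stage reads and writes plain CSV/JSON artifacts in an output
directory; a run manifest records the resolved configuration, per-stage
row/feature counts, wall-clock, and a SHA-256 content hash of each
artifact (the integration surface where a downstream ledger could anchor
results).  All randomness flows from the seeds recorded in the config, so
any artifact can be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ensemble import TriBoostConfig, TriBoostModel, train_triboost
from .metrics import compute_metrics, confusion
from .preprocessing import preprocess_table
from .scso import SwarmConfig
from .selection import FitnessConfig, select_features
from .synthetic import CohortSpec, generate_cohort, read_cohort_csv, write_cohort_csv

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("triboostcardio")

TARGET_COLUMN = "target"


@dataclass
class RunConfig:
    """Flat per-stage parameter sections; round-trips losslessly via YAML."""

    seed: int = 0
    out_dir: str = "runs/default"
    input_csv: str | None = None          # None -> simulate a cohort
    # simulate
    n_samples: int = 2000
    n_informative: int = 4
    n_noise: int = 16
    effect_size: float = 2.0
    class_balance: float = 0.5
    # preprocess
    impute_strategy: str = "mean"
    kalman_q: float = 0.01
    kalman_r: float = 1.0
    # select
    skip_select: bool = False
    lam: float = 0.99
    pop_size: int = 20
    max_iter: int = 30
    # train
    cat_trees: int = 500
    ada_estimators: int = 200
    logit_stages: int = 100
    cv_folds: int = 5
    force: bool = False

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    package_version: str = __version__
    stages: dict = field(default_factory=dict)
    artifact_hashes: dict = field(default_factory=dict)

    def record(self, stage: str, path: Path | None, seconds: float,
               n_rows: int | None = None, n_features: int | None = None,
               extra: dict | None = None) -> None:
        entry: dict = {"wall_clock_s": round(seconds, 4)}
        if n_rows is not None:
            entry["n_rows"] = int(n_rows)
        if n_features is not None:
            entry["n_features"] = int(n_features)
        if extra:
            entry.update(extra)
        self.stages[stage] = entry
        if path is not None and path.exists():
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            self.artifact_hashes[path.name] = digest
        log.info("stage=%s %s", stage, entry)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "package_version": self.package_version,
             "stages": self.stages, "artifact_hashes": self.artifact_hashes},
            indent=2))


def _n_feature_cols(df) -> int:
    return sum(1 for c in df.columns if c != TARGET_COLUMN)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order, writing artifacts under ``out_dir``.

    Stages whose output files already exist are skipped unless
    ``config.force`` is set.  Raises ``ValueError`` on schema mismatches
    between consecutive stages (reported with the offending columns).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))

    # ---- simulate / load --------------------------------------------------
    cohort_path = out / "cohort.csv"
    t0 = time.perf_counter()
    if config.input_csv is not None:
        cohort = read_cohort_csv(config.input_csv)
        if TARGET_COLUMN not in cohort.columns:
            raise ValueError(
                f"input lacks {TARGET_COLUMN!r}; columns = {list(cohort.columns)}")
        cohort_path = Path(config.input_csv)
    elif cohort_path.exists() and not config.force:
        cohort = read_cohort_csv(cohort_path)
        log.info("stage=simulate reused existing %s", cohort_path)
    else:
        spec = CohortSpec(
            n_samples=config.n_samples, n_informative=config.n_informative,
            n_noise=config.n_noise,
            effect_sizes=tuple([config.effect_size] * config.n_informative),
            class_balance=config.class_balance, seed=config.seed,
        )
        cohort = generate_cohort(spec)
        write_cohort_csv(cohort, cohort_path)
    manifest.record("simulate", cohort_path, time.perf_counter() - t0,
                    n_rows=len(cohort), n_features=_n_feature_cols(cohort))

    # ---- preprocess -------------------------------------------------------
    pre_path = out / "preprocessed.csv"
    t0 = time.perf_counter()
    if pre_path.exists() and not config.force:
        pre = read_cohort_csv(pre_path)
    else:
        pre = preprocess_table(cohort, strategy=config.impute_strategy)
        write_cohort_csv(pre, pre_path)
    manifest.record("preprocess", pre_path, time.perf_counter() - t0,
                    n_rows=len(pre), n_features=_n_feature_cols(pre),
                    extra={"duplicates_dropped": len(cohort) - len(pre)})

    feature_cols = [c for c in pre.columns if c != TARGET_COLUMN]

    # ---- select -----------------------------------------------------------
    mask_path = out / "mask.json"
    t0 = time.perf_counter()
    if config.skip_select:
        mask = np.ones(len(feature_cols), dtype=int)
        mask_path.write_text(json.dumps(
            {"mask": mask.tolist(), "fitness": None, "trace": [],
             "selected": feature_cols}))
        manifest.record("select", mask_path, time.perf_counter() - t0,
                        n_features=len(feature_cols),
                        extra={"skipped": True, "n_selected": len(feature_cols)})
    elif mask_path.exists() and not config.force:
        mask = np.asarray(json.loads(mask_path.read_text())["mask"], dtype=int)
        manifest.record("select", mask_path, time.perf_counter() - t0,
                        extra={"reused": True, "n_selected": int(mask.sum())})
    else:
        sel = select_features(
            pre,
            fc=FitnessConfig(lam=config.lam, fold_seed=config.seed),
            config=SwarmConfig(pop_size=config.pop_size, max_iter=config.max_iter,
                               seed=config.seed),
        )
        mask = sel.mask
        mask_path.write_text(sel.to_json())
        manifest.record("select", mask_path, time.perf_counter() - t0,
                        n_features=len(feature_cols),
                        extra={"n_selected": int(mask.sum()),
                               "fitness": sel.fitness})

    selected_cols = [c for c, b in zip(feature_cols, mask) if b]
    missing = set(selected_cols) - set(pre.columns)
    if missing:
        raise ValueError(f"schema mismatch after selection; missing columns {sorted(missing)}")

    # ---- train ------------------------------------------------------------
    model_path = out / "model.json"
    report_path = out / "report.json"
    t0 = time.perf_counter()
    tb_config = TriBoostConfig(cat_trees=config.cat_trees,
                               ada_estimators=config.ada_estimators,
                               logit_stages=config.logit_stages,
                               cv_folds=config.cv_folds, seed=config.seed)
    data = pre[selected_cols + [TARGET_COLUMN]]
    result = train_triboost(data, config=tb_config)
    model_path.write_text(result.model.to_json())
    manifest.record("train", model_path, time.perf_counter() - t0,
                    n_rows=len(result.train_index), n_features=len(selected_cols))

    # ---- evaluate ---------------------------------------------------------
    t0 = time.perf_counter()
    report = {
        "test_metrics": result.test_metrics.as_dict(),
        "member_test_metrics": {k: v.as_dict()
                                for k, v in result.member_test_metrics.items()},
        "cv_metrics": result.cv_metrics.as_dict() if result.cv_metrics else None,
        "selected_features": selected_cols,
        "n_test": len(result.test_index),
    }
    report_path.write_text(json.dumps(report, indent=2))
    manifest.record("evaluate", report_path, time.perf_counter() - t0,
                    n_rows=len(result.test_index),
                    extra={"test_accuracy": result.test_metrics.acc})

    manifest.write(out / "manifest.json")
    return manifest


def evaluate_model(model_json_path, table, y=None) -> dict:
    """Re-evaluate a serialized ensemble on a labelled table."""
    model = TriBoostModel.from_json(Path(model_json_path).read_text())
    from .ensemble import _as_xy
    X, yv = _as_xy(table, y)
    pred = model.predict(X)
    return compute_metrics(confusion(yv, pred)).as_dict()
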