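"""End-to-end pipeline: scan -> split -> extract -> select -> evaluate.

One YAML run configuration drives all stages; every stage persists its
artifact (manifest, feature table, selection result, reduced table,
report) so stages are independently inspectable and resumable. A single
global seed deterministically derives one sub-seed per stage.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .aco import ACOConfig, run_aco
from .bench import PRESET_NAMES, crossval_evaluate, holdout_evaluate, write_report
from .dataset_io import SplitSpec, save_manifest, scan_dataset, split_manifest
from .features import (
    BackboneSpec,
    FeatureTable,
    TrainConfig,
    build_modified_backbone,
    extract_features,
    finetune,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "load_run_config"]

_STAGES = ("split", "train", "extract", "select", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed: first state word of SeedSequence([seed, i]) mod 2^31."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _from_mapping(cls, mapping: dict, section: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{section}' section: {sorted(unknown)}")
    return cls(**mapping)


@dataclass
class RunConfig:
    output_dir: Path
    dataset_root: Path | None = None
    feature_table: Path | None = None  # skip extraction, start from a table
    backbone: BackboneSpec = field(default_factory=lambda: BackboneSpec("resnet50"))
    train: TrainConfig = field(default_factory=TrainConfig)
    aco: ACOConfig = field(default_factory=ACOConfig)
    folds: int = 10
    presets: tuple = PRESET_NAMES
    eval_mode: str = "cv10"  # cv10 | holdout
    test_fraction: float = 0.20
    seed: int = 0
    skip_train: bool = False
    resume: bool = False

    def __post_init__(self):
        if self.dataset_root is None and self.feature_table is None:
            raise ValueError("either dataset_root or feature_table must be set")
        if self.eval_mode not in ("cv10", "holdout"):
            raise ValueError("eval_mode must be 'cv10' or 'holdout'")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse the YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {"dataset", "backbone", "train", "aco", "bench", "output_dir", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config sections: {sorted(unknown)}")
    ds = dict(raw.get("dataset", {}))
    bb = dict(raw.get("backbone", {}))
    bb.setdefault("name", "resnet50")
    if "input_size" in bb:
        bb["input_size"] = tuple(bb["input_size"])
    train = dict(raw.get("train", {}))
    skip_train = bool(train.pop("skip", False))
    bench = dict(raw.get("bench", {}))
    seed = int(raw.get("seed", 0))
    return RunConfig(
        output_dir=Path(raw.get("output_dir", "octaco_run")),
        dataset_root=Path(ds["root"]) if "root" in ds else None,
        feature_table=Path(ds["feature_table"]) if "feature_table" in ds else None,
        backbone=_from_mapping(BackboneSpec, bb, "backbone"),
        train=_from_mapping(
            TrainConfig, {"seed": stage_seed(seed, "train"), **train}, "train"
        ),
        aco=_from_mapping(
            ACOConfig, {"seed": stage_seed(seed, "select"), **raw.get("aco", {})},
            "aco",
        ),
        folds=int(bench.get("folds", 10)),
        presets=tuple(bench.get("presets", PRESET_NAMES)),
        eval_mode=bench.get("mode", "cv10"),
        test_fraction=float(ds.get("test_fraction", 0.20)),
        seed=seed,
        skip_train=skip_train,
    )


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages in order; returns the output directory.

    Artifacts: ``manifest.csv``, ``features.csv`` (+ metadata sidecar),
    ``selection.json``, ``features_selected.csv``, ``report/`` and
    ``run_metadata.json``. With ``resume=True`` a stage whose artifact
    already exists is loaded instead of recomputed.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "stages": [],
    }

    features_path = out / "features.csv"
    test_mask = None
    if cfg.feature_table is not None and (not cfg.resume or not features_path.exists()):
        table = FeatureTable.load(cfg.feature_table)
        table.save(features_path)
        meta["stages"].append("load_features")
    elif cfg.resume and features_path.exists():
        table = FeatureTable.load(features_path)
        meta["stages"].append("resume_features")
    else:
        manifest = scan_dataset(cfg.dataset_root)
        manifest = split_manifest(
            manifest,
            SplitSpec(cfg.test_fraction, seed=stage_seed(cfg.seed, "split")),
        )
        save_manifest(manifest, out / "manifest.csv")
        model = build_modified_backbone(cfg.backbone)
        if not cfg.skip_train:
            model, history = finetune(model, manifest, cfg.train)
            (out / "loss_history.json").write_text(json.dumps(history))
        table = extract_features(model, manifest)
        table.save(features_path)
        test_mask = np.array([r.split == "test" for r in manifest.records])
        meta["stages"].append("extract")

    selection_path = out / "selection.json"
    from .aco import SelectionResult  # local import to keep module deps one-way

    if cfg.resume and selection_path.exists():
        result = SelectionResult.load(selection_path)
        meta["stages"].append("resume_select")
    else:
        result = run_aco(table, cfg.aco)
        result.save(selection_path)
        meta["stages"].append("select")
    reduced = table.select(result.kept_indices)
    reduced.save(out / "features_selected.csv")

    presets = cfg.presets
    seed_eval = stage_seed(cfg.seed, "evaluate")
    if cfg.eval_mode == "holdout":
        if test_mask is None:
            raise ValueError("holdout mode requires an image dataset with a split")
        report = holdout_evaluate(reduced, presets, test_mask, seed=seed_eval)
    else:
        report = crossval_evaluate(reduced, presets, folds=cfg.folds, seed=seed_eval)
    write_report(report, out / "report")
    meta["stages"].append("evaluate")
    meta["eval_mode"] = cfg.eval_mode
    meta["partition_hash"] = report.partition_hash
    (out / "run_metadata.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True), encoding="utf-8"
    )
    return out
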