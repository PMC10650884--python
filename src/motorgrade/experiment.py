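"""End-to-end experiment orchestration.

Stages: simulate -> preprocess -> split -> pretrain -> train ->
evaluate -> cka. Each stage reads the previous stage's artifacts from
the output directory, writes its own deterministically (a fixed
per-stage seed offset fans out from the global seed), and records a
manifest with the config hash. Stages are idempotent: re-running with
an unchanged config reproduces the same artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort, read_cohort, write_cohort
from .cka import compare_attribute_groups
from .evaluate import (
    NoiseSpec,
    aggregate_by_attribute,
    evaluate_model,
    fold_summary,
)
from .masking import MaskSpec
from .network import ModelConfig, load_checkpoint, save_checkpoint
from .preprocess import PreprocessConfig, SegmentSet, preprocess_cohort
from .pretrain import (
    W_PD,
    W_PD_HOA,
    PretrainConfig,
    PretrainedWeights,
    pretrain,
)
from .split import SplitConfig, group_table, load_split_manifests, make_splits, save_split_manifests
from .supervised import enumerate_variants, train_variant

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "split", "pretrain", "train", "evaluate", "cka")

_STAGE_SEED_OFFSET = {s: 1000 * (i + 1) for i, s in enumerate(STAGES)}


class DependencyError(RuntimeError):
    """An upstream stage's artifacts are missing."""


@dataclass
class TrainParams:
    epochs_all: int = 50
    epochs_head: int = 10
    max_learning_rate: float = 1e-3
    batch_size: int = 64


@dataclass
class ExperimentConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    mask: MaskSpec = field(default_factory=MaskSpec)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    train: TrainParams = field(default_factory=TrainParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    task: str = "aggregate"  # FT|HM|PS|TT|LA or "aggregate" (no task filter)
    out_dir: str = "motorgrade_run"
    seed: int = 0
    epochs_scale: float = 1.0

    def scaled(self, n: int) -> int:
        return max(1, int(round(n * self.epochs_scale)))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        for name, sub in (
            ("cohort", CohortSpec),
            ("preprocess", PreprocessConfig),
            ("split", SplitConfig),
            ("model", ModelConfig),
            ("mask", MaskSpec),
            ("pretrain", PretrainConfig),
            ("train", TrainParams),
            ("noise", NoiseSpec),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                sub_kwargs = dict(kwargs[name])
                for key in ("tasks", "severity_distribution"):
                    if key in sub_kwargs and isinstance(sub_kwargs[key], list):
                        sub_kwargs[key] = tuple(sub_kwargs[key])
                kwargs[name] = sub(**sub_kwargs)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw or {})


def _paths(config: ExperimentConfig) -> dict:
    out = Path(config.out_dir)
    return {
        "out": out,
        "recordings": out / "recordings",
        "manifest": out / "recordings" / "manifest.csv",
        "segments_npz": out / "segments.npz",
        "segments_csv": out / "segments_index.csv",
        "splits": out / "splits",
        "weights": out / "weights",
        "models": out / "models",
        "reports": out / "reports",
    }


def _require(path: Path, producer: str) -> None:
    if not path.exists():
        raise DependencyError(
            f"missing artifact {path}; run stage '{producer}' first"
        )


def _stage_seed(config: ExperimentConfig, stage: str) -> int:
    return int(config.seed + _STAGE_SEED_OFFSET[stage]) % (2**31)


def _write_manifest(config: ExperimentConfig, stage: str, artifacts: list) -> None:
    p = _paths(config)
    p["out"].mkdir(parents=True, exist_ok=True)
    manifest_path = p["out"] / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest[stage] = {
        "config_hash": config.config_hash(),
        "seed": _stage_seed(config, stage),
        "artifacts": [str(a) for a in artifacts],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))


def _load_segments(config: ExperimentConfig) -> SegmentSet:
    p = _paths(config)
    _require(p["segments_npz"], "preprocess")
    segments = SegmentSet.load(p["segments_npz"], p["segments_csv"])
    if config.task != "aggregate":
        mask = (segments.index["task"] == config.task).to_numpy()
        segments = SegmentSet(
            segments.X[mask], segments.index[mask].reset_index(drop=True)
        )
    return segments


def run_simulate(config: ExperimentConfig) -> Path:
    p = _paths(config)
    spec = dataclasses.replace(config.cohort, seed=_stage_seed(config, "simulate"))
    recordings, manifest = generate_cohort(spec)
    path = write_cohort(recordings, manifest, p["recordings"])
    _write_manifest(config, "simulate", [path])
    logger.info("simulate: %d recordings", len(recordings))
    return path


def run_preprocess(config: ExperimentConfig) -> SegmentSet:
    p = _paths(config)
    _require(p["manifest"], "simulate")
    recordings, _ = read_cohort(p["manifest"])
    segments = preprocess_cohort(recordings, config.preprocess)
    segments.save(p["segments_npz"], p["segments_csv"])
    _write_manifest(config, "preprocess", [p["segments_npz"], p["segments_csv"]])
    logger.info("preprocess: %d segments", len(segments))
    return segments


def run_split(config: ExperimentConfig):
    p = _paths(config)
    segments = _load_segments(config)
    split_cfg = dataclasses.replace(config.split, seed=_stage_seed(config, "split"))
    splits = make_splits(segments, split_cfg)
    save_split_manifests(splits, group_table(segments), p["splits"])
    _write_manifest(
        config, "split", sorted(p["splits"].glob("fold_*.csv"))
    )
    return splits


def run_pretrain(config: ExperimentConfig) -> dict:
    p = _paths(config)
    segments = _load_segments(config)
    _require(p["splits"], "split")
    splits = load_split_manifests(p["splits"])
    p["weights"].mkdir(parents=True, exist_ok=True)
    base_seed = _stage_seed(config, "pretrain")
    report = {}
    weights = {}
    for split in splits:
        i = split.fold_index
        sets = {
            W_PD: (split.trn_pd, split.val_pd),
            W_PD_HOA: (
                split.trn_pd | split.trn_hoa,
                split.val_pd | split.val_hoa,
            ),
        }
        for tag, (trn_groups, val_groups) in sets.items():
            trn = segments.subset_by_groups(trn_groups)
            val = segments.subset_by_groups(val_groups)
            cfg = dataclasses.replace(
                config.pretrain,
                epochs=config.scaled(config.pretrain.epochs),
                seed=(base_seed + i) % (2**31),
            )
            w = pretrain(
                trn.X,
                model_config=config.model,
                mask_spec=config.mask,
                config=cfg,
                validation_segments=val.X if len(val) else None,
                tag=tag,
                fold=i,
            )
            path = p["weights"] / f"{tag}_fold{i}.npz"
            w.save(path)
            weights[(tag, i)] = w
            report[f"{tag}_fold{i}"] = {"n_train": len(trn), "n_val": len(val)}
    (p["weights"] / "pretrain_report.json").write_text(json.dumps(report, indent=2))
    _write_manifest(config, "pretrain", sorted(p["weights"].glob("*.npz")))
    return weights


def _load_pretrained(config: ExperimentConfig) -> dict:
    p = _paths(config)
    weights = {}
    for path in p["weights"].glob("W_*fold*.npz"):
        w = PretrainedWeights.load(path)
        weights[(w.tag, w.fold)] = w
    return weights


def run_train(config: ExperimentConfig) -> dict:
    p = _paths(config)
    segments = _load_segments(config)
    _require(p["splits"], "split")
    splits = load_split_manifests(p["splits"])
    pretrained = _load_pretrained(config)
    needs_pretrained = True  # the grid always includes transfer variants
    if needs_pretrained and not pretrained:
        raise DependencyError(
            "variants require pre-trained weights W_PD/W_PD_HOA; "
            "run stage 'pretrain' first"
        )
    p["models"].mkdir(parents=True, exist_ok=True)
    base_seed = _stage_seed(config, "train")
    models = {}
    for split in splits:
        for k, spec in enumerate(enumerate_variants(split.fold_index)):
            clf = train_variant(
                spec,
                split,
                segments,
                pretrained,
                model_config=config.model,
                epochs=config.scaled(config.train.epochs_all),
                head_epochs=config.scaled(config.train.epochs_head),
                max_learning_rate=config.train.max_learning_rate,
                batch_size=config.train.batch_size,
                seed=(base_seed + 31 * split.fold_index + k) % (2**31),
            )
            tags = {
                "train_set": spec.train_set,
                "init": spec.init,
                "scheme": spec.scheme,
                "fold": spec.fold,
                "task": config.task,
            }
            save_checkpoint(p["models"] / f"{spec.name}.npz", clf.model_, tags)
            pd.DataFrame(clf.history_).to_csv(
                p["models"] / f"{spec.name}_log.csv", index=False
            )
            models[spec.name] = (clf, tags)
            logger.info("trained %s", spec.name)
    _write_manifest(config, "train", sorted(p["models"].glob("*.npz")))
    return models


class NetworkPredictor:
    """predict_proba facade over a bare checkpointed network."""

    def __init__(self, network):
        self.model_ = network

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64).transpose(0, 2, 1)
        out = []
        for start in range(0, X.shape[0], 256):
            logits = self.model_(X[start : start + 256], training=False)
            out.append(1.0 / (1.0 + np.exp(-logits.data)))
        p = np.concatenate(out) if out else np.empty(0)
        return np.column_stack([1 - p, p])


def _load_models(config: ExperimentConfig) -> list[dict]:
    p = _paths(config)
    _require(p["models"], "train")
    entries = []
    for path in sorted(p["models"].glob("*.npz")):
        network, tags = load_checkpoint(path)
        entries.append({**tags, "model": NetworkPredictor(network)})
    if not entries:
        raise DependencyError("no trained models found; run stage 'train' first")
    return entries


def run_evaluate(config: ExperimentConfig) -> pd.DataFrame:
    p = _paths(config)
    segments = _load_segments(config)
    splits = {s.fold_index: s for s in load_split_manifests(p["splits"])}
    entries = _load_models(config)
    noise = dataclasses.replace(
        config.noise, seed=_stage_seed(config, "evaluate")
    )
    rows = []
    for entry in entries:
        split = splits[entry["fold"]]
        tst = segments.subset_by_groups(split.tst_pd)
        metrics = evaluate_model(entry["model"], tst, noise)
        rows.append(
            {k: entry[k] for k in ("train_set", "init", "scheme", "fold", "task")}
            | metrics
        )
    report = pd.DataFrame(rows)
    p["reports"].mkdir(parents=True, exist_ok=True)
    report.to_csv(p["reports"] / "evaluation.csv", index=False)
    fold_summary(report).to_csv(p["reports"] / "variant_summary.csv", index=False)
    for axis in ("train_set", "init"):
        aggregate_by_attribute(report, axis).to_csv(
            p["reports"] / f"attribute_{axis}.csv", index=False
        )
    (p["reports"] / "evaluation.json").write_text(
        report.to_json(orient="records", indent=2)
    )
    _write_manifest(config, "evaluate", [p["reports"] / "evaluation.csv"])
    return report


def run_cka(config: ExperimentConfig) -> pd.DataFrame:
    p = _paths(config)
    segments = _load_segments(config)
    splits = {s.fold_index: s for s in load_split_manifests(p["splits"])}
    entries = _load_models(config)
    probe_segments = {
        i: segments.subset_by_groups(s.tst_pd).X for i, s in splits.items()
    }
    frames = []
    for probe in ("first", "last"):
        for axis in ("train_set", "init"):
            df = compare_attribute_groups(entries, axis, probe, probe_segments)
            df["axis"] = axis
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    p["reports"].mkdir(parents=True, exist_ok=True)
    table.to_csv(p["reports"] / "cka.csv", index=False)
    _write_manifest(config, "cka", [p["reports"] / "cka.csv"])
    return table


_RUNNERS = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "split": run_split,
    "pretrain": run_pretrain,
    "train": run_train,
    "evaluate": run_evaluate,
    "cka": run_cka,
}


def run_stage(stage: str, config: ExperimentConfig):
    """Run one stage, or 'all' for the full pipeline."""
    if stage == "all":
        result = None
        for s in STAGES:
            result = _RUNNERS[s](config)
        return result
    if stage not in _RUNNERS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    return _RUNNERS[stage](config)
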