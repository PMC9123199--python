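"""End-to-end experiment runs: simulate, split, train, select, evaluate.

An experiment reproduces one of the three training regimes — GE-only,
SE-only, or mixed — on synthetic phantoms: generate the cohort, train the
adversarial pair, evaluate every per-epoch checkpoint on the held-out
split, select the best model by mean MSSIM, predict on the test split and
write the similarity/Dice report.  All artifacts (volumes, checkpoints,
logs, reports, resolved config) land in the output directory, and a
manifest records the file inventory; every stage derives its seed from the
master seed by stage-name hashing, so inserting a stage never shifts the
seeds of the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as _metrics
from .model import DiscriminatorConfig, GeneratorConfig
from .phantom import GE, SE, Dataset, make_dataset, save_dataset
from .train import (
    CheckpointStore,
    TrainConfig,
    evaluate_checkpoints,
    predict,
    train,
)
from .volume import Volume, normalize_minmax, rescale_display, write_volume

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "run_experiment",
    "cross_modality_eval",
    "derive_seed",
]

EXPERIMENTS = ("GE_only", "SE_only", "mixed")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived by hashing the stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, with toy-scale defaults."""

    experiment: str = "GE_only"
    n_ge: int = 10
    n_se: int = 0
    test_fraction: float = 0.2
    grid_shape: tuple = (16, 16, 16)
    voxel_size: tuple = (0.3, 0.3, 0.5)
    noise_sigma: float = 0.05
    train_cfg: TrainConfig = None
    gen_cfg: GeneratorConfig = None
    disc_cfg: DiscriminatorConfig = None
    mssim_cfg: _metrics.MSSIMConfig = None
    out_dir: str = "run"
    master_seed: int = 0

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        if self.experiment == "GE_only" and self.n_se != 0:
            raise ValueError("GE_only experiments must have n_se = 0")
        if self.experiment == "SE_only" and self.n_ge != 0:
            raise ValueError("SE_only experiments must have n_ge = 0")
        if self.experiment == "mixed" and (self.n_ge == 0 or self.n_se == 0):
            raise ValueError("mixed experiments need both modalities")
        if self.train_cfg is None:
            self.train_cfg = TrainConfig(epochs=10)
        if self.gen_cfg is None:
            self.gen_cfg = GeneratorConfig(depth=3, base_filters=32,
                                           dropout_layers=1)
        if self.disc_cfg is None:
            self.disc_cfg = DiscriminatorConfig(levels=3, base_filters=32)
        if self.mssim_cfg is None:
            self.mssim_cfg = _metrics.MSSIMConfig()

    def resolved(self) -> dict:
        out = asdict(self)
        return out

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("train_cfg", TrainConfig),
                         ("gen_cfg", GeneratorConfig),
                         ("disc_cfg", DiscriminatorConfig),
                         ("mssim_cfg", _metrics.MSSIMConfig)):
            if key in raw and isinstance(raw[key], dict):
                if "window_shape" in raw[key]:
                    raw[key]["window_shape"] = tuple(raw[key]["window_shape"])
                raw[key] = sub(**raw[key])
        for key in ("grid_shape", "voxel_size"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunManifest:
    """Inventory of one experiment run."""

    experiment: str
    master_seed: int
    config_hash: str
    stage_seeds: dict = field(default_factory=dict)
    files: list = field(default_factory=list)
    selected_checkpoint: str = ""
    failed_stage: str = ""
    error: str = ""

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(cfg.resolved(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(cfg: ExperimentConfig) -> RunManifest:
    """Run simulate -> split -> train -> select -> predict -> report.

    Partial artifacts are kept on failure; the manifest then names the
    failing stage.  Deterministic under a fixed master seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(experiment=cfg.experiment,
                           master_seed=cfg.master_seed,
                           config_hash=_config_hash(cfg))
    mpath = out / "manifest.json"

    def record(relpath):
        manifest.files.append(str(relpath))

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.resolved(), fh, default_flow_style=None)
    record("config.yaml")

    stage = "simulate"
    try:
        seed = derive_seed(cfg.master_seed, stage)
        manifest.stage_seeds[stage] = seed
        dataset = make_dataset(cfg.n_ge, cfg.n_se, cfg.test_fraction, seed,
                               grid_shape=cfg.grid_shape,
                               voxel_size=cfg.voxel_size,
                               noise_sigma=cfg.noise_sigma)
        save_dataset(dataset, out / "data")
        for stem in sorted(p.name for p in (out / "data").iterdir()):
            record(f"data/{stem}")

        stage = "train"
        seed = derive_seed(cfg.master_seed, stage)
        manifest.stage_seeds[stage] = seed
        tcfg = TrainConfig(**{**asdict(cfg.train_cfg), "seed": seed})
        store, log = train(dataset, cfg.gen_cfg, cfg.disc_cfg, tcfg,
                           out / "ckpts")
        log.to_csv(out / "train_log.csv")
        record("train_log.csv")
        for e in store._entries:
            record(f"ckpts/{e['file']}")
        record("ckpts/manifest.json")

        stage = "select"
        report = evaluate_checkpoints(store, dataset.test_pairs,
                                      cfg.mssim_cfg)
        report.to_csv(out / "selection.csv")
        record("selection.csv")
        (out / "selection.json").write_text(json.dumps(
            {"chosen": report.chosen, "criterion": report.criterion},
            indent=2))
        record("selection.json")
        manifest.selected_checkpoint = report.chosen

        stage = "predict"
        best = store.load_generator(report.chosen)
        (out / "pred").mkdir(exist_ok=True)
        eval_pairs = []
        labels = []
        for i, (pair, split) in enumerate(zip(dataset.pairs, dataset.split)):
            if split != "test":
                continue
            vs = pair.spec.voxel_size if pair.spec else (1.0, 1.0, 1.0)
            pred = predict(best, Volume(pair.source, voxel_size=vs))
            write_volume(pred, out / "pred" / f"pair{i:04d}_pred.nii.gz")
            record(f"pred/pair{i:04d}_pred.nii.gz")
            tgt = rescale_display(normalize_minmax(
                Volume(pair.target, voxel_size=vs)))
            eval_pairs.append((tgt, pred))
            labels.append(f"pair{i:04d}:{pair.modality}")

        stage = "evaluate"
        mreport = _metrics.report(eval_pairs, cfg.mssim_cfg, labels=labels)
        mreport.per_pair["modality"] = [lab.split(":")[1] for lab in labels]
        mreport.to_csv(out / "report.csv", out / "report_summary.csv")
        record("report.csv")
        record("report_summary.csv")
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.error = str(exc)
        manifest.write(mpath)
        raise
    manifest.write(mpath)
    record("manifest.json")
    return manifest


def cross_modality_eval(models: dict, test_pairs) -> pd.DataFrame:
    """Evaluate each trained model on each modality subset of a mixed
    test set.

    ``models`` maps a model name (e.g. experiment label) to a trained
    generator or checkpoint path.  Returns one row per (model, modality)
    cell with mean +/- SD of CAD, L2 and MSSIM; a model that cannot
    process a subset (shape mismatch) yields a row of NaNs rather than
    aborting.
    """
    test_pairs = list(test_pairs)
    rows = []
    for name, model in models.items():
        for modality in (GE, SE):
            subset = [p for p in test_pairs if p.modality == modality]
            row = {"model": name, "modality": modality, "n": len(subset)}
            if not subset:
                rows.append(row)
                continue
            cads, l2s, ssims = [], [], []
            try:
                for pair in subset:
                    vs = pair.spec.voxel_size if pair.spec else (1, 1, 1)
                    pred = predict(model, Volume(pair.source, voxel_size=vs))
                    tgt = rescale_display(normalize_minmax(
                        Volume(pair.target, voxel_size=vs)))
                    cads.append(_metrics.cad(tgt, pred))
                    l2s.append(_metrics.l2(tgt, pred))
                    ssims.append(_metrics.mssim(tgt, pred)[0])
            except ValueError as exc:
                row["error"] = str(exc)
                rows.append(row)
                continue

            def _sd(v):
                return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

            row.update({
                "cad_mean": float(np.mean(cads)), "cad_sd": _sd(cads),
                "l2_mean": float(np.mean(l2s)), "l2_sd": _sd(l2s),
                "mssim_mean": float(np.mean(ssims)), "mssim_sd": _sd(ssims),
            })
            rows.append(row)
    return pd.DataFrame(rows)
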