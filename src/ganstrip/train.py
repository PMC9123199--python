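"""Adversarial training loop, checkpoint selection, and prediction.

Each iteration processes one training pair (batch size 1): first a
discriminator update on the real pair (label 1) and the current fake
(label 0), then one generator update on the non-saturating adversarial
term plus ``lambda`` times the L1 term.  Both networks use Adam
(beta1 = 0.5).  The three logged curves are the two discriminator terms
and the generator composite.  Weights are checkpointed at every epoch
boundary, and the best model is the checkpoint with the highest mean MSSIM
on held-out data (ties broken by the earliest epoch).

A coarse learning-rate search is provided: candidate (lr_G, lr_D) pairs
are probed for a few epochs and rejected when any loss becomes non-finite,
when the generator composite diverges (final-epoch mean above R times the
first-epoch mean), or when its late oscillation amplitude exceeds a
multiple of the first-epoch spread.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .model import (
    EPS,
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    l1_loss,
    load_checkpoint,
    save_checkpoint,
)
from .nn import Adam
from .phantom import Dataset, ImagePair
from .volume import (
    Volume,
    crop_to_original,
    fit_to_network_grid,
    normalize_minmax,
    rescale_display,
)

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "CheckpointStore",
    "SelectionReport",
    "TrainingDivergence",
    "count_iterations",
    "train",
    "predict",
    "evaluate_checkpoints",
    "select_best",
    "grid_search_lr",
]


class TrainingDivergence(RuntimeError):
    """Raised when a loss becomes non-finite during training."""


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults are the full-scale setting:
    lr_G = 2e-4, lr_D = 1e-6, Adam, 200 epochs, batch 1, lambda = 100)."""

    lr_g: float = 2e-4
    lr_d: float = 1e-6
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 200
    batch_size: int = 1
    lam: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def count_iterations(cfg: TrainConfig, n_train: int) -> int:
    """Total generator updates: epochs x ceil(n_train / batch_size)."""
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    return cfg.epochs * math.ceil(n_train / cfg.batch_size)


@dataclass
class TrainingLog:
    """One record per generator update."""

    records: list = field(default_factory=list)

    def append(self, iteration, epoch, d_real, d_fake, g_adv, g_l1, lam):
        self.records.append(
            {"iteration": iteration, "epoch": epoch, "d_real": d_real,
             "d_fake": d_fake, "g_adv": g_adv, "g_l1": g_l1,
             "g_total": g_adv + lam * g_l1}
        )

    def __len__(self):
        return len(self.records)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)


class CheckpointStore:
    """Per-epoch weight checkpoints in a directory, with a JSON manifest.

    Checkpoint ids look like ``e032_i011744`` (epoch and cumulative
    iteration at the save point).
    """

    def __init__(self, directory):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self._entries = []
        mf = self.directory / "manifest.json"
        if mf.exists():
            self._entries = json.loads(mf.read_text())["checkpoints"]

    def save(self, epoch, iteration, generator, discriminator=None):
        cid = f"e{epoch:03d}_i{iteration:06d}"
        fname = f"ckpt_{cid}.npz"
        save_checkpoint(self.directory / fname, generator, discriminator,
                        meta={"epoch": epoch, "iteration": iteration})
        self._entries.append(
            {"id": cid, "epoch": epoch, "iteration": iteration,
             "file": fname})
        (self.directory / "manifest.json").write_text(
            json.dumps({"checkpoints": self._entries}, indent=2))
        return cid

    def ids(self):
        return [e["id"] for e in self._entries]

    def entry(self, cid):
        for e in self._entries:
            if e["id"] == cid:
                return e
        raise KeyError(f"unknown checkpoint id {cid!r}")

    def load_generator(self, cid) -> Generator:
        e = self.entry(cid)
        g, _, _ = load_checkpoint(self.directory / e["file"])
        return g

    def __len__(self):
        return len(self._entries)


def _train_pairs(data):
    if isinstance(data, Dataset):
        pairs = data.train_pairs
    else:
        pairs = list(data)
    if not pairs:
        raise ValueError("training split is empty")
    return pairs


def _prepare(pair: ImagePair, depth: int):
    """Normalize source and target independently and pad to the network grid."""
    vs = pair.spec.voxel_size if pair.spec else (1.0, 1.0, 1.0)
    out = []
    for arr in (pair.source, pair.target):
        nv = normalize_minmax(Volume(arr, voxel_size=vs))
        padded, _ = fit_to_network_grid(
            Volume(nv.data, voxel_size=vs), depth)
        out.append(padded.data)
    return out[0], out[1]


def _finite_or_raise(terms, iteration):
    vals = [terms["d_real"], terms["d_fake"], terms["g_adv"], terms["g_l1"]]
    if not all(np.isfinite(vals)):
        raise TrainingDivergence(
            f"non-finite loss at iteration {iteration}: {terms}"
        )


def train(data, gcfg: GeneratorConfig, dcfg: DiscriminatorConfig,
          cfg: TrainConfig, ckpt_dir) -> tuple[CheckpointStore, TrainingLog]:
    """Run the adversarial loop; returns the checkpoint store and the log.

    ``data`` is a :class:`~ganstrip.phantom.Dataset` (its train split is
    used) or a plain list of pairs.  Fully reproducible given
    ``cfg.seed``: weight init, the per-epoch shuffle and dropout all draw
    from seeds derived from it.
    """
    pairs = _train_pairs(data)
    ss = np.random.SeedSequence(cfg.seed)
    s_init_g, s_init_d, s_shuffle, s_drop = ss.spawn(4)
    prepared = [_prepare(p, gcfg.depth) for p in pairs]
    shape = prepared[0][0].shape
    for c, x in prepared:
        if c.shape != shape or x.shape != shape:
            raise ValueError("all training volumes must share one grid shape")

    G = Generator(gcfg, seed=int(s_init_g.generate_state(1)[0] % 2 ** 31))
    D = Discriminator(dcfg,
                      seed=int(s_init_d.generate_state(1)[0] % 2 ** 31))
    dcfg.patch_shape(shape)  # validate the stride plan up front
    G.dropout_rng = np.random.default_rng(s_drop)
    opt_g = Adam(G.layers(), cfg.lr_g, cfg.beta1, cfg.beta2)
    opt_d = Adam(D.layers(), cfg.lr_d, cfg.beta1, cfg.beta2)
    shuffle_rng = np.random.default_rng(s_shuffle)

    store = CheckpointStore(ckpt_dir)
    log = TrainingLog()
    iteration = 0
    n_vox = int(np.prod(shape))
    for epoch in range(1, cfg.epochs + 1):
        order = shuffle_rng.permutation(len(prepared))
        for idx in order:
            c, x = prepared[idx]
            iteration += 1
            x_fake = G.forward(c, train=True)

            # -- discriminator update (real label 1, fake label 0) ------
            D.zero_grad()
            p_real = D.forward(c, x, train=True)
            pr = np.clip(p_real, EPS, 1 - EPS)
            d_real = float(-np.mean(np.log(pr)))
            D.backward((-1.0 / (pr * pr.size)).astype(np.float32))
            p_fake = D.forward(c, x_fake, train=True)
            pf = np.clip(p_fake, EPS, 1 - EPS)
            d_fake = float(-np.mean(np.log(1.0 - pf)))
            D.backward((1.0 / ((1.0 - pf) * pf.size)).astype(np.float32))
            opt_d.step()

            # -- generator update --------------------------------------
            D.zero_grad()
            p_fake2 = D.forward(c, x_fake, train=True)
            pf2 = np.clip(p_fake2, EPS, 1 - EPS)
            g_adv = float(-np.mean(np.log(pf2)))
            _, g_cand = D.backward(
                (-1.0 / (pf2 * pf2.size)).astype(np.float32))
            g_l1 = l1_loss(x, x_fake)
            g_from_l1 = (cfg.lam / n_vox) * np.sign(x_fake - x)
            G.zero_grad()
            G.backward(g_cand + g_from_l1.astype(np.float32))
            opt_g.step()

            terms = {"d_real": d_real, "d_fake": d_fake,
                     "g_adv": g_adv, "g_l1": g_l1}
            _finite_or_raise(terms, iteration)
            log.append(iteration, epoch, d_real, d_fake, g_adv, g_l1,
                       cfg.lam)
        store.save(epoch, iteration, G, D)
    return store, log


def predict(model, source: Volume) -> Volume:
    """Apply a trained generator to a source volume.

    normalize -> pad to the network grid -> forward (dropout off, batch
    statistics from training) -> crop -> rescale to the [0, 1] display
    range.  ``model`` is a :class:`Generator` or a checkpoint file path.
    """
    if not isinstance(model, Generator):
        model, _, _ = load_checkpoint(model)
    nv = normalize_minmax(source)
    padded, pads = fit_to_network_grid(
        Volume(nv.data, voxel_size=source.voxel_size, affine=source.affine),
        model.cfg.depth)
    out = model.forward(padded.data, train=False)
    vol = crop_to_original(
        Volume(out, voxel_size=source.voxel_size, affine=source.affine),
        pads)
    return rescale_display(
        Volume(np.clip(vol.data, -1.0, 1.0), voxel_size=vol.voxel_size,
               affine=vol.affine))


@dataclass
class SelectionReport:
    """Per-checkpoint aggregate similarity of held-out predictions."""

    frame: pd.DataFrame
    per_volume: pd.DataFrame
    criterion: str = "highest mean MSSIM (ties: earliest epoch)"
    chosen: str = ""

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)


def _display_target(pair: ImagePair) -> Volume:
    vs = pair.spec.voxel_size if pair.spec else (1.0, 1.0, 1.0)
    return rescale_display(normalize_minmax(Volume(pair.target,
                                                   voxel_size=vs)))


def evaluate_checkpoints(store: CheckpointStore, eval_pairs,
                         mssim_cfg=None) -> SelectionReport:
    """Predict every evaluation pair under every checkpoint and aggregate
    CAD / L2 / MSSIM (computed on display-rescaled volumes)."""
    eval_pairs = list(eval_pairs)
    if not len(store) or not eval_pairs:
        raise ValueError("need at least one checkpoint and one pair")
    mssim_cfg = mssim_cfg or _metrics.MSSIMConfig()
    targets = [_display_target(p) for p in eval_pairs]
    rows, per_vol = [], []
    for entry in sorted(store._entries, key=lambda e: e["epoch"]):
        g = store.load_generator(entry["id"])
        cads, l2s, ssims = [], [], []
        for k, pair in enumerate(eval_pairs):
            vs = pair.spec.voxel_size if pair.spec else (1.0, 1.0, 1.0)
            pred = predict(g, Volume(pair.source, voxel_size=vs))
            tgt = targets[k]
            cads.append(_metrics.cad(tgt, pred))
            l2s.append(_metrics.l2(tgt, pred))
            ssims.append(_metrics.mssim(tgt, pred, mssim_cfg)[0])
            per_vol.append({"checkpoint": entry["id"],
                            "epoch": entry["epoch"], "pair": k,
                            "CAD": cads[-1], "L2": l2s[-1],
                            "MSSIM": ssims[-1]})
        def _sd(v):
            return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        rows.append({
            "checkpoint": entry["id"], "epoch": entry["epoch"],
            "iteration": entry["iteration"],
            "cad_mean": float(np.mean(cads)), "cad_sd": _sd(cads),
            "l2_mean": float(np.mean(l2s)), "l2_sd": _sd(l2s),
            "mssim_mean": float(np.mean(ssims)), "mssim_sd": _sd(ssims),
        })
    report = SelectionReport(frame=pd.DataFrame(rows),
                             per_volume=pd.DataFrame(per_vol))
    report.chosen = select_best(report)
    return report


def select_best(report: SelectionReport) -> str:
    """Checkpoint id with the highest mean MSSIM; earliest epoch on ties."""
    frame = report.frame
    if frame.empty:
        raise ValueError("selection report is empty")
    ordered = frame.sort_values(["epoch"]).reset_index(drop=True)
    best = ordered.loc[ordered["mssim_mean"].idxmax()]
    return str(best["checkpoint"])


def grid_search_lr(candidates_g, candidates_d, probe_epochs, data, seed,
                   gcfg=None, dcfg=None, ckpt_root=None,
                   divergence_ratio: float = 10.0,
                   oscillation_mult: float = 5.0):
    """Probe each (lr_G, lr_D) pair briefly and return the survivor with
    the lowest final generator composite.

    Rejection rules (recorded per candidate in the trace):
    ``nonfinite`` — any loss became non-finite; ``divergence`` — final-epoch
    mean composite exceeded ``divergence_ratio`` x the first-epoch mean;
    ``oscillation`` — final-epoch SD of the composite exceeded
    ``oscillation_mult`` x the first-epoch SD.
    """
    if not candidates_g or not candidates_d:
        raise ValueError("candidate lists must be non-empty")
    import tempfile
    trace = []
    best = None
    for lr_g, lr_d in itertools.product(candidates_g, candidates_d):
        cfg = TrainConfig(lr_g=lr_g, lr_d=lr_d, epochs=probe_epochs,
                          seed=seed)
        row = {"lr_g": lr_g, "lr_d": lr_d, "status": "ok",
               "final_composite": np.nan}
        with tempfile.TemporaryDirectory(dir=ckpt_root) as td:
            try:
                _, log = train(data, gcfg or GeneratorConfig(),
                               dcfg or DiscriminatorConfig(), cfg, td)
            except TrainingDivergence as exc:
                row["status"] = "nonfinite"
                row["detail"] = str(exc)
                trace.append(row)
                continue
        frame = log.frame
        first = frame[frame.epoch == 1]["g_total"]
        last = frame[frame.epoch == frame.epoch.max()]["g_total"]
        row["first_mean"] = float(first.mean())
        row["final_composite"] = float(last.mean())
        row["first_sd"] = float(first.std(ddof=0))
        row["final_sd"] = float(last.std(ddof=0))
        # The L1 term dominates the composite, so adversarial breakdown is
        # monitored on the adversarial term itself, against its balanced
        # equilibrium value ln 2 (D outputting 1/2 everywhere): a final
        # -log D(c, G(c)) far above ln 2 means the discriminator has
        # saturated and crushed the generator.
        adv_last = float(
            frame[frame.epoch == frame.epoch.max()]["g_adv"].mean())
        row["adv_final"] = adv_last
        if row["final_composite"] > divergence_ratio * row["first_mean"] \
                or adv_last > divergence_ratio * math.log(2.0):
            row["status"] = "divergence"
        # Oscillation is judged against the larger of the first-epoch SD
        # and 1% of the loss scale, so a near-constant first epoch (few
        # iterations) cannot make a calm run look oscillatory.
        elif row["final_sd"] > oscillation_mult * max(
                row["first_sd"], 0.01 * abs(row["first_mean"])):
            row["status"] = "oscillation"
        trace.append(row)
        if row["status"] == "ok" and (
                best is None or row["final_composite"] <
                best["final_composite"]):
            best = row
    trace_frame = pd.DataFrame(trace)
    if best is None:
        raise RuntimeError(
            "all learning-rate candidates were rejected:\n"
            + trace_frame.to_string()
        )
    return best["lr_g"], best["lr_d"], trace_frame
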