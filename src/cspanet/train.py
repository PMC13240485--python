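"""Training protocol, evaluation, and experiment runners.

Default hyperparameters reproduce the published protocol: input
1600 x 800, batch size 8, Adam with initial learning rate 1e-4 under a
cosine-annealing schedule, natural-log cross-entropy, 100 epochs. A
"desk" preset (quarter-width network, 256 x 128 input, 20 epochs,
learning rate 1e-3) makes the full pipeline run on one CPU; the higher
preset learning rate is the usual Adam default for small networks on
short schedules.

The learning rate is updated once per epoch (epoch-level scheduling).
The test split is evaluated after every epoch and the final epoch's
report is the headline result. Every run emits a RunRecord (JSON-ready
dict) carrying the resolved configs, the seed, per-epoch losses and
metrics — enough to reproduce the run from scratch.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import autograd as ag
from .autograd import Adam, Tensor
from .attention import AttentionConfig, attention_names
from .network import (CSPANet, NetworkConfig, default_network_config,
                      save_checkpoint, load_checkpoint, count_parameters)
from .metrics import (confusion_from_predictions, macro_metrics, MetricReport,
                      roc_to_csv)
from .ecg import preprocess_image
from .errors import ConfigurationError, InputError

__all__ = [
    "TrainConfig", "desk_train_config", "cosine_annealing_lr",
    "load_dataset_arrays", "run_train", "run_eval", "run_compare",
    "run_ablation", "ablation_configs", "overfit_one_batch",
]

RUN_RECORD_VERSION = "1"


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; the defaults are the published settings."""

    batch_size: int = 8
    initial_lr: float = 1e-4
    lr_schedule: str = "cosine_annealing"  # or "constant"
    lr_min: float = 0.0
    epochs: int = 100
    optimizer: str = "adam"
    seed: int = 0
    device: str = "cpu"
    checkpoint_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.initial_lr <= 0:
            raise ConfigurationError("batch_size, epochs and initial_lr must be positive")
        if self.lr_schedule not in ("cosine_annealing", "constant"):
            raise ConfigurationError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def desk_train_config(seed: int = 0, epochs: int = 20, **overrides) -> TrainConfig:
    """CPU-scale preset: 20 epochs at Adam's customary 1e-3."""
    return TrainConfig(epochs=epochs, initial_lr=1e-3, seed=seed, **overrides)


def cosine_annealing_lr(t: int, T: int, lr_max: float, lr_min: float = 0.0) -> float:
    """lr(t) = lr_min + (lr_max - lr_min) (1 + cos(pi t / T)) / 2 for 0 <= t <= T."""
    if T < 1:
        raise InputError(f"total epochs T must be >= 1, got {T}")
    if not (0 <= t <= T):
        raise InputError(f"epoch index t={t} outside [0, {T}]")
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t / T))


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

def load_dataset_arrays(manifest: pd.DataFrame, root, input_size: tuple) -> dict:
    """Load and preprocess every manifest image once.

    Returns {"train": (X, y), "test": (X, y)} with X of shape
    (N, 1, H, W) float32. Images are inverted (ink = 1, background = 0) so
    the waveform carries the activation mass.
    """
    from PIL import Image
    root = Path(root)
    out = {}
    for split in ("train", "test"):
        part = manifest[manifest["split"] == split]
        xs, ys = [], []
        for row in part.itertuples():
            path = root / row.file
            if not path.exists():
                raise InputError(f"manifest references missing image {path}")
            img = np.asarray(Image.open(path).convert("L"))
            xs.append(1.0 - preprocess_image(img, input_size))
            ys.append(int(row.label))
        W, H = input_size
        X = (np.stack(xs).reshape(len(xs), 1, H, W).astype(np.float32)
             if xs else np.zeros((0, 1, H, W), dtype=np.float32))
        out[split] = (X, np.asarray(ys, dtype=np.int64))
    return out


def _evaluate_arrays(model: CSPANet, X: np.ndarray, y: np.ndarray,
                     batch_size: int = 32) -> MetricReport:
    if len(X) == 0:
        raise InputError("evaluation split is empty")
    model.set_training(False)
    probs = np.concatenate([model.predict(X[i:i + batch_size]).probabilities
                            for i in range(0, len(X), batch_size)])
    preds = probs.argmax(axis=1)
    cm = confusion_from_predictions(y, preds)
    return macro_metrics(cm, scores=probs, true_labels=y)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def run_train(net_cfg: NetworkConfig, train_cfg: TrainConfig,
              manifest: pd.DataFrame | None = None, root=None,
              data: dict | None = None, synth_cfg=None, verbose: bool = False):
    """Train a model on a manifest (or preloaded arrays); returns
    (model, run_record dict).

    All randomness (weight init, batch shuffling) is seeded from the
    configs. If ``train_cfg.checkpoint_path`` / ``output_dir`` are set the
    checkpoint and RunRecord JSON are written there.
    """
    if data is None:
        if manifest is None or root is None:
            raise InputError("run_train needs either preloaded data or manifest + root")
        data = load_dataset_arrays(manifest, root, net_cfg.input_size)
    X_train, y_train = data["train"]
    X_test, y_test = data["test"]
    if len(X_train) == 0:
        raise InputError("training split is empty")

    model = CSPANet(net_cfg)
    opt = Adam(model.parameters(), lr=train_cfg.initial_lr)
    shuffle_rng = np.random.default_rng(train_cfg.seed)
    n = len(X_train)
    losses, reports = [], []
    t0 = time.time()
    for epoch in range(train_cfg.epochs):
        if train_cfg.lr_schedule == "cosine_annealing":
            opt.lr = cosine_annealing_lr(epoch, train_cfg.epochs,
                                         train_cfg.initial_lr, train_cfg.lr_min)
        model.set_training(True)
        order = shuffle_rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            logits = model.forward(X_train[idx])
            loss = ag.softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {n_batches}; "
                    f"lr={opt.lr:.3g}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / n_batches)
        report = _evaluate_arrays(model, X_test, y_test) if len(X_test) else None
        reports.append(report)
        if verbose:
            acc = f"{report.accuracy:.3f}" if report else "n/a"
            print(f"epoch {epoch + 1}/{train_cfg.epochs}  "
                  f"loss {losses[-1]:.4f}  test acc {acc}")

    record = {
        "format_version": RUN_RECORD_VERSION,
        "network_config": net_cfg.to_dict(),
        "train_config": train_cfg.to_dict(),
        "synth_config": synth_cfg.to_dict() if synth_cfg is not None else None,
        "seed": train_cfg.seed,
        "adam": {"betas": [opt.beta1, opt.beta2], "eps": opt.eps},
        "n_parameters": count_parameters(model),
        "train_losses": losses,
        "test_metrics": [r.to_dict() if r else None for r in reports],
        "wall_clock_s": time.time() - t0,
    }
    if train_cfg.checkpoint_path:
        save_checkpoint(train_cfg.checkpoint_path, model, seed=train_cfg.seed)
    if train_cfg.output_dir:
        out = Path(train_cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_record.json", "w") as fh:
            json.dump(record, fh, indent=2)
    return model, record


def run_eval(model_or_checkpoint, manifest: pd.DataFrame | None = None, root=None,
             data: dict | None = None, split: str = "test",
             output_dir=None) -> MetricReport:
    """Deterministic evaluation of a model or checkpoint on one split."""
    if isinstance(model_or_checkpoint, CSPANet):
        model = model_or_checkpoint
    else:
        model, _ = load_checkpoint(model_or_checkpoint)
    if data is None:
        if manifest is None or root is None:
            raise InputError("run_eval needs either preloaded data or manifest + root")
        data = load_dataset_arrays(manifest, root, model.cfg.input_size)
    X, y = data[split]
    if len(X) == 0:
        raise InputError(f"evaluation split {split!r} is empty")
    report = _evaluate_arrays(model, X, y)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "metrics.json")
        report.confusion.to_csv(out / "confusion.csv")
        probs = np.concatenate([model.predict(X[i:i + 32]).probabilities
                                for i in range(0, len(X), 32)])
        roc_to_csv(out / "roc.csv", probs, y)
    return report


# ---------------------------------------------------------------------------
# Experiment runners
# ---------------------------------------------------------------------------

def run_compare(names, net_cfg_factory, train_cfg: TrainConfig,
                manifest: pd.DataFrame | None = None, root=None,
                data: dict | None = None, verbose: bool = False) -> pd.DataFrame:
    """Train one model per attention name on identical data and seeds.

    ``net_cfg_factory(name)`` must return the backbone config with that
    attention plugged in. Returns a table with one row per name and the
    four headline metrics.
    """
    unknown = [n for n in names if n not in attention_names()]
    if unknown:
        raise ConfigurationError(
            f"unknown attention name(s) {unknown}; valid: {attention_names()}")
    rows = []
    for name in names:
        cfg = net_cfg_factory(name)
        if data is None:
            data = load_dataset_arrays(manifest, root, cfg.input_size)
        _, record = run_train(cfg, train_cfg, data=data, verbose=verbose)
        final = record["test_metrics"][-1]
        rows.append({"attention": name,
                     "accuracy": final["accuracy"],
                     "sensitivity": final["macro_sensitivity"],
                     "specificity": final["macro_specificity"],
                     "precision": final["macro_precision"]})
    return pd.DataFrame(rows)


def ablation_configs(desk: bool = False, seed: int = 0) -> list:
    """The four ablation arms: {stem off/on} x {attention off/on}.

    Arm (stem off, attention off) is the plain bottleneck baseline whose
    entry is a single 7x7 convolution; arm (on, on) is the full model.
    """
    arms = []
    for stem_on in (False, True):
        for cspa_on in (False, True):
            arms.append({
                "stem": stem_on,
                "cspa": cspa_on,
                "net_cfg": default_network_config(
                    attention="cspa" if cspa_on else "none",
                    stem_enabled=stem_on, desk=desk, seed=seed),
            })
    return arms


def run_ablation(train_cfg: TrainConfig, manifest: pd.DataFrame | None = None,
                 root=None, data: dict | None = None, desk: bool = True,
                 verbose: bool = False) -> pd.DataFrame:
    """Train all four ablation arms on identical data and seeds."""
    arms = ablation_configs(desk=desk, seed=train_cfg.seed)
    if data is None:
        data = load_dataset_arrays(manifest, root, arms[0]["net_cfg"].input_size)
    rows = []
    for arm in arms:
        _, record = run_train(arm["net_cfg"], train_cfg, data=data, verbose=verbose)
        final = record["test_metrics"][-1]
        rows.append({"stem": arm["stem"], "cspa": arm["cspa"],
                     "accuracy": final["accuracy"],
                     "sensitivity": final["macro_sensitivity"],
                     "specificity": final["macro_specificity"],
                     "precision": final["macro_precision"]})
    return pd.DataFrame(rows)


def overfit_one_batch(net_cfg: NetworkConfig, X: np.ndarray, y: np.ndarray,
                      max_steps: int = 50, lr: float = 1e-3, seed: int = 0):
    """Sanity check: drive one batch to perfect training accuracy.

    Returns (steps_taken, final_accuracy); steps_taken is the first step
    at which the batch is classified perfectly, or max_steps if never.
    """
    model = CSPANet(net_cfg)
    opt = Adam(model.parameters(), lr=lr)
    for step in range(1, max_steps + 1):
        model.set_training(True)
        logits = model.forward(X)
        loss = ag.softmax_cross_entropy(logits, y)
        model.zero_grad()
        loss.backward()
        opt.step()
        preds = model.predict(X).predicted_class
        if np.array_equal(preds, y):
            return step, 1.0
    acc = float((preds == y).mean())
    return max_steps, acc
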