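"""Training and inference for the nine-class classifier.

Published schedule: 30 epochs, batch size 88, ADAM with cross-entropy loss,
initial learning rate 5e-3 dropping by 0.9 every five epochs, L2 1e-4,
epsilon 1e-8, per-epoch shuffling, and reflection/rotation/translation/
90-110%-scaling augmentation. Zero-centring subtracts the mean training
image (stored with the model so inference is deterministic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from mnflow.deepflow.augment import AugmentConfig, augment_batch
from mnflow.deepflow.layers import cross_entropy_grad, softmax
from mnflow.deepflow.network import Network, NetworkConfig, build_network
from mnflow.deepflow.schedule import lr_at_epoch
from mnflow.ingest.records import CellRecord
from mnflow.taxonomy import CLASS_NAMES

F32 = np.float32
U16_MAX = 65535.0


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule and augmentation settings."""

    epochs: int = 30
    batch_size: int = 88
    lr0: float = 5e-3
    lr_drop_factor: float = 0.9
    lr_drop_period_epochs: int = 5
    l2: float = 1e-4
    epsilon: float = 1e-8
    shuffle_each_epoch: bool = True
    augmentation: Optional[AugmentConfig] = field(default_factory=AugmentConfig)
    class_weights: Optional[tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "batch_size", "lr0", "lr_drop_factor",
                     "lr_drop_period_epochs", "l2", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedModel:
    """Network weights plus both configurations, history and label encoding."""

    network: Network
    net_config: NetworkConfig
    train_config: Optional[TrainConfig]
    history: list[dict] = field(default_factory=list)
    mean_image: Optional[np.ndarray] = None  # (H, W, C) float32, training-set mean
    label_names: tuple[str, ...] = CLASS_NAMES


def _to_float_images(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images)
    if x.dtype == np.uint16:
        return (x / U16_MAX).astype(F32)
    return x.astype(F32)


def _records_to_arrays(records: Sequence, labels=None):
    if labels is None and len(records) and isinstance(records[0], CellRecord):
        images = np.stack([r.image for r in records])
        labels = np.array([int(r.label) for r in records])
    else:
        images = np.stack([np.asarray(r) for r in records])
        labels = None if labels is None else np.asarray(labels, dtype=int)
    return _to_float_images(images), labels


def inverse_frequency_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse class-frequency weights normalised to mean 1 over the classes
    that occur; absent classes get weight 1."""
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    present = counts > 0
    w = np.ones(n_classes)
    w[present] = 1.0 / counts[present]
    w[present] *= present.sum() / w[present].sum()
    return w


def train(
    model: TrainedModel | Network | None,
    train_set: Sequence,
    cfg: TrainConfig,
    labels: Sequence[int] | None = None,
    net_config: NetworkConfig | None = None,
) -> TrainedModel:
    """Train the classifier; returns a TrainedModel with per-epoch history.

    ``train_set`` is either a sequence of labelled CellRecords or an array of
    images with ``labels`` given separately. Deterministic for a fixed seed.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    images, y = _records_to_arrays(train_set, labels)
    if y is None:
        raise ValueError("training records must carry labels")

    if isinstance(model, TrainedModel):
        net, net_cfg = model.network, model.net_config
    elif isinstance(model, Network):
        net, net_cfg = model, model.cfg
    else:
        net_cfg = net_config or NetworkConfig(seed=cfg.seed)
        net = build_network(net_cfg)

    if y.min() < 0 or y.max() >= net_cfg.n_classes:
        raise ValueError(
            f"label outside encoding 0..{net_cfg.n_classes - 1}: "
            f"range {y.min()}..{y.max()}"
        )

    mean_image = images.mean(axis=0)
    rng = np.random.default_rng(cfg.seed)
    optimizer = net.make_optimizer(l2=cfg.l2, eps=cfg.epsilon)

    cw = None
    if cfg.class_weights is not None:
        cw = np.asarray(cfg.class_weights, dtype=float)
        if cw.shape != (net_cfg.n_classes,):
            raise ValueError(f"class_weights must have length {net_cfg.n_classes}")

    n = images.shape[0]
    history: list[dict] = []
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_at_epoch(epoch, cfg.lr0, cfg.lr_drop_factor, cfg.lr_drop_period_epochs)
        order = rng.permutation(n) if cfg.shuffle_each_epoch else np.arange(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = images[idx]
            if cfg.augmentation is not None:
                xb = augment_batch(xb, rng, cfg.augmentation)
            xb = xb - mean_image
            logits = net.forward(xb, train=True)
            sw = cw[y[idx]] if cw is not None else None
            loss, dlogits = cross_entropy_grad(logits, y[idx], sw)
            net.backward(dlogits)
            optimizer.step(lr)
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history.append(
            {"epoch": epoch, "lr": lr, "loss": float(np.sum(losses) / n),
             "accuracy": correct / n}
        )

    names = CLASS_NAMES if net_cfg.n_classes == 9 else tuple(
        f"class_{i}" for i in range(net_cfg.n_classes)
    )
    return TrainedModel(
        network=net, net_config=net_cfg, train_config=cfg,
        history=history, mean_image=mean_image, label_names=names,
    )


@dataclass
class Prediction:
    probabilities: np.ndarray  # (N, n_classes)
    labels: np.ndarray         # argmax encoding
    confidence: np.ndarray     # max softmax probability per record


def predict(model: TrainedModel, records: Sequence, batch_size: int = 256) -> Prediction:
    """Class probabilities, argmax labels and confidences for records."""
    images, _ = _records_to_arrays(records)
    if model.mean_image is not None:
        images = images - model.mean_image
    probs = []
    for start in range(0, images.shape[0], batch_size):
        logits = model.network.forward(images[start:start + batch_size], train=False)
        probs.append(softmax(logits.astype(np.float64)))
    p = np.concatenate(probs) if probs else np.zeros((0, model.net_config.n_classes))
    return Prediction(probabilities=p, labels=p.argmax(axis=1),
                      confidence=p.max(axis=1) if len(p) else np.zeros(0))


# ---- checkpointing -----------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Versioned checkpoint: weights + configs + label encoding (.npz)."""
    meta = {
        "format_version": 1,
        "net_config": asdict(model.net_config),
        "train_config": asdict(model.train_config) if model.train_config else None,
        "history": model.history,
        "label_names": list(model.label_names),
    }
    arrays = model.network.state_arrays()
    payload = {f"w::{k}": v for k, v in arrays.items()}
    if model.mean_image is not None:
        payload["mean_image"] = model.mean_image
    np.savez_compressed(path, meta=json.dumps(meta), **payload)


def load_model(path) -> TrainedModel:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        nc = meta["net_config"]
        for key in ("input_shape", "block_widths", "n_blocks_per_scale"):
            nc[key] = tuple(nc[key])
        net_cfg = NetworkConfig(**nc)
        net = build_network(net_cfg)
        net.load_state({k[3:]: data[k] for k in data.files if k.startswith("w::")})
        tc = None
        if meta.get("train_config"):
            t = dict(meta["train_config"])
            if t.get("augmentation"):
                t["augmentation"] = AugmentConfig(**{
                    **t["augmentation"],
                    "scale_range": tuple(t["augmentation"]["scale_range"]),
                })
            if t.get("class_weights"):
                t["class_weights"] = tuple(t["class_weights"])
            tc = TrainConfig(**t)
        mean_image = data["mean_image"] if "mean_image" in data.files else None
    return TrainedModel(
        network=net, net_config=net_cfg, train_config=tc,
        history=meta.get("history", []),
        mean_image=mean_image,
        label_names=tuple(meta.get("label_names", CLASS_NAMES)),
    )
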