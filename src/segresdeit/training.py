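"""Training regimen: Adam + cosine annealing, gradient accumulation,
dynamic augmentation, early stopping on validation loss, prediction and the
ablation runner.

Defaults: Adam at 1e-4 with weight decay
1e-5, micro-batch 8 with gradient accumulation over 2 steps (effective
batch 16), up to 30 epochs, early stopping patience 10, dropout 0.3,
cosine-annealed learning rate with floor 0, and the optimised loss weights
lambda1=0.6, lambda2=0.4, alpha=1.0.  One run seed drives weight
initialisation, shuffling, augmentation and dropout streams.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from .architecture import ModelConfig, SegClsOutput, SegResDeiT, build_model
from .data_pipeline import ImageMaskPair, augment_pair
from .metrics import MetricReport, evaluate_model
from .nn import Adam, Dropout, Module, _collect_modules
from .objectives import LossWeights, total_loss
from .tensor import Tensor


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 8
    grad_accumulation_steps: int = 2
    max_epochs: int = 30
    early_stop_patience: int = 10
    cosine_floor_lr: float = 0.0
    dropout: float = 0.3
    seed: int = 0
    augment: bool = True
    loss_weights: LossWeights = field(default_factory=LossWeights)

    @property
    def effective_batch(self) -> int:
        return self.batch_size * self.grad_accumulation_steps


def cosine_lr(epoch: int, initial_lr: float, t_max: int, floor_lr: float = 0.0) -> float:
    """Cosine annealing: floor + (initial-floor)/2 * (1 + cos(pi*epoch/t_max))."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not 0 <= epoch <= t_max:
        raise ValueError("epoch must lie in [0, t_max]")
    return floor_lr + 0.5 * (initial_lr - floor_lr) * (1.0 + math.cos(math.pi * epoch / t_max))


def _to_batch(pairs: Sequence[ImageMaskPair]) -> tuple[Tensor, Tensor, Tensor]:
    x = Tensor(np.stack([p.image.transpose(2, 0, 1) for p in pairs]))
    masks = Tensor(np.stack([p.mask for p in pairs])[:, None].astype(np.float64))
    labels = Tensor(np.array([p.label for p in pairs], dtype=np.float64))
    return x, masks, labels


def _batch_loss(model: SegResDeiT, pairs: Sequence[ImageMaskPair],
                weights: LossWeights) -> Tensor:
    x, masks, labels = _to_batch(pairs)
    out: SegClsOutput = model(x)
    class_probs = [logit.sigmoid() for logit in out.class_logits]
    return total_loss(out.mask_probability, masks, class_probs, labels, weights)


def _seed_dropout(model: Module, rng: np.random.Generator) -> None:
    for mod in _collect_modules(model):
        if isinstance(mod, Dropout):
            mod.rng = np.random.default_rng(rng.integers(0, 2**31 - 1))


def train(
    model: SegResDeiT,
    train_set: Sequence[ImageMaskPair],
    val_set: Sequence[ImageMaskPair],
    config: TrainConfig = TrainConfig(),
) -> tuple[dict, list[dict]]:
    """Train with gradient accumulation and early stopping.

    Returns ``(checkpoint, history)`` where the checkpoint holds the
    best-validation-loss weights (strict improvement rule) plus configs, and
    history has one record per epoch with losses and the learning rate.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    _seed_dropout(model, rng)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)

    best_loss = math.inf
    best_state = model.state_dict()
    best_epoch = -1
    epochs_since_best = 0
    history: list[dict] = []

    n = len(train_set)
    order = np.arange(n)
    for epoch in range(config.max_epochs):
        lr = cosine_lr(epoch, config.learning_rate, config.max_epochs,
                       config.cosine_floor_lr)
        opt.lr = lr
        model.train()
        rng.shuffle(order)
        epoch_losses = []
        micro = 0
        opt.zero_grad()
        for start in range(0, n, config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            batch = [train_set[i] for i in batch_idx]
            if config.augment:
                batch = [
                    augment_pair(p, seed=int(rng.integers(0, 2**31 - 1)))
                    for p in batch
                ]
            loss = _batch_loss(model, batch, config.loss_weights)
            (loss * (1.0 / config.grad_accumulation_steps)).backward()
            epoch_losses.append(loss.item())
            micro += 1
            if micro % config.grad_accumulation_steps == 0:
                opt.step()
                opt.zero_grad()
        if micro % config.grad_accumulation_steps:
            opt.step()
            opt.zero_grad()

        model.eval()
        val_losses = []
        for start in range(0, len(val_set), config.batch_size):
            chunk = val_set[start : start + config.batch_size]
            val_losses.append(
                _batch_loss(model, chunk, config.loss_weights).item() * len(chunk)
            )
        val_loss = sum(val_losses) / len(val_set)
        history.append({
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
        })
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best > config.early_stop_patience:
                break

    model.load_state_dict(best_state)
    checkpoint = {
        "state": best_state,
        "model_config": model.config.to_dict(),
        "train_config": {**asdict(config),
                         "loss_weights": asdict(config.loss_weights)},
        "best_epoch": best_epoch,
        "best_val_loss": best_loss,
    }
    return checkpoint, history


def save_checkpoint(checkpoint: dict, path: str | Path) -> None:
    path = Path(path)
    meta = {k: v for k, v in checkpoint.items() if k != "state"}
    np.savez_compressed(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"param::{k}": v for k, v in checkpoint["state"].items()},
    )


def load_checkpoint(path: str | Path) -> dict:
    try:
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {
            k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")
        }
    except Exception as exc:  # corrupt or foreign file
        raise ValueError(f"cannot read checkpoint {path}: {exc}") from exc
    meta["state"] = state
    return meta


def model_from_checkpoint(checkpoint: dict) -> SegResDeiT:
    model = build_model(ModelConfig.from_dict(checkpoint["model_config"]))
    model.load_state_dict(checkpoint["state"])
    return model.eval()


def predict(
    model: SegResDeiT,
    pairs: Sequence[ImageMaskPair],
    out_dir: Optional[str | Path] = None,
    batch_size: int = 8,
) -> list[dict]:
    """Single forward pass per batch; thresholded masks/labels at 0.5.

    When `out_dir` is given, writes one predicted-mask PNG per sample and a
    CSV of (sample_id, class_probability, label).
    """
    model.eval()
    results = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        x = Tensor(np.stack([p.image.transpose(2, 0, 1) for p in chunk]))
        out = model(x)
        mask_prob = out.mask_probability.data[:, 0]
        class_prob = out.class_probability.data
        for i, pair in enumerate(chunk):
            results.append({
                "sample_id": pair.sample_id,
                "mask_probability": mask_prob[i],
                "mask": (mask_prob[i] >= 0.5).astype(np.uint8),
                "class_probability": float(class_prob[i]),
                "label": int(class_prob[i] >= 0.5),
            })
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "predictions.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_id", "class_probability", "label"])
            for rec in results:
                Image.fromarray(rec["mask"] * 255).save(
                    out_dir / f"{rec['sample_id']}_pred.png"
                )
                writer.writerow(
                    [rec["sample_id"], f"{rec['class_probability']:.6f}", rec["label"]]
                )
    return results


def run_ablation(
    variants: Sequence[str],
    model_config: ModelConfig,
    train_set: Sequence[ImageMaskPair],
    val_set: Sequence[ImageMaskPair],
    train_config: TrainConfig = TrainConfig(),
) -> list[dict]:
    """Train each variant identically on the same data; report metrics.

    No ordering is asserted — the table is reported as computed.
    """
    if len(variants) < 2:
        raise ValueError("ablation needs at least two variants")
    rows = []
    for variant in variants:
        cfg_dict = model_config.to_dict()
        cfg_dict["variant"] = variant
        cfg = ModelConfig.from_dict(cfg_dict)
        model = build_model(cfg, seed=train_config.seed)
        _, history = train(model, train_set, val_set, train_config)
        report_img = evaluate_model(model, val_set, mode="image")
        report_pix = evaluate_model(model, val_set, mode="pixel")
        row = {"variant": variant, "parameters": model.num_parameters(),
               "epochs_run": len(history)}
        row.update({f"image_{k}": v for k, v in report_img.rounded().items()})
        row.update({f"pixel_{k}": v for k, v in report_pix.rounded().items()})
        rows.append(row)
    return rows


def write_history_csv(history: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
        writer.writeheader()
        writer.writerows(history)
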