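"""Training loop, inference and checkpointing for the segmentation nets."""

from __future__ import annotations


import json
import os
from dataclasses import dataclass, field

import numpy as np

from prlquant.networks import ops
from prlquant.networks.models import ModelConfig, Module, Ctx, build_model


@dataclass
class TrainedModel:
    """A model plus its config snapshot and per-epoch training history."""

    model: Module
    config: ModelConfig
    history: list[dict] = field(default_factory=list)

    @property
    def arch_name(self) -> str:
        return self.config.arch_name


def pad_to_multiple(img: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad bottom/right so both spatial dims divide ``multiple``."""
    h, w = img.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img, (h, w)


def dice_binary(pred: np.ndarray, truth: np.ndarray) -> float:
    """2TP/(2TP+FP+FN); defined as 1.0 when both masks are empty."""
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    tp = np.count_nonzero(pred & truth)
    denom = 2 * tp + np.count_nonzero(pred & ~truth) + np.count_nonzero(~pred & truth)
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def _forward_logits(model: Module, batch: np.ndarray, ctx: Ctx) -> ops.Tensor:
    x = ops.Tensor(batch[:, None, :, :])  # add channel dim
    return model.forward(x, ctx)


def _snapshot(model: Module) -> list[np.ndarray]:
    return [p.data.copy() for p in model.parameters()]


def _restore(model: Module, params: list[np.ndarray]) -> None:
    for p, saved in zip(model.parameters(), params):
        p.data[...] = saved


def train_model(model: Module, train_pairs: list[tuple[np.ndarray, np.ndarray]],
                val_pairs: list[tuple[np.ndarray, np.ndarray]] | None,
                config: ModelConfig) -> TrainedModel:
    """Train with Adam on BCE + soft-Dice; keep the epoch with best
    validation Dice (early stopping on ``config.patience``).

    Deterministic for a fixed ``config.seed`` under single-threaded BLAS.
    """
    if not train_pairs:
        raise ValueError("empty training set")
    multiple = 2 ** (config.depth - 1)
    xs = []
    ys = []
    for img, msk in train_pairs:
        xi, _ = pad_to_multiple(np.asarray(img, dtype=np.float32), multiple)
        yi, _ = pad_to_multiple(np.asarray(msk, dtype=np.float32), multiple)
        if xi.shape != yi.shape:
            raise ValueError("image/mask shape mismatch")
        xs.append(xi)
        ys.append(yi)
    xs = np.stack(xs)
    ys = np.stack(ys)
    if not val_pairs:
        val_pairs = train_pairs

    rng = np.random.default_rng(config.seed + 1)
    optim = ops.Adam(model.parameters(), lr=config.learning_rate)
    history: list[dict] = []
    best_score = -np.inf
    best_params = _snapshot(model)
    since_improve = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(xs))
        epoch_loss = 0.0
        n_batches = 0
        ctx = Ctx(training=True, rng=rng)
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = _forward_logits(model, xs[idx], ctx)
            loss = ops.bce_dice_with_logits(logits, ys[idx][:, None, :, :])
            loss_val = float(np.ravel(loss.data)[0])
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: {loss_val}"
                )
            optim.zero_grad()
            loss.backward()
            optim.step()
            epoch_loss += loss_val
            n_batches += 1

        val_dice = float(np.mean([
            dice_binary(predict_with_module(model, config, img) >= 0.5, msk)
            for img, msk in val_pairs
        ]))
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_dice": val_dice,
        })
        if val_dice > best_score:
            best_score = val_dice
            best_params = _snapshot(model)
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break

    _restore(model, best_params)
    return TrainedModel(model=model, config=config, history=history)


def predict_with_module(model: Module, config: ModelConfig,
                        image: np.ndarray) -> np.ndarray:
    """Score map in [0,1] for one B-scan (same height/width as input)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D B-scan, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("input contains non-finite pixels")
    padded, (h, w) = pad_to_multiple(image.astype(np.float32), 2 ** (config.depth - 1))
    logits = _forward_logits(model, padded[None], Ctx(training=False))
    scores = ops.sigmoid_np(logits.data[0, 0].astype(np.float64))[:h, :w]
    return np.clip(scores, 0.0, 1.0)


def predict_bscan(trained: TrainedModel, image: np.ndarray) -> np.ndarray:
    """Inference contract: [0,1] in, congruent [0,1] score map out."""
    return predict_with_module(trained.model, trained.config, image)


def save_checkpoint(trained: TrainedModel, path: str | os.PathLike) -> None:
    """Single-file container: parameter arrays + JSON config + history."""
    arrays = {f"param_{i:04d}": p.data for i, p in enumerate(trained.model.parameters())}
    meta = json.dumps({
        "config": trained.config.to_dict(),
        "history": trained.history,
    })
    np.savez_compressed(os.fspath(path), _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **arrays)


def load_checkpoint(path: str | os.PathLike) -> TrainedModel:
    with np.load(os.fspath(path)) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        config = ModelConfig.from_dict(meta["config"])
        model = build_model(config)
        params = model.parameters()
        keys = sorted(k for k in data.files if k.startswith("param_"))
        if len(keys) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, k in zip(params, keys):
            p.data[...] = data[k]
    return TrainedModel(model=model, config=config, history=meta["history"])
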