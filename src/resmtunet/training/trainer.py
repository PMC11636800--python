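"""Joint training of the classification and segmentation heads.

SGD with momentum 0.9, initial learning rate 1e-3 halved every 7 epochs,
30 epochs, batch size 16 by default.  Per epoch the trainer logs the total
loss and its two components and, when a validation split is given, the
validation mean IoU; the checkpoint with the best validation mean IoU is
kept.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from ..config import ModelConfig, TrainConfig
from ..metrics import segmentation_metrics
from ..model import ResMTUNet
from ..nn import SGD, Tensor, no_grad
from .augment import augment
from .data import TrainingSample, to_batch
from .losses import multitask_loss

logger = logging.getLogger(__name__)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate at a given epoch: lr0 * 0.5 ** floor(epoch / period)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr0 * 0.5 ** (epoch // cfg.halving_period)


def evaluate_seg(model: ResMTUNet, samples: list[TrainingSample],
                 batch_size: int = 8) -> float:
    """Mean IoU of argmax predictions over a sample list."""
    preds, truths = [], []
    model.eval()
    with no_grad():
        for i in range(0, len(samples), batch_size):
            imgs, masks, _ = to_batch(samples[i:i + batch_size])
            probs = model.predict_proba(imgs)
            preds.extend(list(probs.argmax(axis=1)))
            truths.extend(list(masks))
    n_labels = model.cfg.n_class + 1
    return segmentation_metrics(preds, truths, n_labels).iou


def train(samples: list[TrainingSample],
          model: ResMTUNet | ModelConfig | None = None,
          train_cfg: TrainConfig | None = None,
          val_samples: list[TrainingSample] | None = None,
          out_dir: str | Path | None = None,
          max_steps: int | None = None,
          use_augment: bool = True,
          eval_every: int = 1) -> tuple[ResMTUNet, list[dict]]:
    """Train a model on ``samples``; returns (model, per-epoch history)."""
    if not samples:
        raise ValueError("training requires a non-empty dataset")
    cfg = train_cfg or TrainConfig()
    if isinstance(model, ResMTUNet):
        net = model
    else:
        net = ResMTUNet(model if isinstance(model, ModelConfig) else None)
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(net.parameters(), lr=cfg.lr0, momentum=cfg.momentum)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    history: list[dict] = []
    best_miou = -1.0
    step = 0
    for epoch in range(cfg.epochs):
        opt.lr = lr_at(epoch, cfg)
        order = rng.permutation(len(samples))
        net.train()
        ep_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [samples[j] for j in order[start:start + cfg.batch_size]]
            if use_augment:
                batch = [augment(s, rng, cfg) for s in batch]
            imgs, masks, labels = to_batch(batch)
            output = net(Tensor(imgs))
            total, l_class, l_seg = multitask_loss(
                output, masks, labels, cfg.lambda_weight)
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step}: "
                    f"L_class={l_class.data}, L_seg={l_seg.data}")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_losses.append((float(total.data), float(l_class.data),
                              float(l_seg.data)))
            step += 1
            if max_steps is not None and step >= max_steps:
                break
        mean = np.mean(ep_losses, axis=0)
        record = {"epoch": epoch, "lr": opt.lr, "loss_total": mean[0],
                  "loss_class": mean[1], "loss_seg": mean[2]}
        if val_samples and (epoch % eval_every == 0 or epoch == cfg.epochs - 1):
            miou = evaluate_seg(net, val_samples)
            record["val_miou"] = miou
            if miou > best_miou:
                best_miou = miou
                if out is not None:
                    net.save(out / "best.npz")
        history.append(record)
        logger.info("epoch %d: %s", epoch, record)
        if max_steps is not None and step >= max_steps:
            break

    if out is not None:
        net.save(out / "last.npz")
        keys = sorted({k for r in history for k in r})
        with open(out / "history.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(history)
    return net, history
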