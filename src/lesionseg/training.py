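"""Losses, overlap metrics, paired augmentation and the training loop.

Two loss functions are supported: pixel-mean binary cross-entropy and the
soft-Jaccard ("IoU") surrogate 1 − (Σpy + ε)/(Σp + Σy − Σpy + ε) with
ε = 1.  Training uses Adam, per-epoch validation, best-checkpoint on
validation loss and early stopping, all driven by a single seed so that two
runs with the same seed produce identical histories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import rescale as _sk_rescale

from .nn import autograd as ag
from .nn.autograd import Tensor, astensor
from .nn.optim import Adam
from .architectures import MetaUNet, images_to_batch
from .data_model import LesionSample

LOSSES = ("bce", "iou")


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 200
    early_stop_patience: int = 20
    loss: str = "iou"
    augmentation: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("rates and sizes must be positive")


# ---------------------------------------------------------------------
# losses (differentiable, Tensor-valued)
# ---------------------------------------------------------------------

def bce_loss(pred_probs, mask, eps: float = 1e-7) -> Tensor:
    """Pixel-mean binary cross-entropy with probability clipping."""
    p = astensor(pred_probs)
    y = astensor(mask)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    p = ag.clip(p, eps, 1.0 - eps)
    return ag.tmean(-(y * ag.log(p) + (1.0 - y) * ag.log(1.0 - p)))


def iou_loss(pred_probs, mask, eps: float = 1.0) -> Tensor:
    """Soft-Jaccard loss: 1 − (|p∩y| + ε) / (|p∪y| + ε)."""
    p = astensor(pred_probs)
    y = astensor(mask)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    inter = ag.tsum(p * y)
    union = ag.tsum(p) + ag.tsum(y) - inter
    return 1.0 - (inter + eps) / (union + eps)


_LOSS_FNS = {"bce": bce_loss, "iou": iou_loss}


# ---------------------------------------------------------------------
# overlap metrics (numpy, on binarized masks)
# ---------------------------------------------------------------------

def _binarize(m) -> np.ndarray:
    return (np.asarray(m, dtype=float) > 0.5)


def iou_metric(pred_mask, gt_mask) -> float:
    """|∩|/|∪| after binarizing at 0.5; both-empty convention = 1.0."""
    a, b = _binarize(pred_mask), _binarize(gt_mask)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice_metric(pred_mask, gt_mask) -> float:
    """2|∩|/(|A|+|B|); both-empty convention = 1.0."""
    a, b = _binarize(pred_mask), _binarize(gt_mask)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


# ---------------------------------------------------------------------
# paired augmentation
# ---------------------------------------------------------------------

def _scale_crop(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Rescale then center-crop / zero-pad back to the original size."""
    h, w = arr.shape[:2]
    out = _sk_rescale(arr, factor, order=order, channel_axis=2 if arr.ndim == 3 else None,
                      anti_aliasing=False, preserve_range=True)
    oh, ow = out.shape[:2]
    if oh >= h:
        dy, dx = (oh - h) // 2, (ow - w) // 2
        return out[dy:dy + h, dx:dx + w]
    pad_y, pad_x = h - oh, w - ow
    pads = [(pad_y // 2, pad_y - pad_y // 2), (pad_x // 2, pad_x - pad_x // 2)]
    if arr.ndim == 3:
        pads.append((0, 0))
    return np.pad(out, pads)


def augment_pair(sample: LesionSample, rng: np.random.Generator) -> LesionSample:
    """One random geometric transform applied identically to image and mask.

    Draws from {identity, h-flip, v-flip, rotation 90/180/270, scale in
    [0.9, 1.1] with crop/pad}; the metadata vector is geometry-invariant and
    passes through unchanged, staying paired with the transformed image.
    """
    choice = rng.integers(0, 7)
    img, mask = sample.image, sample.mask
    if choice == 1:
        img, mask = img[:, ::-1], mask[:, ::-1]
    elif choice == 2:
        img, mask = img[::-1], mask[::-1]
    elif choice in (3, 4, 5):
        k = int(choice) - 2
        img, mask = np.rot90(img, k), np.rot90(mask, k)
    elif choice == 6:
        f = rng.uniform(0.9, 1.1)
        img = np.clip(_scale_crop(img, f, order=1), 0, 1)
        mask = _scale_crop(mask.astype(float), f, order=0).astype(np.uint8)
    return LesionSample(sample.id, np.ascontiguousarray(img),
                        np.ascontiguousarray(mask), sample.metadata.copy(),
                        sample.schema)


# ---------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------

@dataclass
class TrainResult:
    history: pd.DataFrame        # epoch, train_loss, val_loss, val_iou
    best_epoch: int
    best_val_loss: float
    best_state: list             # parameter arrays at the checkpoint


def _forward_loss(model: MetaUNet, samples, loss_fn, stochastic, rng) -> Tensor:
    imgs, masks, meta = images_to_batch(samples)
    meta_arg = meta if model.cfg.fusion_strategy != "none" else None
    pred = model.forward(imgs, meta_arg, stochastic=stochastic, rng=rng)
    return loss_fn(pred, masks[:, None, :, :])


def evaluate_loss(model: MetaUNet, samples, loss: str = "iou",
                  batch_size: int = 16) -> float:
    loss_fn = _LOSS_FNS[loss]
    total, n = 0.0, 0
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        total += _forward_loss(model, chunk, loss_fn, False, None).item() * len(chunk)
        n += len(chunk)
    return total / n


def evaluate_iou(model: MetaUNet, samples, batch_size: int = 16) -> float:
    vals = []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        imgs, masks, meta = images_to_batch(chunk)
        meta_arg = meta if model.cfg.fusion_strategy != "none" else None
        probs = model.predict(imgs, meta_arg)
        vals.extend(iou_metric(p, m) for p, m in zip(probs, masks))
    return float(np.mean(vals))


def train(model: MetaUNet, dataset, cfg: TrainConfig) -> TrainResult:
    """Train ``model`` on ``dataset`` = {"train": [...], "val": [...]}.

    Checkpoints the best weights on validation loss, stops after
    ``early_stop_patience`` epochs without improvement, restores the best
    weights before returning.  Fully deterministic for a fixed seed.
    """
    train_samples = list(dataset["train"])
    val_samples = list(dataset["val"])
    if not train_samples or not val_samples:
        raise ValueError("train and val splits must be non-empty")
    loss_fn = _LOSS_FNS[cfg.loss]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)

    best_loss = np.inf
    best_epoch = -1
    best_state = model.state_arrays()
    bad_epochs = 0
    rows = []

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_samples))
        epoch_loss, n_seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_samples[j] for j in order[i:i + cfg.batch_size]]
            if cfg.augmentation:
                batch = [augment_pair(s, rng) for s in batch]
            loss = _forward_loss(model, batch, loss_fn,
                                 stochastic=model.cfg.bayesian, rng=rng)
            if not np.isfinite(loss.item()):
                raise TrainingDivergedError(
                    f"non-finite loss {loss.item()} at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(batch)
            n_seen += len(batch)

        val_loss = evaluate_loss(model, val_samples, cfg.loss, cfg.batch_size)
        val_iou = evaluate_iou(model, val_samples, cfg.batch_size)
        rows.append({"epoch": epoch, "train_loss": epoch_loss / n_seen,
                     "val_loss": val_loss, "val_iou": val_iou})
        if val_loss < best_loss:
            best_loss = val_loss
            best_epoch = epoch
            best_state = model.state_arrays()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.early_stop_patience:
                break

    model.load_state_arrays(best_state)
    return TrainResult(pd.DataFrame(rows), best_epoch, float(best_loss),
                       [a.copy() for a in best_state])
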