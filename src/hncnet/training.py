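"""Training loop: class-weighted BCE, prescribed augmentation, SGD with
momentum and L2 decay, per-epoch AUC logging and early stopping.

Defaults are the tuned recipe: constant learning rate 0.05, momentum 0.9,
L2 1e-4 (weights only), batch size 64, up to 3000 epochs with early stop at
training AUC > 0.95, and loss rescaling 3.7 for the minority class vs 0.7
for the dominating class. Augmentation (training images only): random
horizontal/vertical flips at p = 0.5, a uniform number of 90-degree
rotations, an extra rotation drawn from [0, 20] degrees, and per-axis
shifts of up to 3% of the image size.

All randomness derives from ``TrainConfig.seed`` through three named
substreams (shuffle, augment, dropout) so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .errors import ConfigurationError, TrainingError
from .evaluation import roc_auc
from .models import ModelHandle
from .nn import SGD

PROB_EPS = 1e-7  # probabilities are clamped to [eps, 1-eps] inside the loss


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.05
    momentum: float = 0.9
    l2_lambda: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 3000
    early_stop_train_auc: float = 0.95
    w_pos: float = 3.7
    w_neg: float = 0.7
    leaky_slope: float = 0.01
    seed: int = 0
    augmentation: bool = True
    checkpoint_stride: int = 1  # retain every k-th epoch (best-val always kept)

    def __post_init__(self):
        if min(self.learning_rate, self.w_pos, self.w_neg) < 0 or self.l2_lambda < 0:
            raise ConfigurationError("rates and weights must be non-negative")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("batch_size and max_epochs must be >= 1")
        if not 0.5 < self.early_stop_train_auc <= 1.0:
            raise ConfigurationError("early_stop_train_auc must lie in (0.5, 1]")


@dataclass(frozen=True)
class AugmentSpec:
    flip_prob: float = 0.5
    rot90_max: int = 3               # uniform over {0, .., rot90_max}
    fine_rotation_deg: tuple[float, float] = (0.0, 20.0)
    shift_fraction: float = 0.03     # per-axis shift drawn from [-f, +f]


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    train_auc: float
    val_auc: float
    val_loss: float = float("nan")
    checkpoint: Optional[int] = None  # key into the checkpoint store

    def to_dict(self):
        return {"epoch": self.epoch, "train_loss": self.train_loss,
                "train_auc": self.train_auc, "val_auc": self.val_auc,
                "val_loss": self.val_loss, "checkpoint": self.checkpoint}


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def weighted_bce(probabilities, labels, w_pos: float = 3.7, w_neg: float = 0.7) -> float:
    """Mean of -w(y) * [y log p + (1-y) log(1-p)] with w(1)=w_pos, w(0)=w_neg."""
    p = np.clip(np.asarray(probabilities, dtype=np.float64), PROB_EPS, 1.0 - PROB_EPS)
    y = np.asarray(labels, dtype=np.float64)
    w = np.where(y == 1, w_pos, w_neg)
    return float(np.mean(-w * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(img: np.ndarray, spec: AugmentSpec = AugmentSpec(), rng=None) -> np.ndarray:
    """Flips -> 90-degree rotations -> fine rotation -> shift, zero fill.

    Deterministic given the rng state; output shape equals input shape.
    """
    if rng is None:
        rng = np.random.default_rng()
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ConfigurationError("augment expects a square 2D image")
    if rng.random() < spec.flip_prob:
        img = img[:, ::-1]
    if rng.random() < spec.flip_prob:
        img = img[::-1, :]
    k = int(rng.integers(0, spec.rot90_max + 1))
    if k:
        img = np.rot90(img, k)
    angle = float(rng.uniform(*spec.fine_rotation_deg))
    if angle != 0.0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
    size = img.shape[0]
    max_shift = spec.shift_fraction * size
    dr = int(round(rng.uniform(-max_shift, max_shift)))
    dc = int(round(rng.uniform(-max_shift, max_shift)))
    if dr or dc:
        out = np.zeros_like(img)
        rs, re = max(dr, 0), min(size + dr, size)
        cs, ce = max(dc, 0), min(size + dc, size)
        out[rs:re, cs:ce] = img[rs - dr : re - dr, cs - dc : ce - dc]
        img = out
    return np.ascontiguousarray(img)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_batches(n, batch_size, order):
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _substreams(seed):
    root = np.random.SeedSequence(seed)
    shuffle, aug, drop = root.spawn(3)
    return (np.random.default_rng(shuffle), np.random.default_rng(aug),
            np.random.default_rng(drop))


def _predict(model: ModelHandle, X, clinical, batch_size=64):
    """Clean evaluation pass (no augmentation, dropout off), batched."""
    out = []
    for start in range(0, len(X), batch_size):
        sl = slice(start, start + batch_size)
        clin = None if clinical is None else clinical[sl]
        out.append(model.net.forward_logits(X[sl], clinical=clin, training=False))
    return expit(np.concatenate(out))


def train_model(model: ModelHandle, train_set: dict, val_set: dict, cfg: TrainConfig,
                augment_spec: AugmentSpec = AugmentSpec()):
    """Train ``model`` and return ``(model, logs, checkpoints)``.

    ``train_set``/``val_set`` are dicts with keys ``x`` (images ``(N,1,H,W)``
    for CNNs or feature matrices ``(N,d)``), ``y`` (binary labels) and
    optionally ``clinical`` (fusion input). Checkpoints is a dict mapping
    epoch -> weight list, retained every ``cfg.checkpoint_stride`` epochs
    plus the best-validation epoch seen so far.
    """
    Xtr, ytr = np.asarray(train_set["x"], dtype=np.float32), np.asarray(train_set["y"])
    Xva, yva = np.asarray(val_set["x"], dtype=np.float32), np.asarray(val_set["y"])
    ctr = train_set.get("clinical")
    cva = val_set.get("clinical")
    if len(np.unique(ytr)) < 2 or len(np.unique(yva)) < 2:
        raise TrainingError("both training and validation sets need both classes")

    rng_shuffle, rng_aug, rng_drop = _substreams(cfg.seed)
    is_image = Xtr.ndim == 4
    params = model.net.parameters()
    opt = SGD(params, lr=cfg.learning_rate, momentum=cfg.momentum, l2=cfg.l2_lambda)

    logs: list[EpochLog] = []
    checkpoints: dict[int, list] = {}
    best_val = -np.inf
    n = len(Xtr)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng_shuffle.permutation(n)
        losses = []
        for idx in _as_batches(n, cfg.batch_size, order):
            xb = Xtr[idx]
            if is_image and cfg.augmentation:
                xb = np.stack([augment(im[0], augment_spec, rng_aug) for im in xb])[:, None]
            yb = ytr[idx].astype(np.float64)
            cb = None if ctr is None else ctr[idx]
            logits = model.net.forward_logits(xb, clinical=cb, training=True, rng=rng_drop)
            p = np.clip(expit(logits), PROB_EPS, 1.0 - PROB_EPS)
            w = np.where(yb == 1, cfg.w_pos, cfg.w_neg)
            loss = float(np.mean(-w * (yb * np.log(p) + (1 - yb) * np.log(1 - p))))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            losses.append(loss)
            dlogit = (w * (p - yb) / len(yb)).astype(np.float32)
            model.net.backward(dlogit)
            opt.step()

        p_tr = _predict(model, Xtr, ctr, cfg.batch_size)
        p_va = _predict(model, Xva, cva, cfg.batch_size)
        train_auc = roc_auc(ytr, p_tr)
        val_auc = roc_auc(yva, p_va)
        val_loss = weighted_bce(p_va, yva, cfg.w_pos, cfg.w_neg)

        keep = (epoch % cfg.checkpoint_stride == 0) or (val_auc > best_val)
        if keep:
            checkpoints[epoch] = model.net.get_weights()
        best_val = max(best_val, val_auc)
        logs.append(EpochLog(epoch=epoch, train_loss=float(np.mean(losses)),
                             train_auc=train_auc, val_auc=val_auc, val_loss=val_loss,
                             checkpoint=epoch if keep else None))
        if train_auc > cfg.early_stop_train_auc:
            break

    return model, logs, checkpoints


def restore_epoch(model: ModelHandle, checkpoints: dict, epoch: int) -> ModelHandle:
    """Load the weights of a retained epoch back into the model."""
    if epoch not in checkpoints:
        raise ConfigurationError(f"epoch {epoch} was not retained (stride policy)")
    model.net.set_weights(checkpoints[epoch])
    return model


def logs_to_jsonl(logs: list[EpochLog]) -> str:
    import json

    return "\n".join(json.dumps(log.to_dict(), sort_keys=True) for log in logs) + "\n"
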