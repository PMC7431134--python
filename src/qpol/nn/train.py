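"""Training loop: Adam, L1 (optionally foreground-masked) loss, cyclic
learning rate, early stopping on validation loss with best-checkpoint
restore."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .model import UNet

DEFAULT_BATCH_SIZE = {"2D": 64, "2.5D": 16, "3D": 4}


@dataclass
class TrainingConfig:
    """Optimization hyper-parameters."""

    loss: str = "l1"  # "l1" | "masked_l1"
    lr_min: float = 5e-5
    lr_max: float = 6e-3
    batch_size: int = None  # default depends on the model variant
    patience: int = 20
    max_epochs: int = 500
    half_cycle_epochs: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_min < self.lr_max):
            raise ValueError("require 0 < lr_min < lr_max")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.loss not in ("l1", "masked_l1"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def to_dict(self) -> dict:
        return asdict(self)


class Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def cyclic_lr(epoch: float, lr_min: float, lr_max: float, half_cycle: float) -> float:
    """Triangular schedule bounded by [lr_min, lr_max]."""
    phase = (epoch / half_cycle) % 2.0
    tri = 1.0 - abs(phase - 1.0)
    return lr_min + (lr_max - lr_min) * tri


def _stack_batch(tiles):
    x = np.stack([t.inputs for t in tiles])
    y = np.stack([t.target for t in tiles])
    m = np.stack([t.mask[None] for t in tiles])
    return x, y, m


def _evaluate(model, tiles, cfg, batch_size):
    model.eval()
    total, count = 0.0, 0
    for start in range(0, len(tiles), batch_size):
        x, y, m = _stack_batch(tiles[start : start + batch_size])
        pred = model(ag.Tensor(x))
        mask = m if cfg.loss == "masked_l1" else None
        if mask is not None and not mask.any():
            continue
        loss = ag.l1_loss(pred, y, mask=mask)
        total += float(loss.data) * len(x)
        count += len(x)
    model.train()
    return total / max(count, 1)


def train_model(model: UNet, train_tiles, val_tiles, cfg: TrainingConfig):
    """Train in place; returns a history dict.

    History keys: ``train_loss``, ``val_loss``, ``lr`` (per epoch),
    ``best_epoch``.  The model is left holding the parameters of the
    epoch with minimal validation loss.
    """
    if not train_tiles:
        raise ValueError("empty training set")
    batch_size = cfg.batch_size or DEFAULT_BATCH_SIZE[model.spec.variant]
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters())
    monitor = val_tiles if val_tiles else train_tiles

    history = {"train_loss": [], "val_loss": [], "lr": [], "best_epoch": None}
    best_loss = np.inf
    best_state = model.state_dict()
    since_best = 0
    model.train()

    for epoch in range(cfg.max_epochs):
        lr = cyclic_lr(epoch, cfg.lr_min, cfg.lr_max, cfg.half_cycle_epochs)
        order = rng.permutation(len(train_tiles))
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), batch_size):
            batch = [train_tiles[i] for i in order[start : start + batch_size]]
            x, y, m = _stack_batch(batch)
            mask = m if cfg.loss == "masked_l1" else None
            if mask is not None and not mask.any():
                continue
            model.zero_grad()
            pred = model(ag.Tensor(x))
            loss = ag.l1_loss(pred, y, mask=mask)
            loss.backward()
            optimizer.step(lr)
            epoch_loss += float(loss.data) * len(batch)
            seen += len(batch)
        history["train_loss"].append(epoch_loss / max(seen, 1))
        history["lr"].append(lr)
        val_loss = _evaluate(model, monitor, cfg, batch_size)
        history["val_loss"].append(val_loss)

        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            history["best_epoch"] = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    model.load_state_dict(best_state)
    return history
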