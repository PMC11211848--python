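"""Siamese training of the hash-code network.

Both sequences of every labeled pair pass through the *same* network (one
parameter set, two forward calls), so the pairwise hinge loss can drive a
single gradient update — the Siamese branches stay synchronized by
construction.  Per-epoch training and validation losses are recorded and
the parameters with minimum validation loss are retained.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .losses import LossConfig, hinge_loss_batch
from .lsbnet import InceptionModel, encode_batch
from .seqsim import LabeledPair

__all__ = ["TrainConfig", "TrainingRecord", "AdamState", "siamese_step", "train"]


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    d1: int = 1
    d2: int = 2
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.d1 < self.d2):
            raise ValueError("require 0 < d1 < d2")


@dataclass
class TrainingRecord:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    config: TrainConfig | None = None


class AdamState:
    """Adaptive-moment optimizer state over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * (g * g)
            mhat = self.m[name] / (1 - b1 ** self.t)
            vhat = self.v[name] / (1 - b2 ** self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batch_arrays(pairs: list[LabeledPair], alphabet: str):
    xs = encode_batch([p.s for p in pairs], alphabet)
    xt = encode_batch([p.t for p in pairs], alphabet)
    y = np.array([p.y for p in pairs], dtype=np.float64)
    if np.any(np.abs(y) != 1):
        raise ValueError("all pairs must be labeled (y in {-1, +1})")
    return xs, xt, y


def batch_loss(model: InceptionModel, pairs: list[LabeledPair],
               loss_cfg: LossConfig, chunk: int = 512) -> float:
    """Forward-only loss of a labeled set under the current parameters."""
    sum_cfg = LossConfig(variant=loss_cfg.variant, reduction="sum",
                         theta=loss_cfg.theta)
    total = 0.0
    for start in range(0, len(pairs), chunk):
        part = pairs[start : start + chunk]
        xs, xt, y = _batch_arrays(part, model.config.alphabet)
        gs, _ = model.forward(xs)
        gt, _ = model.forward(xt)
        loss, _, _ = hinge_loss_batch(gs, gt, y, sum_cfg)
        total += loss
    if loss_cfg.reduction == "mean":
        total /= len(pairs)
    return total


def siamese_step(
    model: InceptionModel,
    pairs: list[LabeledPair],
    loss_cfg: LossConfig,
    opt: AdamState,
) -> float:
    """One shared-parameter gradient update on a batch of labeled pairs.

    When the batch loss is exactly zero (all hinge margins satisfied) the
    parameters are left untouched.
    """
    for p in pairs:
        if len(p.s) != model.config.n or len(p.t) != model.config.n:
            raise ValueError("pair length does not match model n")
    xs, xt, y = _batch_arrays(pairs, model.config.alphabet)
    gs, cache_s = model.forward(xs)
    gt, cache_t = model.forward(xt)
    loss, dgs, dgt = hinge_loss_batch(gs, gt, y, loss_cfg)
    if loss == 0.0:
        return 0.0
    grads_s = model.backward(dgs, cache_s)
    grads_t = model.backward(dgt, cache_t)
    grads = {k: grads_s[k] + grads_t[k] for k in grads_s}
    opt.step(model.params, grads)
    return loss


def train(
    model: InceptionModel,
    train_pairs: list[LabeledPair],
    val_pairs: list[LabeledPair],
    config: TrainConfig,
) -> TrainingRecord:
    """Run the full training loop; the model ends at the best-validation epoch.

    Deterministic under a fixed ``config.seed`` (batch shuffling is the only
    source of randomness; parameter initialization is seeded at model
    construction).
    """
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = AdamState(model.params, lr=config.learning_rate)
    record = TrainingRecord(config=config)
    best_params = copy.deepcopy(model.params)
    order = np.arange(len(train_pairs))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_pairs[i] for i in order[start : start + config.batch_size]]
            epoch_loss += siamese_step(model, batch, config.loss, opt)
            n_batches += 1
        record.train_loss.append(epoch_loss / n_batches)
        vloss = batch_loss(model, val_pairs, config.loss)
        record.val_loss.append(vloss)
        if vloss < record.best_val_loss:
            record.best_val_loss = vloss
            record.best_epoch = epoch
            best_params = copy.deepcopy(model.params)
    model.params = best_params
    return record
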