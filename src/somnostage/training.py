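"""Label-smoothed supervised training.

Targets are smoothed one-hot vectors: the true class gets 1 - eps and every
other class eps/(k-1), which keeps the target argmax while discouraging the
over-confident logits that plain one-hot targets reward — useful both
against a small rate of mislabelled epochs and against the heavy S2
imbalance of sleep data.  The loss is mean cross-entropy against these
smoothed rows; with eps = 0 it is exactly standard cross-entropy.

The optimizer is Adam (beta1 0.9, beta2 0.999, eps 1e-8) at learning rate
0.005 with weight-decay ratio 0.1 and batch size 16 by default.  Weight
decay is decoupled from the adaptive step (AdamW-style) by default, because
coupling a 0.1 decay through Adam's preconditioner is degenerate; a flag
restores coupled L2.  Batches are windows of ``sequence_length`` consecutive
epochs; shuffling permutes windows, never epochs within a window.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _engine as E
from .data_io import EpochSet, InvalidConfigError
from .network import SleepStager

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "smooth_labels",
    "cross_entropy",
    "Adam",
    "make_windows",
    "train",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    weight_decay: float = 0.1
    decoupled_weight_decay: bool = True
    batch_size: int = 16
    n_epochs: int = 200          # training passes over the data
    label_smoothing: float = 0.1
    seed: int = 0
    early_stopping_patience: int | None = None   # off by default

    def __post_init__(self):
        if not (0.0 <= self.label_smoothing < 1.0):
            raise InvalidConfigError("label_smoothing must lie in [0, 1)")


def smooth_labels(y: int, k: int, eps: float) -> np.ndarray:
    """Smoothed target row: 1 - eps at the true class, eps/(k-1) elsewhere."""
    if not (0.0 <= eps < 1.0):
        raise InvalidConfigError(f"smoothing mass must lie in [0, 1), got {eps}")
    if k < 2:
        raise InvalidConfigError("need at least 2 classes")
    if not (0 <= y < k):
        raise InvalidConfigError(f"class index {y} outside [0, {k})")
    p = np.full(k, eps / (k - 1), dtype=np.float64)
    p[y] = 1.0 - eps
    return p


def smooth_label_matrix(y: np.ndarray, k: int, eps: float) -> np.ndarray:
    """Vectorised :func:`smooth_labels` for an integer label array."""
    y = np.asarray(y, dtype=np.int64).ravel()
    if not (0.0 <= eps < 1.0):
        raise InvalidConfigError(f"smoothing mass must lie in [0, 1), got {eps}")
    out = np.full((y.size, k), eps / (k - 1), dtype=np.float64)
    out[np.arange(y.size), y] = 1.0 - eps
    return out


def cross_entropy(pred: np.ndarray, target: np.ndarray, eps: float = 1e-12) -> float:
    """Mean cross-entropy H(P, q) between probability rows.

    Both arguments are probability matrices (rows summing to 1); this is the
    numpy-level functional used for evaluation and as the reference for the
    fused softmax loss used in training.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(-(target * np.log(np.clip(pred, eps, None))).sum(axis=-1).mean())


class Adam:
    """Adam with optional decoupled (AdamW-style) weight decay."""

    def __init__(self, params, lr: float = 0.005, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0, decoupled: bool = True):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay, self.decoupled = weight_decay, decoupled
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            g = g.astype(p.data.dtype)
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            update = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and self.decoupled:
                update = update + self.lr * self.weight_decay * p.data
            p.data = p.data - update


def make_windows(es: EpochSet, seq_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping windows of ``seq_len`` consecutive epochs.

    Returns (windows, labels) of shapes (N, L, C, S) and (N, L); a trailing
    partial window is dropped.
    """
    n = len(es) // seq_len
    if n == 0:
        return (np.empty((0, seq_len) + es.data.shape[1:], dtype=np.float32),
                np.empty((0, seq_len), dtype=np.int64))
    data = es.data[:n * seq_len].reshape((n, seq_len) + es.data.shape[1:])
    labels = es.labels[:n * seq_len].reshape(n, seq_len)
    return data, labels


def _run_epoch(model, opt, X, y, cfg, k, training: bool):
    """One pass over windows; returns (mean loss, accuracy)."""
    n = len(X)
    order = np.arange(n)
    losses, correct, total = [], 0, 0
    model.set_training(training)
    bs = cfg.batch_size
    for start in range(0, n, bs):
        idx = order[start:start + bs]
        xb, yb = X[idx], y[idx]
        targets = smooth_label_matrix(yb, k, cfg.label_smoothing)
        if training:
            logits = model(xb)
            flat = E.reshape(logits, (-1, k))
            loss = E.softmax_cross_entropy(flat, targets)
            opt.zero_grad()
            loss.backward()
            opt.step()
            logits_np = logits.data
        else:
            with E.no_grad():
                logits = model(xb)
            logits_np = logits.data
            flat = logits_np.reshape(-1, k)
            z = flat - flat.max(axis=1, keepdims=True)
            logq = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            loss_val = float(-(targets * logq).sum() / len(targets))
            loss = None
        loss_val = float(loss.data) if loss is not None else loss_val
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"non-finite loss ({loss_val}) at step {start // bs}; aborting")
        losses.append(loss_val * len(idx))
        pred = logits_np.argmax(axis=-1)
        correct += int((pred == yb).sum())
        total += int(yb.size)
    return float(np.sum(losses) / n), correct / max(total, 1)


def train(model: SleepStager, train_set: EpochSet, val_set: EpochSet,
          cfg: TrainConfig, shuffle: bool = True) -> dict:
    """Train a model; returns {"history": [...], "best_state": state_dict}.

    History records per pass: train_loss, train_acc, val_loss, val_acc.  The
    state with the best validation accuracy is retained and loaded back into
    the model on return.  Fully deterministic under ``cfg.seed``.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    k = model.cfg.n_classes
    L = model.cfg.sequence_length
    Xtr, ytr = make_windows(train_set, L)
    Xva, yva = make_windows(val_set, L)
    if len(Xtr) == 0:
        raise ValueError(f"training set too short to build {L}-epoch windows")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1,
               beta2=cfg.beta2, eps=cfg.adam_eps, weight_decay=cfg.weight_decay,
               decoupled=cfg.decoupled_weight_decay)
    history = []
    best_acc, best_state, since_best = -1.0, None, 0
    for ep in range(cfg.n_epochs):
        if shuffle:
            perm = rng.permutation(len(Xtr))
            Xtr, ytr = Xtr[perm], ytr[perm]
        tr_loss, tr_acc = _run_epoch(model, opt, Xtr, ytr, cfg, k, training=True)
        if len(Xva):
            va_loss, va_acc = _run_epoch(model, None, Xva, yva, cfg, k, training=False)
        else:
            va_loss, va_acc = float("nan"), float("nan")
        history.append({"pass": ep, "train_loss": tr_loss, "train_acc": tr_acc,
                        "val_loss": va_loss, "val_acc": va_acc})
        logger.info("pass %d: train loss %.4f acc %.3f | val loss %.4f acc %.3f",
                    ep, tr_loss, tr_acc, va_loss, va_acc)
        score = va_acc if len(Xva) else tr_acc
        if score > best_acc:
            best_acc, best_state, since_best = score, copy.deepcopy(model.state_dict()), 0
        else:
            since_best += 1
            if (cfg.early_stopping_patience is not None
                    and since_best >= cfg.early_stopping_patience):
                logger.info("early stopping after pass %d", ep)
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.set_training(False)
    return {"history": history, "best_state": best_state}
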