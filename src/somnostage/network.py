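"""The multi-scale attention residual network with BiGRU sequence head.

Architecture, front to back:

* a shared stem — width-7 convolution (stride 2), batch norm, activation,
  width-3 max pool (stride 2);
* three parallel branches identical except for their convolution kernel
  width (3 / 5 / 7).  Each branch is a stack of residual
  spatial-channel-attention blocks (RSCAM) at widths 64/128/256/512, one
  stride-2 downsampling per stage, finished with global average pooling to a
  512-vector.  An RSCAM is a two-convolution residual block whose branch
  output is reweighted by a channel attention unit (dual-pooled descriptors
  through a shared MLP and sigmoid) then a spatial attention unit (a width-7
  convolution over the channel-mean/max map and sigmoid), before the
  shortcut addition;
* the three 512-vectors are concatenated into a 1536-wide fused feature per
  epoch;
* a bidirectional GRU consumes the sequence of fused vectors over
  consecutive epochs (per-step output is the concatenation of forward and
  backward states) and a dropout + dense head produces 5-class logits per
  epoch.

Residual identities hold exactly: a zero branch makes the block the
identity, and zero attention pre-activations gate uniformly at sigmoid(0) =
0.5.
"""

from __future__ import annotations

import io
import json
import math
import zipfile
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _engine as E
from ._engine import Module, Parameter, Tensor
from .data_io import InvalidConfigError

__all__ = [
    "ModelConfig",
    "ChannelAttention",
    "SpatialAttention",
    "ResidualBlock",
    "rscam_block",
    "BranchEncoder",
    "MultiScaleEncoder",
    "GRUCell",
    "BiGRU",
    "SleepStager",
    "build_model",
    "classify_sequence",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """All architecture hyperparameters.

    Defaults follow the full-size recipe: parallel kernel widths 3/5/7,
    stage widths 64/128/256/512 (each branch emits a 512-vector after global
    average pooling, fused to 3x512 = 1536), BiGRU hidden size 128 per
    direction over sequences of 10 consecutive epochs, dropout 0.5, ReLU
    activation inside the blocks (a SELU switch is provided).
    """

    in_channels: int = 1
    fs: float = 100.0
    epoch_samples: int = 3000
    branch_kernel_sizes: tuple[int, ...] = (3, 5, 7)
    stem_kernel: int = 7
    stem_pool: int = 3
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: int = 1
    attention_reduction: int = 16
    bigru_hidden: int = 128
    dropout_p: float = 0.5
    sequence_length: int = 10
    n_classes: int = 5
    activation: str = "relu"

    def __post_init__(self):
        self.branch_kernel_sizes = tuple(self.branch_kernel_sizes)
        self.stage_widths = tuple(self.stage_widths)
        if self.activation not in ("relu", "selu"):
            raise InvalidConfigError("activation must be 'relu' or 'selu'")

    @property
    def fused_dim(self) -> int:
        return len(self.branch_kernel_sizes) * self.stage_widths[-1]


def _act(name: str):
    return E.relu if name == "relu" else E.selu


# ---------------------------------------------------------------------------
# attention units
# ---------------------------------------------------------------------------

class ChannelAttention(Module):
    """Channel attention: sigmoid(MLP(avgpool) + MLP(maxpool)) per channel.

    Descriptors are temporal average and max per channel; the two pooled
    vectors pass through one shared bottleneck MLP (hidden width
    ceil(C/r), floor 1) and their sum is squashed to (0, 1) gates.
    """

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, math.ceil(channels / reduction))
        self.fc1 = E.Linear(channels, hidden, bias=False, rng=rng)
        self.fc2 = E.Linear(hidden, channels, bias=False, rng=rng)
        self.bypass = False  # force unit gates (for equivalence checks)

    def weights(self, x: Tensor) -> Tensor:
        xavg = E.mean(x, axis=2)          # (B, C)
        xmax = E.amax(x, axis=2)
        s = self.fc2(E.relu(self.fc1(xavg))) + self.fc2(E.relu(self.fc1(xmax)))
        return E.sigmoid(s)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        if self.bypass:
            return Tensor(np.ones(x.shape[:2], dtype=x.dtype)), x
        m = self.weights(x)
        B, C = m.shape
        return m, E.mul(x, E.reshape(m, (B, C, 1)))


class SpatialAttention(Module):
    """Spatial attention: sigmoid(conv_width7([channel-avg; channel-max]))."""

    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = E.Conv1d(2, 1, kernel, padding=kernel // 2, bias=True, rng=rng)
        self.bypass = False

    def weights(self, x: Tensor) -> Tensor:
        lavg = E.mean(x, axis=1, keepdims=True)   # (B, 1, T)
        lmax = E.amax(x, axis=1, keepdims=True)
        m = E.sigmoid(self.conv(E.concat([lavg, lmax], axis=1)))
        return m                                   # (B, 1, T)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        if self.bypass:
            return Tensor(np.ones((x.shape[0], 1, x.shape[2]), dtype=x.dtype)), x
        m = self.weights(x)
        return m, E.mul(x, m)


# ---------------------------------------------------------------------------
# residual blocks
# ---------------------------------------------------------------------------

class ResidualBlock(Module):
    """conv-BN-act -> conv-BN (optionally attended) + shortcut, then act.

    The shortcut is the identity when shapes match, otherwise a 1x1
    strided projection with its own batch norm.  With ``channel_attention``
    and ``spatial_attention`` attached this is the RSCAM block: the branch
    output is gated by channel then spatial attention before the addition.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, activation: str = "relu",
                 attention: bool = False, reduction: int = 16,
                 affine_bn: bool = True, post_activation: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.post_activation = post_activation
        pad = kernel // 2
        self.conv1 = E.Conv1d(in_channels, out_channels, kernel, stride=stride,
                              padding=pad, bias=False, rng=rng)
        self.bn1 = E.BatchNorm1d(out_channels, affine=affine_bn)
        self.conv2 = E.Conv1d(out_channels, out_channels, kernel, stride=1,
                              padding=pad, bias=False, rng=rng)
        self.bn2 = E.BatchNorm1d(out_channels, affine=affine_bn)
        self.act_name = activation
        self.cau = ChannelAttention(out_channels, reduction, rng=rng) if attention else None
        self.sau = SpatialAttention(rng=rng) if attention else None
        if stride != 1 or in_channels != out_channels:
            self.proj = E.Conv1d(in_channels, out_channels, 1, stride=stride,
                                 padding=0, bias=False, rng=rng)
            self.bn_proj = E.BatchNorm1d(out_channels, affine=affine_bn)
        else:
            self.proj = None

    def set_attention_bypass(self, flag: bool) -> None:
        if self.cau is not None:
            self.cau.bypass = flag
            self.sau.bypass = flag

    def branch(self, x: Tensor) -> Tensor:
        act = _act(self.act_name)
        h = act(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        if self.cau is not None:
            _, h = self.cau(h)
            _, h = self.sau(h)
        return h

    def shortcut(self, x: Tensor) -> Tensor:
        if self.proj is None:
            return x
        return self.bn_proj(self.proj(x))

    def forward(self, x: Tensor) -> Tensor:
        h = self.branch(x)
        s = self.shortcut(x)
        if h.shape != s.shape:
            raise InvalidConfigError(
                f"residual shapes differ ({h.shape} vs {s.shape}) and no projection configured")
        out = h + s
        return _act(self.act_name)(out) if self.post_activation else out


def rscam_block(in_channels: int, out_channels: int, kernel: int,
                stride: int = 1, activation: str = "relu", reduction: int = 16,
                rng: np.random.Generator | None = None) -> ResidualBlock:
    """Residual spatial-channel attention block (attention enabled)."""
    return ResidualBlock(in_channels, out_channels, kernel, stride=stride,
                         activation=activation, attention=True,
                         reduction=reduction, rng=rng)


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

def _conv_out_len(t: int, kernel: int, stride: int, padding: int) -> int:
    return (t + 2 * padding - kernel) // stride + 1


class BranchEncoder(Module):
    """One kernel-width branch: stacked RSCAM stages + global average pool."""

    def __init__(self, cfg: ModelConfig, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.blocks: list[ResidualBlock] = []
        c_in = cfg.stage_widths[0]
        for width in cfg.stage_widths:
            for b in range(cfg.blocks_per_stage):
                stride = 2 if b == 0 else 1
                self.blocks.append(rscam_block(c_in, width, kernel, stride=stride,
                                               activation=cfg.activation,
                                               reduction=cfg.attention_reduction,
                                               rng=rng))
                c_in = width

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return E.mean(x, axis=2)   # global average pooling -> (B, width)


class MultiScaleEncoder(Module):
    """Shared stem feeding the three kernel-width branches; outputs the
    concatenated per-scale vectors (B, 3*512 by default)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        w0 = cfg.stage_widths[0]
        self.stem_conv = E.Conv1d(cfg.in_channels, w0, cfg.stem_kernel, stride=2,
                                  padding=cfg.stem_kernel // 2, bias=False, rng=rng)
        self.stem_bn = E.BatchNorm1d(w0)
        self.branches = [BranchEncoder(cfg, k, rng) for k in cfg.branch_kernel_sizes]
        min_len = self._min_epoch_samples()
        if cfg.epoch_samples < min_len:
            raise InvalidConfigError(
                f"epoch_samples={cfg.epoch_samples} too short for the downsampling "
                f"chain; minimum supported length is {min_len}")

    def _min_epoch_samples(self) -> int:
        # every stride-2 step (stem conv, stem pool, one per stage) must see
        # at least one real sample, i.e. 2^(2 + n_stages) input samples;
        # shorter inputs would convolve over padding only
        return 2 ** (2 + len(self.cfg.stage_widths))

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        act = _act(cfg.activation)
        h = act(self.stem_bn(self.stem_conv(x)))
        h = E.max_pool1d(h, cfg.stem_pool, stride=2, padding=cfg.stem_pool // 2)
        feats = [branch(h) for branch in self.branches]
        return E.concat(feats, axis=1)


# ---------------------------------------------------------------------------
# recurrent head
# ---------------------------------------------------------------------------

class GRUCell(Module):
    """Gated recurrent unit: reset/update sigmoid gates, tanh candidate,
    convex state update h_t = (1 - z_t) h_{t-1} + z_t h~_t."""

    def __init__(self, input_dim: int, hidden: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.hidden = hidden
        bound = math.sqrt(1.0 / hidden)

        def w(shape):
            return Parameter(rng.uniform(-bound, bound, shape).astype(np.float32))

        self.W_r, self.U_r = w((input_dim, hidden)), w((hidden, hidden))
        self.W_z, self.U_z = w((input_dim, hidden)), w((hidden, hidden))
        self.W_h, self.U_h = w((input_dim, hidden)), w((hidden, hidden))
        self.b_r = Parameter(np.zeros(hidden, dtype=np.float32))
        self.b_z = Parameter(np.zeros(hidden, dtype=np.float32))
        self.b_h = Parameter(np.zeros(hidden, dtype=np.float32))

    def step(self, x_t: Tensor, h_prev: Tensor) -> Tensor:
        r = E.sigmoid(x_t @ self.W_r + h_prev @ self.U_r + self.b_r)
        z = E.sigmoid(x_t @ self.W_z + h_prev @ self.U_z + self.b_z)
        h_cand = E.tanh(x_t @ self.W_h + E.mul(r, h_prev) @ self.U_h + self.b_h)
        return E.mul(1.0 - z, h_prev) + E.mul(z, h_cand)

    forward = step

    def scan(self, seq: list[Tensor]) -> list[Tensor]:
        batch = seq[0].shape[0]
        h = Tensor(np.zeros((batch, self.hidden), dtype=seq[0].dtype))
        out = []
        for x_t in seq:
            h = self.step(x_t, h)
            out.append(h)
        return out


class BiGRU(Module):
    """Two independent GRUs scanning in opposite directions; the per-step
    output is the concatenation of the forward and backward states (2H)."""

    def __init__(self, input_dim: int, hidden: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.forward_cell = GRUCell(input_dim, hidden, rng=rng)
        self.backward_cell = GRUCell(input_dim, hidden, rng=rng)

    def forward(self, seq: list[Tensor]) -> list[Tensor]:
        if len(seq) == 0:
            raise ValueError("BiGRU requires a non-empty sequence")
        fwd = self.forward_cell.scan(seq)
        bwd = self.backward_cell.scan(list(reversed(seq)))[::-1]
        return [E.concat([f, b], axis=1) for f, b in zip(fwd, bwd)]


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class SleepStager(Module):
    """Epoch encoder + BiGRU + dropout + dense head over epoch sequences."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.cfg = cfg
        self.encoder = MultiScaleEncoder(cfg, rng=rng)
        self.bigru = BiGRU(cfg.fused_dim, cfg.bigru_hidden, rng=rng)
        self.dropout = E.Dropout(cfg.dropout_p,
                                 rng=np.random.default_rng(np.random.SeedSequence(seed + 1)))
        self.head = E.Linear(2 * cfg.bigru_hidden, cfg.n_classes, rng=rng)

    def forward(self, windows) -> Tensor:
        """windows: (B, L, C, S) array or Tensor -> logits (B, L, n_classes)."""
        x = windows if isinstance(windows, Tensor) else Tensor(np.asarray(windows, dtype=np.float32))
        if x.ndim != 4:
            raise InvalidConfigError("expected (batch, sequence, channels, samples)")
        B, L, C, S = x.shape
        if L != self.cfg.sequence_length:
            raise InvalidConfigError(
                f"window length {L} != configured sequence_length {self.cfg.sequence_length}")
        feats = self.encoder(E.reshape(x, (B * L, C, S)))          # (B*L, F)
        feats = E.reshape(feats, (B, L, feats.shape[1]))
        seq = [E.reshape(E.narrow(feats, 1, t, 1), (B, feats.shape[2])) for t in range(L)]
        outs = self.bigru(seq)                                      # L x (B, 2H)
        logits = [E.reshape(self.head(self.dropout(z)), (B, 1, self.cfg.n_classes))
                  for z in outs]
        return E.concat(logits, axis=1)                             # (B, L, k)


def build_model(cfg: ModelConfig, seed: int = 0) -> SleepStager:
    return SleepStager(cfg, seed=seed)


def classify_sequence(model: SleepStager, windows: np.ndarray) -> np.ndarray:
    """Per-epoch class probabilities for windows of L_seq epochs.

    Runs in evaluation mode (dropout off, batch-norm running statistics);
    rows sum to 1.
    """
    was_training = model.training
    model.set_training(False)
    try:
        with E.no_grad():
            logits = model(windows).data
    finally:
        model.set_training(was_training)
    return E.softmax(logits, axis=-1)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SleepStager, path: str | Path) -> None:
    """Single-archive checkpoint: model config JSON + parameter arrays."""
    path = Path(path)
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION,
            "model_config": asdict(model.cfg)}
    buf = io.BytesIO()
    np.savez(buf, **model.state_dict())
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(meta, indent=2, sort_keys=True))
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> SleepStager:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('format_version')}")
        with np.load(io.BytesIO(zf.read("weights.npz"))) as npz:
            state = {k: npz[k] for k in npz.files}
    cfg = ModelConfig(**meta["model_config"])
    model = SleepStager(cfg, seed=0)
    model.load_state_dict(state)
    return model
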