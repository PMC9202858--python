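"""Architectural identities and contracts of the staging network."""

from __future__ import annotations

import numpy as np
import pytest

import somnostage as ss
from somnostage import _engine as E
from somnostage.data_io import InvalidConfigError
from somnostage.network import (
    BiGRU,
    ChannelAttention,
    GRUCell,
    ModelConfig,
    ResidualBlock,
    SleepStager,
    SpatialAttention,
    classify_sequence,
    load_checkpoint,
    rscam_block,
    save_checkpoint,
)

RNG = np.random.default_rng(2024)


def _zero_branch(block):
    block.conv1.weight.data[:] = 0
    block.conv2.weight.data[:] = 0
    block.set_training(False)   # running stats: mean 0, var 1 -> BN(0) = 0


# ---------------------------------------------------------------------------
# residual blocks
# ---------------------------------------------------------------------------

def test_zero_branch_block_is_identity_on_nonnegative_input():
    """With a zero residual branch the block reduces to its shortcut; on the
    non-negative activations it receives in-network this is exact identity."""
    block = ResidualBlock(4, 4, 3, rng=np.random.default_rng(0))
    _zero_branch(block)
    x = np.maximum(RNG.normal(size=(2, 4, 16)), 0).astype(np.float64)
    out = block(E.Tensor(x)).data
    np.testing.assert_allclose(out, x, atol=1e-12)


def test_projection_shortcut_changes_channels():
    block = ResidualBlock(64, 128, 3, stride=2, rng=np.random.default_rng(0))
    out = block(E.Tensor(RNG.normal(size=(2, 64, 32)).astype(np.float32)))
    assert out.shape == (2, 128, 16)
    # matching dims use the identity shortcut, no projection parameters
    plain = ResidualBlock(64, 64, 3, rng=np.random.default_rng(0))
    assert plain.proj is None and block.proj is not None


def test_residual_recursion_deep_feature_equals_shallow_plus_branch_sum():
    """Composing identity-shortcut blocks (no outer nonlinearity) equals the
    shallow feature plus the explicitly accumulated branch outputs."""
    rng = np.random.default_rng(5)
    blocks = [ResidualBlock(3, 3, 3, post_activation=False, rng=rng) for _ in range(3)]
    for b in blocks:
        b.set_training(False)
        # give running stats non-trivial values so BN is not a no-op
        b.bn1.running_mean = rng.normal(size=3).astype(np.float32)
        b.bn1.running_var = (0.5 + rng.random(3)).astype(np.float32)
    x = E.Tensor(RNG.normal(size=(2, 3, 12)).astype(np.float32))
    out = x
    for b in blocks:
        out = b(out)
    acc = x.data.copy()
    for b in blocks:
        acc = acc + b.branch(E.Tensor(acc)).data
    np.testing.assert_allclose(out.data, acc, rtol=1e-5, atol=1e-6)


# ---------------------------------------------------------------------------
# attention units
# ---------------------------------------------------------------------------

def test_channel_attention_zero_weights_gate_at_half():
    cau = ChannelAttention(4, reduction=2, rng=np.random.default_rng(0))
    cau.fc1.weight.data[:] = 0
    cau.fc2.weight.data[:] = 0
    x = RNG.normal(size=(2, 4, 10))
    m, out = cau(E.Tensor(x))
    np.testing.assert_allclose(m.data, 0.5)
    np.testing.assert_allclose(out.data, 0.5 * x)


def test_channel_attention_constant_signal_pools_agree():
    """If each channel is constant in time, avg and max descriptors agree and
    the gate is sigmoid(2 * MLP(x_avg))."""
    cau = ChannelAttention(3, reduction=1, rng=np.random.default_rng(1))
    x = np.repeat(RNG.normal(size=(2, 3, 1)), 8, axis=2)
    m, _ = cau(E.Tensor(x))
    xavg = E.Tensor(x.mean(axis=2))
    single = cau.fc2(E.relu(cau.fc1(xavg))).data
    np.testing.assert_allclose(m.data, 1 / (1 + np.exp(-2 * single)), rtol=1e-6)


def test_channel_attention_hand_case():
    """C=2, T=2, X=[[1,3],[2,2]], identity MLP: gates sigmoid([5, 4])."""
    cau = ChannelAttention(2, reduction=1, rng=np.random.default_rng(0))
    cau.fc1.weight.data = np.eye(2, dtype=np.float32)
    cau.fc2.weight.data = np.eye(2, dtype=np.float32)
    x = np.array([[[1.0, 3.0], [2.0, 2.0]]])
    m, _ = cau(E.Tensor(x))
    np.testing.assert_allclose(m.data[0], [0.99331, 0.98201], atol=1e-5)


def test_spatial_attention_zero_weights_gate_at_half():
    sau = SpatialAttention(rng=np.random.default_rng(0))
    sau.conv.weight.data[:] = 0
    sau.conv.bias.data[:] = 0
    x = RNG.normal(size=(3, 5, 11))
    m, out = sau(E.Tensor(x))
    np.testing.assert_allclose(m.data, 0.5)
    np.testing.assert_allclose(out.data, 0.5 * x)
    assert out.shape == x.shape


def test_spatial_attention_hand_case():
    """T=1, C=2, L=[[4],[0]], all-ones width-7 kernel: gate sigmoid(6)."""
    sau = SpatialAttention(rng=np.random.default_rng(0))
    sau.conv.weight.data = np.ones_like(sau.conv.weight.data)
    sau.conv.bias.data[:] = 0
    x = np.array([[[4.0], [0.0]]])
    m, _ = sau(E.Tensor(x))
    assert m.data.shape == (1, 1, 1)
    np.testing.assert_allclose(m.data.ravel(), [0.99753], atol=1e-5)


def test_attention_gates_strictly_inside_unit_interval():
    cau = ChannelAttention(8, rng=np.random.default_rng(3))
    sau = SpatialAttention(rng=np.random.default_rng(4))
    x = E.Tensor(RNG.normal(size=(2, 8, 20)).astype(np.float32))
    mc, _ = cau(x)
    msx, _ = sau(x)
    for m in (mc.data, msx.data):
        assert (m > 0).all() and (m < 1).all()


# ---------------------------------------------------------------------------
# RSCAM
# ---------------------------------------------------------------------------

def test_rscam_zero_branch_reduces_to_shortcut():
    block = rscam_block(4, 4, 5, rng=np.random.default_rng(0))
    _zero_branch(block)
    x = np.maximum(RNG.normal(size=(2, 4, 16)), 0)
    np.testing.assert_allclose(block(E.Tensor(x)).data, x, atol=1e-12)


def test_rscam_bypass_equals_plain_residual_block():
    rng = np.random.default_rng(6)
    attended = rscam_block(3, 6, 3, stride=2, rng=rng)
    plain = ResidualBlock(3, 6, 3, stride=2, rng=np.random.default_rng(0))
    for name in ("conv1", "conv2", "proj"):
        getattr(plain, name).weight.data = getattr(attended, name).weight.data.copy()
    attended.set_training(False)
    plain.set_training(False)
    attended.set_attention_bypass(True)
    x = E.Tensor(RNG.normal(size=(2, 3, 20)).astype(np.float32))
    np.testing.assert_allclose(attended(x).data, plain(x).data, rtol=1e-6)
    attended.set_attention_bypass(False)
    assert np.any(np.abs(attended(x).data - plain(x).data) > 1e-6)


def test_rscam_output_shape_matches_plain_block():
    att = rscam_block(4, 8, 7, stride=2, rng=np.random.default_rng(0))
    plain = ResidualBlock(4, 8, 7, stride=2, rng=np.random.default_rng(1))
    x = E.Tensor(RNG.normal(size=(3, 4, 30)).astype(np.float32))
    assert att(x).shape == plain(x).shape


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

def test_encoder_too_short_epoch_reports_minimum():
    with pytest.raises(InvalidConfigError, match="minimum"):
        ss.build_model(ModelConfig(epoch_samples=16,
                                   stage_widths=(4, 4, 4, 4), bigru_hidden=4))


def test_encoder_batching_contract(tiny_night):
    cfg = ModelConfig(stage_widths=(4, 8, 8, 16), bigru_hidden=8, sequence_length=5)
    model = ss.build_model(cfg, seed=0)
    x = E.Tensor(tiny_night.data[:4])
    with E.no_grad():
        feats = model.encoder(x)
    assert feats.shape == (4, 3 * 16)


def test_batch_permutation_equivariance(tiny_night):
    cfg = ModelConfig(stage_widths=(4, 8, 8, 16), bigru_hidden=8, sequence_length=5)
    model = ss.build_model(cfg, seed=0)
    windows = tiny_night.data[:20].reshape(4, 5, 1, 3000)
    probs = classify_sequence(model, windows)
    perm = np.array([2, 0, 3, 1])
    probs_perm = classify_sequence(model, windows[perm])
    np.testing.assert_allclose(probs_perm, probs[perm], rtol=1e-5, atol=1e-7)


# ---------------------------------------------------------------------------
# GRU / BiGRU
# ---------------------------------------------------------------------------

def test_gru_gate_limits():
    cell = GRUCell(2, 3, rng=np.random.default_rng(0))
    x = E.Tensor(RNG.normal(size=(2, 2)).astype(np.float32))
    h = E.Tensor(RNG.normal(size=(2, 3)).astype(np.float32))
    cell.b_z.data[:] = 30.0    # z -> 1: state jumps to the candidate
    h_new = cell.step(x, h).data
    r = 1 / (1 + np.exp(-(x.data @ cell.W_r.data + h.data @ cell.U_r.data + cell.b_r.data)))
    cand = np.tanh(x.data @ cell.W_h.data + (r * h.data) @ cell.U_h.data + cell.b_h.data)
    np.testing.assert_allclose(h_new, cand, atol=1e-5)
    cell.b_z.data[:] = -30.0   # z -> 0: state carried through unchanged
    np.testing.assert_allclose(cell.step(x, h).data, h.data, atol=1e-5)


def test_gru_scalar_hand_case():
    """H=1, x=1, h=0.5, all weights 1, no biases.

    r = z = sigmoid(1.5) = 0.81757; candidate tanh(1 + 0.40879) = 0.88724;
    h_t = (1 - z) * 0.5 + z * 0.88724 = 0.81659.
    """
    cell = GRUCell(1, 1, rng=np.random.default_rng(0))
    for p in (cell.W_r, cell.U_r, cell.W_z, cell.U_z, cell.W_h, cell.U_h):
        p.data[:] = 1.0
    h_new = cell.step(E.Tensor([[1.0]]), E.Tensor([[0.5]])).data
    np.testing.assert_allclose(h_new, [[0.8165945]], atol=1e-5)


def test_gru_state_bounded_in_tanh_range():
    cell = GRUCell(4, 6, rng=np.random.default_rng(1))
    h = E.Tensor(np.zeros((3, 6)))
    for _ in range(20):
        h = cell.step(E.Tensor(RNG.normal(size=(3, 4))), h)
        assert (np.abs(h.data) < 1.0).all()


def test_bigru_symmetry_and_reversal():
    rng = np.random.default_rng(2)
    bigru = BiGRU(3, 4, rng=rng)
    # share parameters between directions
    bigru.backward_cell.load_state_dict(bigru.forward_cell.state_dict())
    seq_np = [RNG.normal(size=(2, 3)) for _ in range(4)]
    outs = [z.data for z in bigru([E.Tensor(s) for s in seq_np])]
    # single step: forward and backward states coincide
    single = bigru([E.Tensor(seq_np[0])])[0].data
    np.testing.assert_allclose(single[:, :4], single[:, 4:], atol=1e-7)
    # reversing the input swaps the two output streams, time-reversed
    outs_rev = [z.data for z in bigru([E.Tensor(s) for s in reversed(seq_np)])]
    for t in range(4):
        np.testing.assert_allclose(outs_rev[t][:, :4], outs[3 - t][:, 4:], atol=1e-7)
        np.testing.assert_allclose(outs_rev[t][:, 4:], outs[3 - t][:, :4], atol=1e-7)
    assert outs[0].shape == (2, 8)


def test_bigru_empty_sequence_rejected():
    with pytest.raises(ValueError):
        BiGRU(2, 2, rng=np.random.default_rng(0))([])


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

def test_classify_sequence_probability_contract(tiny_night):
    cfg = ModelConfig(stage_widths=(4, 8, 8, 16), bigru_hidden=8, sequence_length=5)
    model = ss.build_model(cfg, seed=0)
    windows = tiny_night.data[:10].reshape(2, 5, 1, 3000)
    probs = classify_sequence(model, windows)
    assert probs.shape == (2, 5, 5)
    np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
    assert (probs >= 0).all()
    assert set(np.unique(probs.argmax(axis=-1))) <= {0, 1, 2, 3, 4}


def test_wrong_window_length_rejected(tiny_night):
    cfg = ModelConfig(stage_widths=(4, 8, 8, 16), bigru_hidden=8, sequence_length=5)
    model = ss.build_model(cfg, seed=0)
    with pytest.raises(InvalidConfigError):
        model(tiny_night.data[:8].reshape(2, 4, 1, 3000))


def test_every_parameter_receives_gradient():
    """End-to-end gradient flow with attention enabled."""
    cfg = ModelConfig(epoch_samples=512, stage_widths=(4, 4, 8, 8),
                      attention_reduction=2, bigru_hidden=4,
                      sequence_length=2, dropout_p=0.0)
    model = SleepStager(cfg, seed=1)
    x = RNG.normal(size=(2, 2, 1, 512)).astype(np.float32)
    logits = model(x)
    targets = np.full((4, 5), 0.2)
    loss = E.softmax_cross_entropy(E.reshape(logits, (-1, 5)), targets)
    loss.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None and np.any(p.grad != 0), f"dead parameter {name}"


def test_checkpoint_roundtrip(tmp_path, tiny_night):
    cfg = ModelConfig(stage_widths=(4, 8, 8, 16), bigru_hidden=8, sequence_length=5)
    model = ss.build_model(cfg, seed=3)
    windows = tiny_night.data[:5].reshape(1, 5, 1, 3000)
    before = classify_sequence(model, windows)
    path = tmp_path / "model.zip"
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    after = classify_sequence(restored, windows)
    np.testing.assert_allclose(after, before, rtol=1e-6)
    assert restored.cfg == model.cfg
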