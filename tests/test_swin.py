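"""Window attention model: oracles, masks, shapes, gradients, checkpoints."""

import numpy as np
import pytest

from swinbeat.nn import Adam, cross_entropy, softmax
from swinbeat.swin import (
    ModelConfig,
    PatchMerging,
    SwinBlock,
    SwinNet,
    WindowAttention,
    build_shift_mask,
    flops_msa,
    flops_wmsa,
    patch_partition,
    patch_unpartition,
    scaled_dot_attention,
    shift_region_ids,
    sw_msa,
    w_msa,
    window_partition,
    window_reverse,
)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def naive_window_attention(xw, attn, labels=None):
    """Loop-based per-head attention inside one window (reference path)."""
    N, C = xw.shape
    h, hd = attn.num_heads, C // attn.num_heads
    qkv = xw @ attn.qkv.W.value + attn.qkv.b.value
    bias = (attn.rel_bias.value[attn._bias_index]
            if attn.rel_bias is not None else np.zeros((N, N, h)))
    out = np.zeros((N, C))
    for head in range(h):
        q = qkv[:, head * hd:(head + 1) * hd]
        k = qkv[:, C + head * hd:C + (head + 1) * hd]
        v = qkv[:, 2 * C + head * hd:2 * C + (head + 1) * hd]
        S = q @ k.T / np.sqrt(hd) + bias[:, :, head]
        if labels is not None:
            S = np.where(labels[:, None] != labels[None, :], -np.inf, S)
        P = np.exp(S - S.max(axis=1, keepdims=True))
        P /= P.sum(axis=1, keepdims=True)
        out[:, head * hd:(head + 1) * hd] = P @ v
    return out @ attn.proj.W.value + attn.proj.b.value


# ---------------------------------------------------------------------------
# Plumbing
# ---------------------------------------------------------------------------

def test_patch_partition_dims_and_roundtrip(rng):
    img = rng.random((224, 224, 3))
    t = patch_partition(img, 4)
    assert t.shape == (56, 56, 48)
    small = patch_partition(rng.random((8, 8, 3)), 4)
    assert small.shape == (2, 2, 48)
    np.testing.assert_allclose(patch_unpartition(t, 4), img)
    with pytest.raises(ValueError):
        patch_partition(rng.random((10, 10, 3)), 4)


def test_window_partition_counts_and_roundtrip(rng):
    g = rng.random((1, 56, 56, 8))
    wins = window_partition(g, 7)
    assert wins.shape == (64, 49, 8)
    np.testing.assert_array_equal(window_reverse(wins, 7, 56, 56), g)
    single = window_partition(rng.random((1, 7, 7, 4)), 7)
    assert single.shape == (1, 49, 4)
    with pytest.raises(ValueError):
        window_partition(g, 5)


def test_scaled_dot_attention_degenerate_cases(rng):
    # single token: softmax of a scalar is 1 -> output equals V
    q = rng.standard_normal((1, 3))
    v = rng.standard_normal((1, 3))
    np.testing.assert_allclose(scaled_dot_attention(q, q, v), v, atol=1e-12)
    # identical keys -> uniform weights -> column mean of V
    Q = rng.standard_normal((4, 2))
    K = np.tile(rng.standard_normal(2), (4, 1))
    V = rng.standard_normal((4, 2))
    np.testing.assert_allclose(scaled_dot_attention(Q, K, V),
                               np.tile(V.mean(axis=0), (4, 1)), atol=1e-10)
    # random tokens vs explicit loop
    Q, K, V = (rng.standard_normal((3, 2)) for _ in range(3))
    S = Q @ K.T / np.sqrt(2)
    P = np.exp(S - S.max(1, keepdims=True))
    P /= P.sum(1, keepdims=True)
    np.testing.assert_allclose(scaled_dot_attention(Q, K, V), P @ V, atol=1e-6)
    with pytest.raises(ValueError):
        scaled_dot_attention(np.zeros((2, 0)), np.zeros((2, 0)), V)


# ---------------------------------------------------------------------------
# W-MSA / SW-MSA vs oracles
# ---------------------------------------------------------------------------

def test_wmsa_equals_perwindow_oracle(rng):
    C, heads, M = 8, 2, 2
    attn = WindowAttention(C, heads, M, np.random.default_rng(1))
    x = rng.standard_normal((2, 4, 4, C)).astype(np.float32)
    out = w_msa(x, attn, M)
    wins = window_partition(x, M)
    ref = window_reverse(
        np.stack([naive_window_attention(w, attn) for w in wins]), M, 4, 4)
    assert np.max(np.abs(out - ref)) < 1e-6


def test_wmsa_locality(rng):
    C, M = 8, 2
    attn = WindowAttention(C, 2, M, np.random.default_rng(2))
    x = rng.standard_normal((1, 4, 4, C)).astype(np.float32)
    base = w_msa(x, attn, M)
    x2 = x.copy()
    x2[0, 0, 0] += 5.0  # perturb window (0,0)
    pert = w_msa(x2, attn, M)
    np.testing.assert_array_equal(pert[0, 2:, 2:], base[0, 2:, 2:])


def test_wmsa_single_window_is_global_msa(rng):
    C, M = 8, 4
    attn = WindowAttention(C, 2, M, np.random.default_rng(3))
    x = rng.standard_normal((1, M, M, C)).astype(np.float32)
    out = w_msa(x, attn, M)
    ref = window_reverse(
        attn.forward(window_partition(x, M), None), M, M, M)
    np.testing.assert_array_equal(out, ref)


def test_shift_mask_region_count():
    """2x2 windows of side M with shift M/2 give exactly 9 regions."""
    assert len(np.unique(shift_region_ids(8, 8, 4, 2))) == 9
    assert len(np.unique(shift_region_ids(14, 14, 7, 3))) == 9


@pytest.mark.parametrize("M,shift", [(2, 1), (3, 1), (3, 2), (4, 1),
                                     (4, 2), (4, 3)])
def test_shift_mask_matches_bruteforce_labeling(M, shift):
    """Mask regions equal brute-force wrap-fragment labels of shifted windows."""
    H = 2 * M
    mask = build_shift_mask(H, H, M, shift)
    for wi in range(H // M):
        for wj in range(H // M):
            rows = (np.arange(M) + shift + wi * M) % H
            cols = (np.arange(M) + shift + wj * M) % H
            rlab = np.cumsum(np.r_[0, np.diff(rows) != 1])
            clab = np.cumsum(np.r_[0, np.diff(cols) != 1])
            labels = (rlab[:, None] * 7 + clab[None, :]).ravel()
            expected = np.where(labels[:, None] != labels[None, :], True,
                                False)
            got = mask[wi * (H // M) + wj] < 0
            np.testing.assert_array_equal(got, expected)


def test_swmsa_equals_shifted_neighborhood_oracle(rng):
    """Masked shifted attention equals naive attention on the unshifted
    grid's shifted-window neighborhoods (wrap fragments attended apart)."""
    for (H, M, shift, C) in [(4, 2, 1, 8), (8, 4, 2, 8), (6, 3, 1, 6)]:
        attn = WindowAttention(C, 2, M, np.random.default_rng(H))
        x = rng.standard_normal((1, H, H, C)).astype(np.float32)
        out = sw_msa(x, attn, M, shift)
        ref = np.zeros_like(out)
        for wi in range(H // M):
            for wj in range(H // M):
                rows = (np.arange(M) + shift + wi * M) % H
                cols = (np.arange(M) + shift + wj * M) % H
                rlab = np.cumsum(np.r_[0, np.diff(rows) != 1])
                clab = np.cumsum(np.r_[0, np.diff(cols) != 1])
                labels = (rlab[:, None] * 7 + clab[None, :]).ravel()
                xw = x[0][np.ix_(rows, cols)].reshape(M * M, C)
                ref[0][np.ix_(rows, cols)] = naive_window_attention(
                    xw, attn, labels).reshape(M, M, C)
        assert np.max(np.abs(out - ref)) < 1e-6


def test_swmsa_invalid_shift(rng):
    attn = WindowAttention(4, 2, 2, np.random.default_rng(0))
    x = rng.standard_normal((1, 4, 4, 4)).astype(np.float32)
    with pytest.raises(ValueError):
        sw_msa(x, attn, 2, 0)
    with pytest.raises(ValueError):
        sw_msa(x, attn, 2, 2)


# ---------------------------------------------------------------------------
# Blocks, merging, full model
# ---------------------------------------------------------------------------

def test_block_preserves_shape_and_gradient_flows(rng):
    blk = SwinBlock(4, (4, 4), 2, 2, 1, np.random.default_rng(3),
                    mlp_ratio=2.0)
    x = rng.standard_normal((1, 4, 4, 4)).astype(np.float32)
    y = blk.forward(x)
    assert y.shape == x.shape
    dy = rng.standard_normal(y.shape).astype(np.float32)
    blk.zero_grad()
    dx = blk.backward(dy)
    # finite-difference check of the input gradient
    eps = 1e-3
    num = np.zeros_like(x)
    for idx in np.ndindex(*x.shape):
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        num[idx] = (float((blk.forward(xp) * dy).sum())
                    - float((blk.forward(xm) * dy).sum())) / (2 * eps)
    rel = np.abs(num - dx).max() / np.abs(num).max()
    assert rel < 5e-3
    assert np.abs(dx).max() > 0


def test_patch_merging_dims(rng):
    pm = PatchMerging(16, np.random.default_rng(0))
    out = pm.forward(rng.standard_normal((1, 2, 2, 16)).astype(np.float32))
    assert out.shape == (1, 1, 1, 32)
    with pytest.raises(ValueError):
        pm.forward(rng.standard_normal((1, 3, 3, 16)).astype(np.float32))


def test_stage_shape_schedule():
    """Dims follow h/4 x w/4 x C -> ... -> h/32 x w/32 x 8C for 224 and 32 px."""
    for cfg in (ModelConfig(), ModelConfig.tiny_test()):
        g = cfg.img_size // cfg.patch_size
        assert cfg.stage_shapes() == [
            (g, g, cfg.embed_dim),
            (g // 2, g // 2, 2 * cfg.embed_dim),
            (g // 4, g // 4, 4 * cfg.embed_dim),
            (g // 8, g // 8, 8 * cfg.embed_dim),
        ]


def test_forward_shapes_and_batch_independence(rng):
    net = SwinNet(ModelConfig.tiny_test())
    imgs = rng.random((3, 32, 32, 3)).astype(np.float32)
    logits = net.forward(imgs)
    assert logits.shape == (3, 5)
    solo = net.forward(imgs[1])
    assert np.max(np.abs(solo - logits[1])) < 1e-6
    with pytest.raises(ValueError):
        net.forward(rng.random((1, 16, 16, 3)))


def test_seed_determinism():
    cfg = ModelConfig.tiny_test(seed=42)
    x = np.random.default_rng(0).random((2, 32, 32, 3)).astype(np.float32)
    a = SwinNet(cfg).forward(x)
    b = SwinNet(cfg).forward(x)
    np.testing.assert_array_equal(a, b)


def test_checkpoint_roundtrip(tmp_path, rng):
    net = SwinNet(ModelConfig.tiny_test(seed=9))
    x = rng.random((2, 32, 32, 3)).astype(np.float32)
    before = net.forward(x)
    path = str(tmp_path / "model.npz")
    net.save(path)
    after = SwinNet.load(path).forward(x)
    np.testing.assert_array_equal(before, after)


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(img_size=225)
    with pytest.raises(ValueError):
        ModelConfig(depths=(1, 2, 2, 2))
    with pytest.raises(ValueError):
        ModelConfig(depths=(2, 2), num_heads=(2, 2, 2))


def test_flops_formulas():
    assert flops_msa(1, 1, 1) == 6
    assert flops_msa(2, 2, 3) == 4 * 4 * 9 + 2 * 16 * 3
    assert flops_wmsa(1, 1, 1, 1) == 6
    assert flops_wmsa(3, 4, 5, 2) == 4 * 12 * 25 + 2 * 4 * 3 * 16 * 5
    with pytest.raises(ValueError):
        flops_msa(0, 1, 1)
    with pytest.raises(ValueError):
        flops_wmsa(1, 1, 1, -2)


def test_training_step_reduces_loss(rng):
    """A few Adam steps on one batch strictly reduce the training loss."""
    net = SwinNet(ModelConfig.tiny_test(seed=1))
    X = rng.random((8, 32, 32, 3)).astype(np.float32)
    y = np.arange(8) % 5
    opt = Adam(net.parameters(), lr=1e-3)
    losses = []
    for _ in range(8):
        loss, dl = cross_entropy(net.forward(X, train=True), y)
        net.zero_grad()
        net.backward(dl)
        opt.step()
        losses.append(loss)
    assert losses[-1] < losses[0]
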