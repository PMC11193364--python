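"""Hierarchical shifted-window attention classifier, built from primitives.

The input RGB image is cut into non-overlapping ``patch x patch`` blocks
(4x4x3 = 48-vectors), linearly embedded to ``C`` channels, and passed
through four stages of paired transformer blocks. Each pair applies

    F^_l   = W-MSA(LN(F_{l-1})) + F_{l-1}
    F_l    = MLP(LN(F^_l))      + F^_l
    F^_l+1 = SW-MSA(LN(F_l))    + F_l
    F_l+1  = MLP(LN(F^_l+1))    + F^_l+1

where W-MSA is multi-head self-attention, softmax(Q K^T / sqrt(d_k)) V,
restricted to non-overlapping M x M token windows, and SW-MSA is the same
attention after a cyclic shift of the token grid by (-M/2, -M/2) with an
additive mask forbidding attention between tokens that were not spatially
contiguous before the shift. Between stages a patch-merging layer
concatenates 2x2 neighbourhoods and projects 4C -> 2C channels, so the
spatial/channel schedule is

    h/4 x w/4 x C  ->  h/8 x w/8 x 2C  ->  h/16 x w/16 x 4C  ->  h/32 x w/32 x 8C.

A final layer norm, global average pool over tokens, and a linear head
produce the five class logits. Forward and backward passes are hand-written
NumPy; gradients check against finite differences in the test suite.

The operation-count helpers :func:`flops_msa` and :func:`flops_wmsa`
implement the quoted complexity formulas verbatim:
``4*m*n*Z^2 + 2*(m*n)^2*Z`` and ``4*m*n*Z^2 + 2*H^2*m*n^2*Z``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    DTYPE,
    Adam,
    Dropout,
    GELU,
    LayerNorm,
    Linear,
    Module,
    Parameter,
    softmax,
    trunc_normal,
)

__all__ = [
    "ModelConfig", "SwinNet", "SwinBlock", "WindowAttention", "PatchMerging",
    "patch_partition", "patch_unpartition", "window_partition",
    "window_reverse", "scaled_dot_attention", "shift_region_ids",
    "build_shift_mask", "w_msa", "sw_msa", "flops_msa", "flops_wmsa",
]

_MASK_VALUE = -1e9  # additive attention mask for forbidden token pairs


# ---------------------------------------------------------------------------
# Complexity accountants
# ---------------------------------------------------------------------------

def flops_msa(m: int, n: int, Z: int) -> int:
    """Operation count of global MSA on an m*n block of dimension Z."""
    for v in (m, n, Z):
        if not isinstance(v, (int, np.integer)) or v <= 0:
            raise ValueError("m, n, Z must be positive integers")
    return 4 * m * n * Z**2 + 2 * (m * n) ** 2 * Z


def flops_wmsa(m: int, n: int, Z: int, H: int) -> int:
    """Operation count of windowed MSA with an H*H window division."""
    for v in (m, n, Z, H):
        if not isinstance(v, (int, np.integer)) or v <= 0:
            raise ValueError("m, n, Z, H must be positive integers")
    return 4 * m * n * Z**2 + 2 * H**2 * m * n**2 * Z


# ---------------------------------------------------------------------------
# Token-grid plumbing (pure reshapes, exactly invertible)
# ---------------------------------------------------------------------------

def patch_partition(image: np.ndarray, patch: int = 4) -> np.ndarray:
    """Split (B,H,W,3) images into flattened patch tokens.

    Returns ``(B, H/patch, W/patch, patch*patch*3)``; a single image
    ``(H,W,3)`` yields ``(H/patch, W/patch, patch*patch*3)``.
    """
    single = image.ndim == 3
    x = image[None] if single else image
    B, H, W, Cin = x.shape
    if H % patch or W % patch:
        raise ValueError(f"image size {H}x{W} not divisible by patch {patch}")
    x = x.reshape(B, H // patch, patch, W // patch, patch, Cin)
    x = x.transpose(0, 1, 3, 2, 4, 5).reshape(
        B, H // patch, W // patch, patch * patch * Cin)
    return x[0] if single else x


def patch_unpartition(tokens: np.ndarray, patch: int = 4,
                      channels: int = 3) -> np.ndarray:
    """Inverse of :func:`patch_partition`."""
    single = tokens.ndim == 3
    x = tokens[None] if single else tokens
    B, Hg, Wg, D = x.shape
    if D != patch * patch * channels:
        raise ValueError("token dimension does not match patch*patch*channels")
    x = x.reshape(B, Hg, Wg, patch, patch, channels)
    x = x.transpose(0, 1, 3, 2, 4, 5).reshape(
        B, Hg * patch, Wg * patch, channels)
    return x[0] if single else x


def window_partition(x: np.ndarray, M: int) -> np.ndarray:
    """(B,H,W,C) -> (B*nW, M*M, C) non-overlapping M x M windows."""
    B, H, W, C = x.shape
    if H % M or W % M:
        raise ValueError(f"grid {H}x{W} not divisible by window {M}")
    x = x.reshape(B, H // M, M, W // M, M, C)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(-1, M * M, C)


def window_reverse(windows: np.ndarray, M: int, H: int, W: int) -> np.ndarray:
    """Inverse of :func:`window_partition`."""
    nW = (H // M) * (W // M)
    B = windows.shape[0] // nW
    x = windows.reshape(B, H // M, W // M, M, M, -1)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(B, H, W, -1)


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V on the last two axes.

    ``Q, K, V`` have shape ``(..., N, d)``; ``mask`` is additive
    (0 / large-negative) and broadcastable to ``(..., N, N)``.
    """
    d_k = Q.shape[-1]
    if d_k <= 0:
        raise ValueError("key dimension must be positive")
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    if mask is not None:
        scores = scores + mask
    return softmax(scores) @ V


def shift_region_ids(H: int, W: int, M: int, shift: int) -> np.ndarray:
    """Integer region label per token for the shifted-window mask.

    Tokens that share a label were spatially contiguous before the cyclic
    shift and may attend to each other; labels are constant on the 3x3
    slab pattern cut at ``-M`` and ``-shift`` along each axis.
    """
    if not 0 < shift < M:
        raise ValueError("shift must satisfy 0 < shift < M")
    ids = np.zeros((H, W), dtype=int)
    h_slices = (slice(0, H - M), slice(H - M, H - shift), slice(H - shift, H))
    w_slices = (slice(0, W - M), slice(W - M, W - shift), slice(W - shift, W))
    cnt = 0
    for hs in h_slices:
        for ws in w_slices:
            ids[hs, ws] = cnt
            cnt += 1
    return ids


def build_shift_mask(H: int, W: int, M: int, shift: int) -> np.ndarray:
    """Additive attention mask per window, shape (nW, M*M, M*M)."""
    ids = shift_region_ids(H, W, M, shift)
    win = window_partition(ids[None, :, :, None].astype(float), M)[..., 0]
    diff = win[:, :, None] - win[:, None, :]
    return np.where(diff != 0, _MASK_VALUE, 0.0).astype(DTYPE)


class WindowAttention(Module):
    """Multi-head self-attention within M x M windows.

    Operates on pre-partitioned windows ``(B*nW, N, C)`` with ``N = M*M``.
    Includes a learnable relative-position bias indexed by the (2M-1)^2
    possible token offsets (toggleable, since the quoted attention formula
    omits it).
    """

    def __init__(self, dim: int, num_heads: int, M: int,
                 rng: np.random.Generator, rel_pos_bias: bool = True):
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by heads {num_heads}")
        self.dim = dim
        self.num_heads = num_heads
        self.M = M
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.rel_bias: Parameter | None = None
        if rel_pos_bias:
            self.rel_bias = Parameter(
                trunc_normal(rng, ((2 * M - 1) ** 2, num_heads)), "rel_bias")
            coords = np.stack(np.meshgrid(np.arange(M), np.arange(M),
                                          indexing="ij"), axis=0)
            flat = coords.reshape(2, -1)
            rel = flat[:, :, None] - flat[:, None, :] + (M - 1)
            self._bias_index = rel[0] * (2 * M - 1) + rel[1]  # (N, N)
        self._cache = None

    def forward(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        Bw, N, C = x.shape
        h, hd = self.num_heads, C // self.num_heads
        qkv = self.qkv.forward(x).reshape(Bw, N, 3, h, hd)
        q, k, v = (qkv[:, :, i].transpose(0, 2, 1, 3) for i in range(3))
        scale = 1.0 / np.sqrt(hd)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        if self.rel_bias is not None:
            bias = self.rel_bias.value[self._bias_index]      # (N, N, h)
            scores = scores + bias.transpose(2, 0, 1)[None]
        if mask is not None:
            nW = mask.shape[0]
            scores = (scores.reshape(Bw // nW, nW, h, N, N)
                      + mask[None, :, None]).reshape(Bw, h, N, N)
        attn = softmax(scores).astype(DTYPE)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(Bw, N, C)
        self._cache = (q, k, v, attn, scale)
        return self.proj.forward(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, attn, scale = self._cache
        Bw, h, N, hd = q.shape
        C = h * hd
        dout = self.proj.backward(dy)
        dout = dout.reshape(Bw, N, h, hd).transpose(0, 2, 1, 3)
        dattn = dout @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dout
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        if self.rel_bias is not None:
            db = dscores.sum(axis=0).transpose(1, 2, 0)        # (N, N, h)
            np.add.at(self.rel_bias.grad, self._bias_index.ravel(),
                      db.reshape(-1, h))
        dq = (dscores @ k) * scale
        dk = (dscores.transpose(0, 1, 3, 2) @ q) * scale
        dqkv = np.empty((Bw, N, 3, h, hd), dtype=DTYPE)
        dqkv[:, :, 0] = dq.transpose(0, 2, 1, 3)
        dqkv[:, :, 1] = dk.transpose(0, 2, 1, 3)
        dqkv[:, :, 2] = dv.transpose(0, 2, 1, 3)
        return self.qkv.backward(dqkv.reshape(Bw, N, 3 * C))


def w_msa(grid: np.ndarray, attn: WindowAttention, M: int) -> np.ndarray:
    """Window attention on a token grid (B,H,W,C); no cross-window flow."""
    B, H, W, C = grid.shape
    wins = window_partition(grid, M)
    return window_reverse(attn.forward(wins, None), M, H, W)


def sw_msa(grid: np.ndarray, attn: WindowAttention, M: int,
           shift: int) -> np.ndarray:
    """Shifted-window attention: cyclic shift, masked windows, unshift."""
    B, H, W, C = grid.shape
    if not 0 < shift < M:
        raise ValueError("shift must satisfy 0 < shift < M")
    shifted = np.roll(grid, (-shift, -shift), axis=(1, 2))
    mask = build_shift_mask(H, W, M, shift)
    wins = window_partition(shifted, M)
    out = window_reverse(attn.forward(wins, mask), M, H, W)
    return np.roll(out, (shift, shift), axis=(1, 2))


# ---------------------------------------------------------------------------
# Blocks and stages
# ---------------------------------------------------------------------------

class Mlp(Module):
    """Two-layer token MLP with GELU and dropout."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 drop: float = 0.0):
        self.fc1 = Linear(dim, hidden, rng)
        self.act = GELU()
        self.fc2 = Linear(hidden, dim, rng)
        self.drop = Dropout(drop, rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.act.forward(self.fc1.forward(x))
        return self.drop.forward(self.fc2.forward(y), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.act.backward(
            self.fc2.backward(self.drop.backward(dy))))


class SwinBlock(Module):
    """One transformer block: LN -> (S)W-MSA -> residual, LN -> MLP -> residual."""

    def __init__(self, dim: int, input_res: tuple[int, int], num_heads: int,
                 M: int, shift: int, rng: np.random.Generator,
                 mlp_ratio: float = 4.0, drop: float = 0.0,
                 rel_pos_bias: bool = True):
        H, W = input_res
        if H % M or W % M:
            raise ValueError(f"grid {H}x{W} not divisible by window {M}")
        if shift and not 0 < shift < M:
            raise ValueError("shift must satisfy 0 < shift < M (or be 0)")
        self.input_res = input_res
        self.M = M
        self.shift = shift
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, M, rng, rel_pos_bias)
        self.drop1 = Dropout(drop, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng, drop)
        self._mask = build_shift_mask(H, W, M, shift) if shift else None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        y = self.norm1.forward(x)
        if self.shift:
            y = np.roll(y, (-self.shift, -self.shift), axis=(1, 2))
        wins = window_partition(y, self.M)
        out = self.attn.forward(wins, self._mask)
        y = window_reverse(out, self.M, H, W)
        if self.shift:
            y = np.roll(y, (self.shift, self.shift), axis=(1, 2))
        x = x + self.drop1.forward(y, train)
        return x + self.mlp.forward(self.norm2.forward(x), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, H, W, C = dy.shape
        dx = dy + self.norm2.backward(self.mlp.backward(dy))
        d = self.drop1.backward(dx)
        if self.shift:
            d = np.roll(d, (-self.shift, -self.shift), axis=(1, 2))
        dwins = window_partition(d, self.M)
        d = window_reverse(self.attn.backward(dwins), self.M, H, W)
        if self.shift:
            d = np.roll(d, (self.shift, self.shift), axis=(1, 2))
        return dx + self.norm1.backward(d)


class PatchMerging(Module):
    """Concatenate 2x2 token neighbourhoods, LN, project 4C -> 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"grid {H}x{W} has odd side; cannot merge 2x2")
        merged = np.concatenate(
            [x[:, 0::2, 0::2], x[:, 1::2, 0::2],
             x[:, 0::2, 1::2], x[:, 1::2, 1::2]], axis=-1)
        return self.reduction.forward(self.norm.forward(merged))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.norm.backward(self.reduction.backward(dy))
        B, Hh, Wh, _ = d.shape
        C = self.dim
        dx = np.zeros((B, 2 * Hh, 2 * Wh, C), dtype=DTYPE)
        dx[:, 0::2, 0::2] = d[..., 0 * C:1 * C]
        dx[:, 1::2, 0::2] = d[..., 1 * C:2 * C]
        dx[:, 0::2, 1::2] = d[..., 2 * C:3 * C]
        dx[:, 1::2, 1::2] = d[..., 3 * C:4 * C]
        return dx


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the tiny recipe of the original hierarchical window
    architecture (C=96, depths 2-2-6-2, heads 3-6-12-24, window 7, 224px
    input). :meth:`tiny_test` returns a CPU-sized configuration used
    throughout the test suite.
    """

    img_size: int = 224
    patch_size: int = 4
    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    num_heads: tuple[int, ...] = (3, 6, 12, 24)
    window: int = 7
    num_classes: int = 5
    mlp_ratio: float = 4.0
    drop_rate: float = 0.0
    rel_pos_bias: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.img_size % self.patch_size:
            raise ValueError("img_size must be divisible by patch_size")
        if len(self.depths) != len(self.num_heads):
            raise ValueError("depths and num_heads must have equal length")
        if any(d % 2 for d in self.depths):
            raise ValueError("stage depths must be even (W-MSA/SW-MSA pairs)")
        g = self.img_size // self.patch_size
        for s, heads in enumerate(self.num_heads):
            if (g >> s) < 1:
                raise ValueError("too many stages for this image size")
            if (self.embed_dim << s) % heads:
                raise ValueError(f"stage {s} dim not divisible by heads")
            m_eff = min(self.window, g >> s)
            if (g >> s) % m_eff:
                raise ValueError(
                    f"stage {s} grid {g >> s} not tileable by window {m_eff}")

    @classmethod
    def tiny_test(cls, **overrides) -> "ModelConfig":
        """Small CPU-friendly configuration (32px, C=16, depths 2-2-2-2)."""
        kw = dict(img_size=32, patch_size=4, embed_dim=16,
                  depths=(2, 2, 2, 2), num_heads=(2, 2, 2, 2), window=4,
                  mlp_ratio=2.0)
        kw.update(overrides)
        return cls(**kw)

    def stage_shapes(self) -> list[tuple[int, int, int]]:
        """(H_g, W_g, dim) after each stage's blocks."""
        g = self.img_size // self.patch_size
        return [(g >> s, g >> s, self.embed_dim << s)
                for s in range(len(self.depths))]


class SwinNet(Module):
    """The four-stage windowed-attention classifier."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        g = cfg.img_size // cfg.patch_size
        in_dim = cfg.patch_size * cfg.patch_size * 3
        self.embed = Linear(in_dim, cfg.embed_dim, rng)
        self.embed_norm = LayerNorm(cfg.embed_dim)
        self.stages: list[list[SwinBlock]] = []
        self.merges: list[PatchMerging] = []
        dim = cfg.embed_dim
        res = g
        for s, (depth, heads) in enumerate(zip(cfg.depths, cfg.num_heads)):
            m_eff = min(cfg.window, res)
            blocks = []
            for b in range(depth):
                shift = 0 if (b % 2 == 0 or m_eff >= res) else m_eff // 2
                blocks.append(SwinBlock(
                    dim, (res, res), heads, m_eff, shift, rng,
                    mlp_ratio=cfg.mlp_ratio, drop=cfg.drop_rate,
                    rel_pos_bias=cfg.rel_pos_bias))
            self.stages.append(blocks)
            if s < len(cfg.depths) - 1:
                self.merges.append(PatchMerging(dim, rng))
                dim *= 2
                res //= 2
        self.norm = LayerNorm(dim)
        self.head = Linear(dim, cfg.num_classes, rng)
        self._pool_shape: tuple[int, ...] | None = None

    # -- forward / backward -------------------------------------------------

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Class logits for (B, img, img, 3) images in [0, 1]."""
        single = images.ndim == 3
        x = images[None] if single else images
        B, H, W, C = x.shape
        if (H, W, C) != (self.cfg.img_size, self.cfg.img_size, 3):
            raise ValueError(
                f"expected {self.cfg.img_size}x{self.cfg.img_size}x3 input, "
                f"got {H}x{W}x{C}")
        t = patch_partition(x.astype(DTYPE), self.cfg.patch_size)
        t = self.embed_norm.forward(self.embed.forward(t))
        for s, blocks in enumerate(self.stages):
            for blk in blocks:
                t = blk.forward(t, train)
            if s < len(self.merges):
                t = self.merges[s].forward(t)
        t = self.norm.forward(t)
        self._pool_shape = t.shape
        pooled = t.reshape(t.shape[0], -1, t.shape[-1]).mean(axis=1)
        logits = self.head.forward(pooled)
        return logits[0] if single else logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dpooled = self.head.backward(dlogits.astype(DTYPE))
        B, Hg, Wg, C = self._pool_shape
        dt = np.broadcast_to(
            dpooled[:, None, :] / (Hg * Wg), (B, Hg * Wg, C)
        ).reshape(B, Hg, Wg, C).astype(DTYPE)
        dt = self.norm.backward(dt)
        for s in range(len(self.stages) - 1, -1, -1):
            if s < len(self.merges):
                dt = self.merges[s].backward(dt)
            for blk in reversed(self.stages[s]):
                dt = blk.backward(dt)
        dt = self.embed.backward(self.embed_norm.backward(dt))
        return patch_unpartition(dt, self.cfg.patch_size)

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str) -> None:
        """Single-file checkpoint: versioned JSON header + named arrays."""
        header = {"format": "swinbeat-checkpoint", "version": 1,
                  "config": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in self.cfg.__dict__.items()}}
        arrays = {f"p{i:04d}": p.value for i, p in enumerate(self.parameters())}
        with open(path, "wb") as fh:
            np.savez(fh, __header__=np.frombuffer(
                json.dumps(header).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "SwinNet":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            if header.get("format") != "swinbeat-checkpoint":
                raise ValueError("not a model checkpoint")
            cfg_d = header["config"]
            cfg = ModelConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                 for k, v in cfg_d.items()})
            net = cls(cfg)
            params = net.parameters()
            names = sorted(k for k in data.files if k.startswith("p"))
            if len(names) != len(params):
                raise ValueError("checkpoint/model parameter count mismatch")
            for name, p in zip(names, params):
                if data[name].shape != p.value.shape:
                    raise ValueError("checkpoint parameter shape mismatch")
                p.value[...] = data[name]
        return net

    def parameters(self) -> list[Parameter]:
        out = list(self.embed.parameters()) + list(self.embed_norm.parameters())
        for s, blocks in enumerate(self.stages):
            for blk in blocks:
                out.extend(blk.parameters())
            if s < len(self.merges):
                out.extend(self.merges[s].parameters())
        out.extend(self.norm.parameters())
        out.extend(self.head.parameters())
        return out
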