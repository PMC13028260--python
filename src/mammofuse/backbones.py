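"""The two encoder streams.

Local stream: a ConvNeXt-style stack — 7x7 depthwise convolutions, inverted
bottleneck blocks that expand the channel width by a factor of 4, layer
normalization instead of batch normalization — returning the final-stage
spatial feature map (1024 channels for the base preset).

Global stream: a SwinV2-style hierarchical transformer — self-attention inside
non-overlapping M x M token windows (M = 7 for base), with the window grid
cyclically shifted by floor(M/2) in alternating blocks, scaled cosine
attention with a learnable per-head temperature, and a learnable relative
position bias table — returning the final-stage token grid.

Both are simplified re-creations that preserve the named operators at desk
scale; presets are registered by name and serializable through ``state_dict``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .nn import Conv2d, LayerNorm, Linear, Module, Parameter, Tensor


# ------------------------------------------------------------------- presets
@dataclass(frozen=True)
class BackbonePreset:
    """Architecture hyperparameters for one (local, global) encoder pair."""

    name: str
    input_size: int
    local_depths: tuple
    local_channels: tuple
    global_depths: tuple
    global_channels: tuple
    global_heads: tuple
    window_size: int
    patch_size: int
    stem_stride: int = 4

    def __post_init__(self):
        if list(self.local_channels) != sorted(set(self.local_channels)):
            raise ValueError("stage channels must be strictly increasing")
        if self.window_size < 1:
            raise ValueError("window size must be >= 1")

    @property
    def local_stride(self) -> int:
        return self.stem_stride * 2 ** (len(self.local_channels) - 1)

    @property
    def global_stride(self) -> int:
        return self.patch_size * 2 ** (len(self.global_channels) - 1)


PRESETS: dict[str, BackbonePreset] = {
    "tiny": BackbonePreset(
        name="tiny", input_size=96,
        local_depths=(1, 1), local_channels=(16, 32),
        global_depths=(2, 2), global_channels=(24, 48), global_heads=(2, 4),
        window_size=6, patch_size=8,
    ),
    "base": BackbonePreset(
        name="base", input_size=384,
        local_depths=(1, 1, 1, 1), local_channels=(128, 256, 512, 1024),
        global_depths=(2, 2, 2, 2), global_channels=(128, 256, 512, 1024),
        global_heads=(4, 8, 16, 32),
        window_size=7, patch_size=4,
    ),
}


def get_preset(name: str) -> BackbonePreset:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name]


# --------------------------------------------------------------- result types
@dataclass
class LocalFeatureGrid:
    """F_L: spatial feature map (N, C, h, w) from the convolutional stream."""

    grid: Tensor
    stride: int

    @property
    def channels(self) -> int:
        return self.grid.shape[1]


@dataclass
class GlobalTokenGrid:
    """F_G: token sequence (N, T, C) with its retained (rows, cols) shape."""

    tokens: Tensor
    grid_shape: tuple
    stride: int

    @property
    def channels(self) -> int:
        return self.tokens.shape[2]


# -------------------------------------------------------------- local stream
class ConvNeXtBlock(Module):
    """7x7 depthwise conv -> LN -> 1x1 expand (4C) -> GELU -> 1x1 project -> +x."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.dwconv = Conv2d(dim, dim, 7, rng, padding=3, groups=dim)
        self.norm = LayerNorm(dim)
        self.pwconv1 = Linear(dim, 4 * dim, rng)
        self.pwconv2 = Linear(4 * dim, dim, rng)
        self.dim = dim

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.dim:
            raise ValueError(f"expected {self.dim} channels, got {x.shape[1]}")
        y = self.dwconv(x)
        y = y.transpose(0, 2, 3, 1)  # channels-last for LN and pointwise layers
        y = self.norm(y)
        y = self.pwconv1(y).gelu()
        y = self.pwconv2(y)
        y = y.transpose(0, 3, 1, 2)
        return x + y


class LocalEncoder(Module):
    """Staged depthwise-conv encoder; returns the final-stage feature map."""

    def __init__(self, preset: BackbonePreset, rng: np.random.Generator):
        super().__init__()
        self.preset = preset
        dims = preset.local_channels
        self.stem = Conv2d(1, dims[0], preset.stem_stride, rng, stride=preset.stem_stride)
        self.stem_norm = LayerNorm(dims[0])
        blocks, downs = [], []
        for i, (dim, depth) in enumerate(zip(dims, preset.local_depths)):
            blocks.append([ConvNeXtBlock(dim, rng) for _ in range(depth)])
            if i + 1 < len(dims):
                downs.append(_Downsample(dim, dims[i + 1], rng))
        self.stage_blocks = [b for stage in blocks for b in stage]
        self._stage_sizes = [len(s) for s in blocks]
        self.downsamples = downs

    def forward(self, images) -> LocalFeatureGrid:
        x = _as_nchw(images)
        size = x.shape[2]
        stride = self.preset.local_stride
        if size % stride or x.shape[3] % stride:
            raise ValueError(f"input size {x.shape[2:]} not divisible by stride {stride}")
        x = self.stem(x)
        x = self.stem_norm(x.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)
        idx = 0
        for i, n in enumerate(self._stage_sizes):
            for _ in range(n):
                x = self.stage_blocks[idx](x)
                idx += 1
            if i < len(self.downsamples):
                x = self.downsamples[i](x)
        return LocalFeatureGrid(x, stride)


class _Downsample(Module):
    def __init__(self, dim_in: int, dim_out: int, rng):
        super().__init__()
        self.norm = LayerNorm(dim_in)
        self.conv = Conv2d(dim_in, dim_out, 2, rng, stride=2)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm(x.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)
        return self.conv(x)


def _as_nchw(images) -> Tensor:
    if isinstance(images, Tensor):
        x = images
    else:
        x = Tensor(np.asarray(images, dtype=np.float64))
    if x.ndim == 2:
        x = x.reshape(1, 1, *x.shape)
    elif x.ndim == 3:
        x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
    return x


# ------------------------------------------------------------- window algebra
def window_partition(x: Tensor, window: int) -> Tensor:
    """(N, H, W, C) -> (N * nWindows, window*window, C); H, W multiples of window."""
    n, h, w, c = x.shape
    if h % window or w % window:
        raise ValueError("grid sides must be padded to multiples of the window size")
    x = x.reshape(n, h // window, window, w // window, window, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(n * (h // window) * (w // window), window * window, c)


def window_reverse(windows: Tensor, window: int, h: int, w: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    nw = (h // window) * (w // window)
    n = windows.shape[0] // nw
    x = windows.reshape(n, h // window, w // window, window, window, windows.shape[-1])
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(n, h, w, windows.shape[-1])


def scaled_cosine_attention(
    q: Tensor, k: Tensor, v: Tensor, tau: Tensor,
    bias: Tensor | None = None, mask: np.ndarray | None = None,
) -> Tensor:
    """Attention with logits cos(q_i, k_j) / tau + bias.

    ``q, k, v``: (..., heads, T, d); ``tau``: positive per-head temperature,
    broadcastable to the logit shape.  Zero-norm queries/keys yield cosine 0
    by the norm clamp.  Rows are softmax-normalized, so each output token is a
    convex combination of value vectors.
    """
    # clamp before the square root: sqrt'(0) is infinite and would poison the
    # backward pass for exactly-zero token vectors
    qn = q / (q * q).sum(axis=-1, keepdims=True).clamp_min(1e-24).sqrt()
    kn = k / (k * k).sum(axis=-1, keepdims=True).clamp_min(1e-24).sqrt()
    logits = (qn @ kn.transpose(*range(qn.ndim - 2), qn.ndim - 1, qn.ndim - 2)) / tau
    if bias is not None:
        logits = logits + bias
    if mask is not None:
        logits = logits + Tensor(mask)
    weights = logits.softmax(axis=-1)
    return weights @ v


def _relative_position_index(window: int) -> np.ndarray:
    coords = np.stack(
        np.meshgrid(np.arange(window), np.arange(window), indexing="ij")
    ).reshape(2, -1)
    rel = coords[:, :, None] - coords[:, None, :] + window - 1
    return (rel[0] * (2 * window - 1) + rel[1]).astype(np.int64)


def _shift_attention_mask(hp: int, wp: int, h: int, w: int,
                          window: int, shift: int) -> np.ndarray | None:
    """(nWindows, T, T) additive mask blocking attention between tokens whose
    true (unwrapped) neighborhoods differ, and to padded positions."""
    seg = np.zeros((hp, wp), dtype=np.int64)
    if shift > 0:
        cnt = 0
        yslices = (slice(0, hp - window), slice(hp - window, hp - shift), slice(hp - shift, hp))
        xslices = (slice(0, wp - window), slice(wp - window, wp - shift), slice(wp - shift, wp))
        for sy in yslices:
            for sx in xslices:
                seg[sy, sx] = cnt
                cnt += 1
    pad = np.zeros((hp, wp), dtype=bool)
    pad[h:, :] = True
    pad[:, w:] = True
    if shift > 0:
        pad = np.roll(pad, (-shift, -shift), axis=(0, 1))
    ids = np.where(pad, -1, seg)
    if shift == 0 and not pad.any():
        return None
    t = window * window
    win = (
        ids.reshape(hp // window, window, wp // window, window)
        .transpose(0, 2, 1, 3)
        .reshape(-1, t)
    )
    return np.where(win[:, :, None] != win[:, None, :], -1e9, 0.0)


class WindowAttention(Module):
    """Multi-head scaled-cosine attention within windows, with relative bias."""

    def __init__(self, dim: int, heads: int, window: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.window = dim, heads, window
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.tau = Parameter(np.ones((heads, 1, 1)))
        self.rel_bias_table = Parameter(np.zeros(((2 * window - 1) ** 2, heads)))
        self._rel_index = _relative_position_index(window)

    def forward(self, windows: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b, t, c = windows.shape
        qkv = self.qkv(windows).reshape(b, t, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, b, heads, t, d)
        q, k, v = qkv[0], qkv[1], qkv[2]
        bias = self.rel_bias_table.take(self._rel_index.ravel(), axis=0)
        bias = bias.reshape(t, t, self.heads).transpose(2, 0, 1)  # (heads, t, t)
        tau = self.tau.clamp_min(0.01)
        if mask is not None:
            nw = mask.shape[0]
            mask = np.tile(mask[:, None], (b // nw, 1, 1, 1))  # (b, 1, t, t)
        out = scaled_cosine_attention(q, k, v, tau, bias=bias, mask=mask)
        out = out.transpose(0, 2, 1, 3).reshape(b, t, c)
        return self.proj(out)


class SwinBlock(Module):
    """One shifted-window attention block with post-residual layer norms."""

    def __init__(self, dim: int, heads: int, window: int, shift: int,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = WindowAttention(dim, heads, window, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.mlp_fc1 = Linear(dim, 4 * dim, rng)
        self.mlp_fc2 = Linear(4 * dim, dim, rng)
        self.window, self.shift = window, shift

    def forward(self, tokens: Tensor, grid_shape: tuple) -> Tensor:
        n, t, c = tokens.shape
        h, w = grid_shape
        m = self.window
        hp = -(-h // m) * m
        wp = -(-w // m) * m
        x = tokens.reshape(n, h, w, c)
        if (hp, wp) != (h, w):
            x = x.transpose(0, 3, 1, 2).pad2d((0, hp - h), (0, wp - w)).transpose(0, 2, 3, 1)
        if self.shift:
            x = x.roll((-self.shift, -self.shift), axis=(1, 2))
        mask = _shift_attention_mask(hp, wp, h, w, m, self.shift)
        wins = window_partition(x, m)
        wins = self.attn(wins, mask=mask)
        x = window_reverse(wins, m, hp, wp)
        if self.shift:
            x = x.roll((self.shift, self.shift), axis=(1, 2))
        x = x[:, :h, :w, :]
        attn_out = x.reshape(n, t, c)
        tokens = self.norm1(tokens + attn_out)
        mlp = self.mlp_fc2(self.mlp_fc1(tokens).gelu())
        return self.norm2(tokens + mlp)


class PatchMerging(Module):
    """2x2 token concatenation -> LN -> linear reduction to 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = LayerNorm(4 * dim)
        self.reduce = Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, tokens: Tensor, grid_shape: tuple):
        n, t, c = tokens.shape
        h, w = grid_shape
        x = tokens.reshape(n, h, w, c)
        x = x.reshape(n, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(n, (h // 2) * (w // 2), 4 * c)
        return self.reduce(self.norm(x)), (h // 2, w // 2)


class GlobalEncoder(Module):
    """Patch embedding + hierarchical shifted-window attention stages."""

    def __init__(self, preset: BackbonePreset, rng: np.random.Generator):
        super().__init__()
        self.preset = preset
        dims, heads = preset.global_channels, preset.global_heads
        self.patch_embed = Conv2d(1, dims[0], preset.patch_size, rng,
                                  stride=preset.patch_size)
        self.embed_norm = LayerNorm(dims[0])
        blocks, merges = [], []
        m = preset.window_size
        for i, (dim, depth, nh) in enumerate(zip(dims, preset.global_depths, heads)):
            stage = [
                SwinBlock(dim, nh, m, 0 if j % 2 == 0 else m // 2, rng)
                for j in range(depth)
            ]
            blocks.append(stage)
            if i + 1 < len(dims):
                merges.append(PatchMerging(dim, rng))
        self.stage_blocks = [b for stage in blocks for b in stage]
        self._stage_sizes = [len(s) for s in blocks]
        self.merges = merges

    def forward(self, images) -> GlobalTokenGrid:
        x = _as_nchw(images)
        p = self.preset.patch_size
        if x.shape[2] % p or x.shape[3] % p:
            raise ValueError(f"input size {x.shape[2:]} not divisible by patch size {p}")
        x = self.patch_embed(x)  # (N, C, h, w)
        n, c, h, w = x.shape
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)
        tokens = self.embed_norm(tokens)
        grid = (h, w)
        idx = 0
        for i, ns in enumerate(self._stage_sizes):
            for _ in range(ns):
                tokens = self.stage_blocks[idx](tokens, grid)
                idx += 1
            if i < len(self.merges):
                tokens, grid = self.merges[i](tokens, grid)
        return GlobalTokenGrid(tokens, grid, self.preset.global_stride)


def local_encode(image, preset: BackbonePreset | str, rng=None) -> LocalFeatureGrid:
    """Convenience: build a fresh local encoder and run one forward pass."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    rng = rng or np.random.default_rng(0)
    return LocalEncoder(preset, rng)(image)


def global_encode(image, preset: BackbonePreset | str, rng=None) -> GlobalTokenGrid:
    """Convenience: build a fresh global encoder and run one forward pass."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    rng = rng or np.random.default_rng(0)
    return GlobalEncoder(preset, rng)(image)
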