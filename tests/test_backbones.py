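"""Encoder behavior: block algebra, window algebra, cosine attention, masking."""

import time

import numpy as np
import pytest

from mammofuse.backbones import (BackbonePreset, ConvNeXtBlock, GlobalEncoder,
                                 LocalEncoder, SwinBlock, WindowAttention,
                                 get_preset, scaled_cosine_attention,
                                 window_partition, window_reverse)
from mammofuse.nn import Identity, Tensor


# --------------------------------------------------------------- ConvNeXt block
def test_convnext_block_zero_input_zero_biases_gives_zero():
    block = ConvNeXtBlock(8, np.random.default_rng(0))  # biases init to zero
    out = block(Tensor(np.zeros((1, 8, 12, 12))))
    assert np.allclose(out.data, 0.0)


def test_convnext_block_channel_widths_expand_by_four():
    block = ConvNeXtBlock(16, np.random.default_rng(0))
    assert block.pwconv1.weight.shape == (16, 64)
    assert block.pwconv2.weight.shape == (64, 16)
    x = Tensor(np.random.default_rng(1).normal(size=(2, 16, 10, 10)))
    assert block(x).shape == x.shape
    with pytest.raises(ValueError):
        block(Tensor(np.zeros((1, 8, 10, 10))))


def test_convnext_block_delta_kernel_identity_pointwise_doubles_input():
    c = 6
    block = ConvNeXtBlock(c, np.random.default_rng(0))
    w = np.zeros((c, 1, 7, 7))
    w[:, 0, 3, 3] = 1.0  # centered delta depthwise kernel
    block.dwconv.weight.data = w
    block.norm = Identity()
    pw1 = np.zeros((c, 4 * c))
    pw1[np.arange(c), np.arange(c)] = 1.0
    block.pwconv1.weight.data = pw1
    pw2 = np.zeros((4 * c, c))
    pw2[np.arange(c), np.arange(c)] = 1.0
    block.pwconv2.weight.data = pw2
    # large positive values keep the GELU within 3e-4 of identity
    x = np.random.default_rng(2).uniform(5.0, 9.0, (1, c, 9, 9))
    out = block(Tensor(x))
    assert np.allclose(out.data, 2 * x, atol=1e-3)


def test_local_encoder_shapes_and_determinism():
    preset = get_preset("tiny")
    enc = LocalEncoder(preset, np.random.default_rng(0))
    img = np.random.default_rng(1).random((96, 96))
    f1 = enc(img)
    f2 = enc(img)
    side = 96 // preset.local_stride
    assert f1.grid.shape == (1, preset.local_channels[-1], side, side)
    assert np.array_equal(f1.grid.data, f2.grid.data)
    with pytest.raises(ValueError):
        enc(np.zeros((50, 50)))


def test_tiny_forward_pass_is_subsecond_on_cpu(tiny_model):
    img = np.random.default_rng(0).random((96, 96))
    tiny_model(img[None])  # warm path
    t0 = time.time()
    tiny_model(img[None])
    assert time.time() - t0 < 1.0


# -------------------------------------------------------------- window algebra
@pytest.mark.parametrize("h,w,m", [(14, 14, 7), (12, 24, 6), (8, 8, 4)])
def test_window_partition_counts_and_roundtrip(h, w, m):
    rng = np.random.default_rng(0)
    x = Tensor(rng.normal(size=(2, h, w, 5)))
    wins = window_partition(x, m)
    assert wins.shape == (2 * (h // m) * (w // m), m * m, 5)
    back = window_reverse(wins, m, h, w)
    assert np.array_equal(back.data, x.data)


def test_shifted_partition_roundtrip_is_identity():
    rng = np.random.default_rng(1)
    x = Tensor(rng.normal(size=(1, 12, 12, 3)))
    shift = 3
    y = x.roll((-shift, -shift), axis=(1, 2))
    y = window_reverse(window_partition(y, 6), 6, 12, 12)
    y = y.roll((shift, shift), axis=(1, 2))
    assert np.array_equal(y.data, x.data)


# ------------------------------------------------------------ cosine attention
def test_identical_keys_give_uniform_weights_and_mean_value_output():
    rng = np.random.default_rng(2)
    q = Tensor(rng.normal(size=(1, 2, 5, 4)))
    k = Tensor(np.tile(rng.normal(size=(1, 2, 1, 4)), (1, 1, 5, 1)))
    v = Tensor(rng.normal(size=(1, 2, 5, 4)))
    out = scaled_cosine_attention(q, k, v, Tensor(np.ones((2, 1, 1))))
    assert np.allclose(out.data, v.data.mean(axis=2, keepdims=True), atol=1e-12)


def test_attention_rows_sum_to_one_via_constant_values():
    # with every value vector = ones, a softmax-weighted output of ones proves
    # each attention row sums to 1
    rng = np.random.default_rng(3)
    q = Tensor(rng.normal(size=(2, 3, 6, 4)))
    k = Tensor(rng.normal(size=(2, 3, 6, 4)))
    v = Tensor(np.ones((2, 3, 6, 4)))
    out = scaled_cosine_attention(q, k, v, Tensor(np.full((3, 1, 1), 0.7)))
    assert np.allclose(out.data, 1.0, atol=1e-12)


def test_small_temperature_selects_argmax_cosine_key():
    rng = np.random.default_rng(4)
    q = Tensor(rng.normal(size=(1, 1, 3, 8)))
    k = Tensor(rng.normal(size=(1, 1, 7, 8)))
    v = Tensor(rng.normal(size=(1, 1, 7, 8)))
    out = scaled_cosine_attention(q, k, v, Tensor(np.full((1, 1, 1), 1e-3)))
    qn = q.data / np.linalg.norm(q.data, axis=-1, keepdims=True)
    kn = k.data / np.linalg.norm(k.data, axis=-1, keepdims=True)
    cos = qn @ np.swapaxes(kn, -1, -2)
    hard = v.data[0, 0, cos[0, 0].argmax(axis=-1)]
    assert np.allclose(out.data[0, 0], hard, atol=1e-6)


def test_zero_norm_query_defines_cosine_zero_uniform_row():
    q = Tensor(np.zeros((1, 1, 1, 4)))
    k = Tensor(np.random.default_rng(5).normal(size=(1, 1, 5, 4)))
    v = Tensor(np.random.default_rng(6).normal(size=(1, 1, 5, 4)))
    out = scaled_cosine_attention(q, k, v, Tensor(np.ones((1, 1, 1))))
    assert np.allclose(out.data[0, 0, 0], v.data[0, 0].mean(axis=0))


# ----------------------------------------------------------------- Swin blocks
def _attention_only_block(dim, heads, window, shift, seed):
    """SwinBlock rigged so output - input == its attention branch."""
    block = SwinBlock(dim, heads, window, shift, np.random.default_rng(seed))
    block.norm1 = Identity()
    block.norm2 = Identity()
    block.mlp_fc2.weight.data[:] = 0.0
    rng = np.random.default_rng(seed + 100)
    block.attn.rel_bias_table.data = rng.normal(0, 0.5, block.attn.rel_bias_table.shape)
    block.attn.tau.data = rng.uniform(0.5, 2.0, block.attn.tau.shape)
    return block


def _attention_oracle(attn: WindowAttention, tokens: np.ndarray, grid, shift):
    """Brute-force per-neighborhood cosine attention on the true (unwrapped)
    neighborhoods, using the module's own weights."""
    h, w = grid
    c, m, heads, d = attn.dim, attn.window, attn.heads, attn.head_dim
    x = tokens.reshape(h, w, c)
    qkv = x.reshape(-1, c) @ attn.qkv.weight.data + attn.qkv.bias.data
    qkv = qkv.reshape(h * w, 3, heads, d)
    tau = np.maximum(attn.tau.data[:, 0, 0], 0.01)
    table = attn.rel_bias_table.data

    def group_key(y, x_):
        ry, rx = (y - shift) % h, (x_ - shift) % w
        return (ry // m, rx // m, y < shift, x_ < shift)

    def inwin(y, x_):
        return ((y - shift) % h) % m, ((x_ - shift) % w) % m

    out = np.zeros((h * w, heads, d))
    flat = [(y, x_) for y in range(h) for x_ in range(w)]
    for i, (yi, xi) in enumerate(flat):
        members = [j for j, (yj, xj) in enumerate(flat)
                   if group_key(yj, xj) == group_key(yi, xi)]
        for hd in range(heads):
            qi = qkv[i, 0, hd]
            qi = qi / max(np.linalg.norm(qi), 1e-12)
            logits = []
            for j in members:
                kj = qkv[j, 1, hd]
                kj = kj / max(np.linalg.norm(kj), 1e-12)
                dyi, dxi = inwin(yi, xi)
                dyj, dxj = inwin(*flat[j])
                bias = table[(dyi - dyj + m - 1) * (2 * m - 1) + (dxi - dxj + m - 1), hd]
                logits.append(float(qi @ kj) / tau[hd] + bias)
            weights = np.exp(logits - np.max(logits))
            weights /= weights.sum()
            out[i, hd] = sum(wt * qkv[j, 2, hd] for wt, j in zip(weights, members))
    merged = out.reshape(h * w, heads * d)
    return merged @ attn.proj.weight.data + attn.proj.bias.data


@pytest.mark.parametrize("shift", [0, 2])
def test_swin_attention_matches_per_neighborhood_oracle(shift):
    h, w, m, c, heads = 4, 8, 4, 8, 2
    block = _attention_only_block(c, heads, m, shift, seed=shift)
    tokens = np.random.default_rng(7 + shift).normal(size=(1, h * w, c))
    out = block(Tensor(tokens), (h, w))
    attn_branch = out.data[0] - tokens[0]
    oracle = _attention_oracle(block.attn, tokens[0], (h, w), shift)
    assert np.allclose(attn_branch, oracle, atol=1e-10)


def test_unshifted_block_blocks_cross_window_attention():
    # move one window's tokens; the other window's outputs must not change
    h, w, m, c = 4, 8, 4, 8
    block = _attention_only_block(c, 2, m, 0, seed=42)
    rng = np.random.default_rng(8)
    tokens = rng.normal(size=(1, h * w, c))
    base = block(Tensor(tokens), (h, w)).data.reshape(h, w, c)
    perturbed = tokens.reshape(h, w, c).copy()
    perturbed[:, 4:, :] += rng.normal(size=(h, 4, c))  # second window only
    out = block(Tensor(perturbed.reshape(1, -1, c)), (h, w)).data.reshape(h, w, c)
    assert np.allclose(out[:, :4], base[:, :4], atol=1e-12)
    assert not np.allclose(out[:, 4:], base[:, 4:])


def test_zero_value_projection_reduces_block_to_mlp_path():
    c = 6
    block = SwinBlock(c, 2, 3, 0, np.random.default_rng(9))
    qkv = block.attn.qkv.weight.data
    qkv[:, 2 * c:] = 0.0  # zero the value projection
    block.attn.proj.bias.data[:] = 0.0
    tokens = Tensor(np.random.default_rng(10).normal(size=(1, 36, c)))
    out = block(tokens, (6, 6))
    x = block.norm1(tokens)
    expected = block.norm2(x + block.mlp_fc2(block.mlp_fc1(x).gelu()))
    assert np.allclose(out.data, expected.data, atol=1e-12)


# --------------------------------------------------------------- global stream
def test_global_encoder_token_count_and_determinism():
    preset = get_preset("tiny")
    enc = GlobalEncoder(preset, np.random.default_rng(0))
    img = np.random.default_rng(1).random((96, 96))
    g1, g2 = enc(img), enc(img)
    side = 96 // preset.global_stride
    assert g1.tokens.shape == (1, side * side, preset.global_channels[-1])
    assert g1.grid_shape == (side, side)
    assert np.all(np.isfinite(g1.tokens.data))
    assert np.array_equal(g1.tokens.data, g2.tokens.data)


def test_early_stage_tokens_shift_with_a_full_window_input_shift():
    preset = BackbonePreset(
        name="single", input_size=96,
        local_depths=(1,), local_channels=(8,),
        global_depths=(1,), global_channels=(24,), global_heads=(2,),
        window_size=6, patch_size=8,
    )
    enc = GlobalEncoder(preset, np.random.default_rng(0))
    img = np.random.default_rng(2).random((96, 96))
    shift_px = preset.window_size * preset.patch_size  # one full window
    rolled = np.roll(img, (shift_px, shift_px), axis=(0, 1))
    t_base = enc(img).tokens.data.reshape(12, 12, 24)
    t_roll = enc(rolled).tokens.data.reshape(12, 12, 24)
    assert np.allclose(t_roll, np.roll(t_base, (6, 6), axis=(0, 1)), atol=1e-10)


def test_base_preset_reaches_1024_channels_and_validates_input():
    preset = get_preset("base")
    assert preset.local_channels[-1] == 1024
    assert preset.global_channels[-1] == 1024
    assert preset.window_size == 7
    enc = LocalEncoder(preset, np.random.default_rng(0))
    f = enc(np.random.default_rng(1).random((384, 384)).astype(np.float64))
    assert f.channels == 1024
    assert f.grid.shape[2] == 384 // preset.local_stride


def test_preset_registry_and_invariants():
    with pytest.raises(KeyError):
        get_preset("nope")
    with pytest.raises(ValueError):
        BackbonePreset(name="bad", input_size=96, local_depths=(1, 1),
                       local_channels=(32, 32), global_depths=(1,),
                       global_channels=(8,), global_heads=(1,),
                       window_size=6, patch_size=8)
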