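"""Bi-Directional Cross-Guidance (BDCG) fusion.

The two streams refine each other through reciprocal multi-head
cross-attention: the local (convolutional) tokens query the global
(transformer) tokens, F'_L = LN(F_L + MCA(Q_L, K_G, V_G)), and the global
tokens query the local ones, F'_G = LN(F_G + MCA(Q_G, K_L, V_L)).  Both
pathways run in parallel from the raw streams.  Each refined stream is then
mean-pooled over its tokens and the pooled vectors are concatenated
local-first into the fused representation Z (length C_L + C_G; 2048 for the
base presets).  The pre-pool spatial maps are retained for saliency.

Cross-attention here uses plain scaled dot-product softmax attention
(cosine attention is reserved for the global encoder's window attention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbones import GlobalTokenGrid, LocalFeatureGrid
from .nn import LayerNorm, Linear, Module, Tensor, concat
from .preprocess import resize_bilinear


# ------------------------------------------------------------------ tokenizing
def tokenize_local(f_l: LocalFeatureGrid) -> Tensor:
    """Row-major flattening of the (N, C, h, w) grid into (N, h*w, C) tokens."""
    n, c, h, w = f_l.grid.shape
    return f_l.grid.transpose(0, 2, 3, 1).reshape(n, h * w, c)


def detokenize_local(tokens: Tensor, grid_shape: tuple) -> Tensor:
    """Inverse of :func:`tokenize_local`: (N, h*w, C) -> (N, C, h, w)."""
    n, t, c = tokens.shape
    h, w = grid_shape
    return tokens.reshape(n, h, w, c).transpose(0, 3, 1, 2)


# ------------------------------------------------------------- cross-attention
def multi_head_cross_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """Per-head softmax(Q K^T / sqrt(d)) V with heads concatenated.

    ``q``: (N, heads, T_q, d); ``k``, ``v``: (N, heads, T_kv, d).
    Returns (N, T_q, heads * d).  Attention rows sum to 1, so each output
    token is a convex combination of value vectors; permuting the key/value
    token order leaves the output unchanged.
    """
    if k.shape[2] != v.shape[2]:
        raise ValueError("key and value token counts must match")
    if q.shape[1] != k.shape[1] or q.shape[3] != k.shape[3]:
        raise ValueError("query and key head count / head dim must match")
    d = q.shape[3]
    logits = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(d)
    weights = logits.softmax(axis=-1)
    out = weights @ v  # (N, heads, T_q, d)
    n, heads, tq, _ = out.shape
    return out.transpose(0, 2, 1, 3).reshape(n, tq, heads * d)


class CrossAttentionPathway(Module):
    """One guidance direction: queries from one stream, keys/values from the
    other, output projected back to the query stream's channel width."""

    def __init__(self, query_dim: int, kv_dim: int, heads: int, d_head: int,
                 rng: np.random.Generator):
        super().__init__()
        self.heads, self.d_head = heads, d_head
        inner = heads * d_head
        self.q_proj = Linear(query_dim, inner, rng)
        self.k_proj = Linear(kv_dim, inner, rng)
        self.v_proj = Linear(kv_dim, inner, rng)
        self.out_proj = Linear(inner, query_dim, rng)
        self.norm = LayerNorm(query_dim)

    def _split_heads(self, x: Tensor) -> Tensor:
        n, t, _ = x.shape
        return x.reshape(n, t, self.heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, query_tokens: Tensor, kv_tokens: Tensor) -> Tensor:
        q = self._split_heads(self.q_proj(query_tokens))
        k = self._split_heads(self.k_proj(kv_tokens))
        v = self._split_heads(self.v_proj(kv_tokens))
        mca = self.out_proj(multi_head_cross_attention(q, k, v))
        return self.norm(query_tokens + mca)


# ------------------------------------------------------------------- fusion
@dataclass
class FusedRepresentation:
    """Z plus the pre-pool spatial maps retained for Grad-CAM."""

    z: Tensor                 # (N, C_L + C_G)
    local_map: Tensor | None  # (N, C_L, h_L, w_L), refined
    global_map: Tensor | None  # (N, C_G, h_G, w_G), refined
    local_shape: tuple | None
    global_shape: tuple | None

    @property
    def dim(self) -> int:
        return self.z.shape[-1]

    def fused_spatial_map(self) -> np.ndarray:
        """Channel-concatenated map after bilinear resolution alignment
        (numpy, display/saliency only)."""
        maps = []
        shapes = [s for s in (self.local_shape, self.global_shape) if s is not None]
        target = max(shapes, key=lambda s: s[0] * s[1])
        for m in (self.local_map, self.global_map):
            if m is None:
                continue
            maps.append(align_map(m.data, target))
        return np.concatenate(maps, axis=1)


def align_map(maps: np.ndarray, target_shape: tuple) -> np.ndarray:
    """Bilinearly resize a (N, C, h, w) stack to (N, C, *target_shape*)."""
    n, c, h, w = maps.shape
    th, tw = target_shape
    if (h, w) == (th, tw):
        return maps.copy()
    out = np.empty((n, c, th, tw))
    for i in range(n):
        for j in range(c):
            out[i, j] = resize_bilinear(maps[i, j], (th, tw))
    return out


class BDCGFusion(Module):
    """The full reciprocal exchange plus concatenation/pooling into Z.

    Pathways can be disabled individually (ablations); a disabled pathway
    reduces its stream to LN(F), which is exactly the zeroed-MCA-branch
    "passive fusion" configuration.
    """

    def __init__(self, c_local: int, c_global: int, heads: int = 8,
                 d_head: int = 128, rng: np.random.Generator | None = None,
                 enable_g2l: bool = True, enable_l2g: bool = True):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.enable_g2l, self.enable_l2g = enable_g2l, enable_l2g
        if enable_g2l:
            self.g2l = CrossAttentionPathway(c_local, c_global, heads, d_head, rng)
        else:
            self.g2l_norm = LayerNorm(c_local)
        if enable_l2g:
            self.l2g = CrossAttentionPathway(c_global, c_local, heads, d_head, rng)
        else:
            self.l2g_norm = LayerNorm(c_global)

    def refine_local(self, local_tokens: Tensor, global_tokens: Tensor) -> Tensor:
        if self.enable_g2l:
            return self.g2l(local_tokens, global_tokens)
        return self.g2l_norm(local_tokens)

    def refine_global(self, global_tokens: Tensor, local_tokens: Tensor) -> Tensor:
        if self.enable_l2g:
            return self.l2g(global_tokens, local_tokens)
        return self.l2g_norm(global_tokens)

    def forward(self, f_l: LocalFeatureGrid, f_g: GlobalTokenGrid) -> FusedRepresentation:
        local_tokens = tokenize_local(f_l)
        global_tokens = f_g.tokens
        refined_l = self.refine_local(local_tokens, global_tokens)
        refined_g = self.refine_global(global_tokens, local_tokens)
        local_shape = (f_l.grid.shape[2], f_l.grid.shape[3])
        return fuse_concat_pool(refined_l, refined_g, local_shape, f_g.grid_shape)


def global_to_local_refine(f_l: LocalFeatureGrid, f_g: GlobalTokenGrid,
                           pathway: CrossAttentionPathway) -> Tensor:
    """F'_L = LN(F_L + MCA(Q_L, K_G, V_G)); output is query-shaped."""
    return pathway(tokenize_local(f_l), f_g.tokens)


def local_to_global_refine(f_g: GlobalTokenGrid, f_l: LocalFeatureGrid,
                           pathway: CrossAttentionPathway) -> Tensor:
    """F'_G = LN(F_G + MCA(Q_G, K_L, V_L)); mirror of the other pathway."""
    return pathway(f_g.tokens, tokenize_local(f_l))


def fuse_concat_pool(refined_l: Tensor, refined_g: Tensor,
                     local_shape: tuple, global_shape: tuple) -> FusedRepresentation:
    """Mean-pool each refined stream over its tokens; concatenate local-first.

    Pooling is routed through the spatial maps so that the class score is a
    function of them — saliency gradients at the maps are then well-defined.
    """
    local_map = detokenize_local(refined_l, local_shape)
    global_map = detokenize_local(refined_g, global_shape)
    pooled_l = local_map.mean(axis=(2, 3))
    pooled_g = global_map.mean(axis=(2, 3))
    z = concat([pooled_l, pooled_g], axis=-1)
    return FusedRepresentation(
        z=z,
        local_map=local_map,
        global_map=global_map,
        local_shape=local_shape,
        global_shape=global_shape,
    )
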