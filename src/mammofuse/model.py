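"""The assembled dual-stream classifier.

Composition (full configuration): local encoder and global encoder in
parallel, BDCG reciprocal cross-attention fusion, mean-pool + concatenation
into Z, and the prototype-anchored similarity head.  Component switches
reproduce the ablation variants: either encoder alone, passive fusion
(no cross-guidance), softmax head instead of PASH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbones import BackbonePreset, GlobalEncoder, LocalEncoder, get_preset
from .bdcg import BDCGFusion, FusedRepresentation, detokenize_local, tokenize_local
from .nn import LayerNorm, Linear, Module, Tensor, concat
from .pash import ClassPosterior, PashLossTerms, PrototypeHead, pash_loss


@dataclass
class ModelOutput:
    probs: Tensor                      # (N, 2) class posterior
    z: Tensor                          # (N, D) fused vector
    fused: FusedRepresentation | None  # refined spatial maps for saliency
    logits: Tensor | None              # softmax-head logits, if that head is used
    # encoder stage-4 maps (pre-normalization, magnitude-preserving):
    local_stage4: Tensor | None = None
    global_stage4: Tensor | None = None


class DualStreamClassifier(Module):
    """Configurable dual-stream model covering all ablation variants."""

    def __init__(
        self,
        preset: BackbonePreset | str = "tiny",
        rng: np.random.Generator | None = None,
        use_local: bool = True,
        use_global: bool = True,
        use_bdcg: bool = True,
        head: str = "pash",
        heads: int | None = None,
        d_head: int | None = None,
        alpha: float = 3.0,
        learnable_alpha: bool = False,
        prototype_scale: float = 0.05,
    ):
        super().__init__()
        if not (use_local or use_global):
            raise ValueError("at least one encoder stream must be enabled")
        if head not in ("pash", "softmax"):
            raise ValueError("head must be 'pash' or 'softmax'")
        if isinstance(preset, str):
            preset = get_preset(preset)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.preset = preset
        self.use_local, self.use_global = use_local, use_global
        self.use_bdcg = use_bdcg and use_local and use_global
        self.head_kind = head

        c_l = preset.local_channels[-1]
        c_g = preset.global_channels[-1]
        if use_local:
            self.local = LocalEncoder(preset, rng)
        if use_global:
            self.global_ = GlobalEncoder(preset, rng)

        if use_local and use_global:
            if heads is None:
                heads = 8 if preset.name == "base" else 2
            if d_head is None:
                d_head = 128 if preset.name == "base" else 16
            self.fusion = BDCGFusion(
                c_l, c_g, heads=heads, d_head=d_head, rng=rng,
                enable_g2l=self.use_bdcg, enable_l2g=self.use_bdcg,
            )
            dim = c_l + c_g
        elif use_local:
            self.solo_norm = LayerNorm(c_l)
            dim = c_l
        else:
            self.solo_norm = LayerNorm(c_g)
            dim = c_g
        self.fused_dim = dim

        if head == "pash":
            self.classifier = PrototypeHead(
                dim, alpha=alpha, learnable_alpha=learnable_alpha,
                rng=rng, init_scale=prototype_scale,
            )
        else:
            self.classifier = Linear(dim, 2, rng)

    # ------------------------------------------------------------------ forward
    def forward(self, images) -> ModelOutput:
        fused = None
        local_s4 = global_s4 = None
        if self.use_local and self.use_global:
            f_l = self.local(images)
            f_g = self.global_(images)
            local_s4 = f_l.grid
            global_s4 = detokenize_local(f_g.tokens, f_g.grid_shape)
            fused = self.fusion(f_l, f_g)
            z = fused.z
        elif self.use_local:
            f_l = self.local(images)
            tokens = self.solo_norm(tokenize_local(f_l))
            shape = (f_l.grid.shape[2], f_l.grid.shape[3])
            local_s4 = f_l.grid
            smap = detokenize_local(tokens, shape)
            fused = FusedRepresentation(
                z=smap.mean(axis=(2, 3)), local_map=smap,
                global_map=None, local_shape=shape, global_shape=None,
            )
            z = fused.z
        else:
            f_g = self.global_(images)
            tokens = self.solo_norm(f_g.tokens)
            global_s4 = detokenize_local(f_g.tokens, f_g.grid_shape)
            smap = detokenize_local(tokens, f_g.grid_shape)
            fused = FusedRepresentation(
                z=smap.mean(axis=(2, 3)), local_map=None,
                global_map=smap,
                local_shape=None, global_shape=f_g.grid_shape,
            )
            z = fused.z

        if self.head_kind == "pash":
            probs = self.classifier.posteriors(z)
            return ModelOutput(probs=probs, z=z, fused=fused, logits=None,
                               local_stage4=local_s4, global_stage4=global_s4)
        logits = self.classifier(z)
        return ModelOutput(probs=logits.softmax(axis=-1), z=z, fused=fused,
                           logits=logits, local_stage4=local_s4, global_stage4=global_s4)

    # --------------------------------------------------------------------- loss
    def loss(self, output: ModelOutput, labels, lambda_proto: float = 0.5) -> PashLossTerms:
        labels = np.asarray(labels, dtype=np.float64)
        if labels.ndim == 1:
            labels = np.eye(2)[labels.astype(int)]
        if self.head_kind == "pash":
            return self.classifier.loss(output.z, labels, lambda_proto)
        logp = output.logits.log_softmax(axis=-1)
        ce = -(Tensor(labels) * logp).sum(axis=-1).mean()
        zero = Tensor(0.0)
        return PashLossTerms(ce=ce, proto=zero, total=ce)

    # ------------------------------------------------------------------ predict
    def predict(self, images) -> ClassPosterior:
        out = self.forward(images)
        probs = out.probs.data
        pred = probs.argmax(axis=-1)
        conf = probs.max(axis=-1)
        ambiguous = np.isclose(probs[:, 0], probs[:, 1], rtol=0.0, atol=1e-15)
        return ClassPosterior(
            probs, np.where(ambiguous, 0, pred), np.where(ambiguous, 0.5, conf), ambiguous
        )

    def class_score(self, output: ModelOutput, class_index: int) -> Tensor:
        """Scalar-per-sample target for Grad-CAM backpropagation."""
        if self.head_kind == "pash":
            return self.classifier.class_score(output.z, class_index)
        return output.logits[:, class_index]
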