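"""Gradient-weighted class activation mapping (Grad-CAM).

For a chosen class c and a chosen spatial layer with feature maps A^k, the
channel weights are the spatially averaged gradients of the class score,
alpha_k = (1/HW) sum_ij dy^c / dA^k_ij, and the saliency map is
ReLU(sum_k alpha_k A^k), optionally upsampled to the input size and
max-normalized for display.  The class score backpropagated for the
prototype head is the pre-normalization log-kernel value of the chosen class
(the analogue of a pre-softmax logit); for a softmax head it is the logit.

The default target layer is the pre-pool fused spatial map — the channel
concatenation of the two refined streams after bilinear resolution
alignment — with the local or global stage map selectable instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bdcg import align_map
from .model import DualStreamClassifier
from .preprocess import resize_bilinear

LAYERS = ("fused", "local", "global")


@dataclass
class ActivationBundle:
    maps: np.ndarray     # (C, H', W') activations at the chosen layer
    grads: np.ndarray    # (C, H', W') d y^c / d A
    class_index: int
    class_score: float
    layer: str


@dataclass
class SaliencyMap:
    grid: np.ndarray     # (H', W') nonnegative
    upsampled: np.ndarray | None = None
    normalized: np.ndarray | None = None


def capture_activations(model: DualStreamClassifier, image: np.ndarray,
                        class_index: int, layer: str = "fused") -> ActivationBundle:
    """Forward one image, backprop the class score, and collect (A, dA)."""
    if layer not in LAYERS:
        raise ValueError(f"layer must be one of {LAYERS}")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("capture_activations expects a single 2-D image")
    model.zero_grad()
    out = model.forward(img[None])
    fused = out.fused
    if layer == "local" and out.local_stage4 is None:
        raise ValueError("model has no local stream")
    if layer == "global" and out.global_stage4 is None:
        raise ValueError("model has no global stream")
    score = model.class_score(out, class_index).sum()
    score.backward()

    def grab(t):
        if t.grad is None:
            return t.data[0], np.zeros_like(t.data[0])
        return t.data[0], t.grad[0]

    if layer == "local":
        maps, grads = grab(out.local_stage4)
    elif layer == "global":
        maps, grads = grab(out.global_stage4)
    else:
        parts_a, parts_g = [], []
        shapes = [s for s in (fused.local_shape, fused.global_shape) if s is not None]
        target = max(shapes, key=lambda s: s[0] * s[1])
        for t in (fused.local_map, fused.global_map):
            if t is None:
                continue
            a, g = grab(t)
            parts_a.append(align_map(a[None], target)[0])
            parts_g.append(align_map(g[None], target)[0])
        maps = np.concatenate(parts_a, axis=0)
        grads = np.concatenate(parts_g, axis=0)
    model.zero_grad()
    return ActivationBundle(
        maps=maps, grads=grads, class_index=int(class_index),
        class_score=float(score.data), layer=layer,
    )


def channel_weights(bundle: ActivationBundle) -> np.ndarray:
    """alpha_k = global average pooling of the gradients, per channel."""
    return bundle.grads.mean(axis=(1, 2))


def compute_cam(bundle: ActivationBundle, weights: np.ndarray | None = None,
                upsample_to: int | tuple | None = None,
                normalize: bool = False) -> SaliencyMap:
    """L^c = ReLU(sum_k alpha_k A^k); every value is nonnegative."""
    if weights is None:
        weights = channel_weights(bundle)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape[0] != bundle.maps.shape[0]:
        raise ValueError("weights length must equal the channel count")
    cam = np.maximum((weights[:, None, None] * bundle.maps).sum(axis=0), 0.0)
    sal = SaliencyMap(grid=cam)
    if upsample_to is not None:
        up = resize_bilinear(cam, upsample_to)
        sal.upsampled = np.maximum(up, 0.0)
    if normalize:
        base = sal.upsampled if sal.upsampled is not None else cam
        peak = base.max()
        sal.normalized = base / peak if peak > 0 else np.zeros_like(base)
    return sal


def lesion_saliency_hit_rate(model: DualStreamClassifier, images: np.ndarray,
                             labels: np.ndarray, masks: np.ndarray,
                             layer: str = "fused",
                             class_index: int = 1) -> tuple[float, int]:
    """Fraction of correctly classified malignant images whose mean saliency
    inside the lesion mask exceeds the mean outside.

    Returns (hit_rate, n_evaluated); images without a mask or misclassified
    are excluded.  This quantifies how lesion-localized the model's evidence
    is — a property of the trained model, not of the saliency machinery.
    """
    labels = np.asarray(labels, dtype=int)
    pred = model.predict(images).predicted_class
    hits = total = 0
    for img, mask, y, p in zip(images, masks, labels, pred):
        if y != 1 or p != 1 or not mask.any():
            continue
        bundle = capture_activations(model, img, class_index, layer)
        sal = compute_cam(bundle, upsample_to=img.shape, normalize=True)
        total += 1
        if sal.normalized[mask].mean() > sal.normalized[~mask].mean():
            hits += 1
    return (hits / total if total else 0.0), total


def explain(model: DualStreamClassifier, image: np.ndarray,
            class_index: int | None = None, layer: str = "fused") -> SaliencyMap:
    """End-to-end: predict (if no class given), capture, and map saliency."""
    if class_index is None:
        class_index = int(model.predict(np.asarray(image)[None]).predicted_class[0])
    bundle = capture_activations(model, image, class_index, layer)
    return compute_cam(bundle, upsample_to=np.asarray(image).shape, normalize=True)
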