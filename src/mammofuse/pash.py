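"""Prototype-Anchored Similarity Head (PASH).

Classification by similarity to learnable class prototypes: the fused vector
Z is compared to one prototype per class (benign = 0, malignant = 1) by
squared Euclidean distance d_k = ||Z - P_k||^2, and distances are turned into
a posterior with a Student-t kernel

    p_k  propto  (1 + d_k / alpha) ** (-(alpha + 1) / 2),

where alpha (default 3, optionally learnable through a softplus
reparameterization) governs how sharply probability falls off with distance.
The training loss is cross-entropy on the posteriors plus
lambda_proto = 0.5 times a prototype clustering pull: the label-weighted mean
squared distance of each sample to its own class prototype.

Posterior arithmetic is done in log space, so normalization holds to machine
precision for alpha spanning [0.5, 1e6].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Module, Parameter, Tensor


@dataclass
class ClassPosterior:
    probs: np.ndarray           # (N, K)
    predicted_class: np.ndarray  # (N,)
    confidence: np.ndarray       # (N,) = max_k p_k
    ambiguous: np.ndarray        # (N,) exact-tie flag


@dataclass
class PashLossTerms:
    ce: Tensor
    proto: Tensor
    total: Tensor


def init_prototypes(rng: np.random.Generator, n_classes: int, dim: int,
                    scale: float = 0.05) -> np.ndarray:
    """I.i.d. Gaussian prototype initialization; seed-reproducible."""
    return rng.normal(0.0, scale, (n_classes, dim))


def squared_distance(z: Tensor | np.ndarray, prototypes: Tensor | np.ndarray) -> Tensor:
    """d_k = ||Z - P_k||_2^2 per class; (N, D) x (K, D) -> (N, K)."""
    z = z if isinstance(z, Tensor) else Tensor(z)
    p = prototypes if isinstance(prototypes, Tensor) else Tensor(prototypes)
    if z.ndim == 1:
        z = z.reshape(1, -1)
    if z.shape[-1] != p.shape[-1]:
        raise ValueError(
            f"dimension mismatch: Z has {z.shape[-1]}, prototypes have {p.shape[-1]}"
        )
    diff = z.reshape(z.shape[0], 1, z.shape[1]) - p.reshape(1, *p.shape)
    return (diff * diff).sum(axis=-1)


def _log_kernel(d: Tensor, alpha) -> Tensor:
    """Unnormalized log Student-t kernel: -(alpha+1)/2 * log(1 + d/alpha)."""
    if isinstance(alpha, Tensor):
        return (1.0 + d / alpha).log() * ((alpha + 1.0) * (-0.5))
    return (1.0 + d * (1.0 / alpha)).log() * (-(alpha + 1.0) / 2.0)


def t_kernel_posterior(d: Tensor | np.ndarray, alpha: float = 3.0) -> Tensor:
    """Student-t posterior over classes, computed in log space."""
    d = d if isinstance(d, Tensor) else Tensor(d)
    if not np.all(np.isfinite(d.data)):
        raise ValueError("t_kernel_posterior: distances must be finite")
    a = alpha.item() if isinstance(alpha, Tensor) else float(alpha)
    if a <= 0:
        raise ValueError("alpha must be positive")
    return _log_kernel(d, alpha).softmax(axis=-1)


def pash_loss(z: Tensor, labels: np.ndarray, prototypes: Tensor,
              alpha=3.0, lambda_proto: float = 0.5) -> PashLossTerms:
    """Cross-entropy on t-kernel posteriors + lambda_proto * clustering pull.

    ``labels`` may be hard class indices or soft (MixUp) probability rows;
    soft labels weight each class pull by its mixing mass.  The cross-entropy
    uses log-softmax directly, so vanishing posteriors stay finite.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if labels.ndim == 1:
        labels = np.eye(prototypes.shape[0])[labels.astype(int)]
    d = squared_distance(z, prototypes)
    logp = _log_kernel(d, alpha).log_softmax(axis=-1)
    y = Tensor(labels)
    ce = -(y * logp).sum(axis=-1).mean()
    proto = (y * d).sum(axis=-1).mean()
    total = ce + proto * lambda_proto
    return PashLossTerms(ce=ce, proto=proto, total=total)


def predict(z, prototypes, alpha: float = 3.0) -> ClassPosterior:
    """Posterior, argmax class, confidence; exact ties resolve to class 0
    with confidence 0.5 and the ambiguous flag set."""
    probs = t_kernel_posterior(squared_distance(z, prototypes), alpha).data
    pred = probs.argmax(axis=-1)
    conf = probs.max(axis=-1)
    ambiguous = np.isclose(probs[:, 0], probs[:, 1], rtol=0.0, atol=1e-15)
    pred = np.where(ambiguous, 0, pred)
    conf = np.where(ambiguous, 0.5, conf)
    return ClassPosterior(probs, pred, conf, ambiguous)


def _softplus_inverse(y: float) -> float:
    return float(np.log(np.expm1(y)))


class PrototypeHead(Module):
    """Learnable prototypes + Student-t posterior as a trainable module."""

    def __init__(self, dim: int, n_classes: int = 2, alpha: float = 3.0,
                 learnable_alpha: bool = False,
                 rng: np.random.Generator | None = None, init_scale: float = 0.05):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.prototypes = Parameter(init_prototypes(rng, n_classes, dim, init_scale))
        self.learnable_alpha = learnable_alpha
        if learnable_alpha:
            self.alpha_raw = Parameter(np.array([_softplus_inverse(alpha)]))
        else:
            self._alpha = float(alpha)

    @property
    def alpha(self):
        if self.learnable_alpha:
            # softplus keeps alpha positive while staying unconstrained underneath;
            # the floor guards against float underflow at very negative raw values
            return (self.alpha_raw.exp() + 1.0).log().clamp_min(1e-6)
        return self._alpha

    def posteriors(self, z: Tensor) -> Tensor:
        return t_kernel_posterior(squared_distance(z, self.prototypes), self.alpha)

    def loss(self, z: Tensor, labels, lambda_proto: float = 0.5) -> PashLossTerms:
        return pash_loss(z, labels, self.prototypes, self.alpha, lambda_proto)

    def predict(self, z) -> ClassPosterior:
        alpha = self.alpha
        a = alpha.item() if isinstance(alpha, Tensor) else alpha
        return predict(z if isinstance(z, Tensor) else Tensor(z),
                       self.prototypes.detach(), a)

    def class_score(self, z: Tensor, class_index: int) -> Tensor:
        """Grad-CAM target: the kernel log-odds of the chosen class.

        For a prototype classifier the analogue of a pre-softmax logit is the
        contrast log k_c - log k_other: its gradient points along the fixed
        prototype axis (P_c - P_other), whereas the single-class log-kernel
        gradient direction (P_c - Z) collapses to noise once Z sits near its
        prototype.
        """
        d = squared_distance(z, self.prototypes)
        lk = _log_kernel(d, self.alpha)
        other = 1 - class_index if self.prototypes.shape[0] == 2 else None
        if other is None:
            return lk[:, class_index]
        return lk[:, class_index] - lk[:, other]
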