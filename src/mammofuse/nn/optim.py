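"""Optimization utilities: AdamW with decoupled weight decay and an EMA shadow."""

from __future__ import annotations

import numpy as np


class AdamW:
    """AdamW (decoupled weight decay regularization).

    Defaults mirror the training configuration used throughout the package:
    lr 1e-4, betas (0.9, 0.999), weight decay 0.05.
    """

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.05,
                 decay_mask=None):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        # decay_mask[i] == False exempts a parameter (norm gains, biases,
        # temperatures, prototypes) from weight decay
        self.decay_mask = (
            list(decay_mask) if decay_mask is not None else [True] * len(self.params)
        )
        if len(self.decay_mask) != len(self.params):
            raise ValueError("decay_mask length must match params")
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            wd = self.weight_decay if self.decay_mask[i] else 0.0
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + wd * p.data
            )

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(step: int, total_steps: int, base_lr: float,
              warmup_steps: int = 0, floor: float = 0.0) -> float:
    """Cosine-annealed learning rate with a linear warm-up ramp.

    Ramps 0 -> base_lr over ``warmup_steps``, then decays with
    ``base_lr * 0.5 * (1 + cos(pi * progress))`` down to ``floor``.
    """
    if warmup_steps >= total_steps:
        raise ValueError("warmup_steps must be smaller than total_steps")
    if not 0 <= step <= total_steps:
        raise ValueError("step outside [0, total_steps]")
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * step / warmup_steps
    progress = (step - warmup_steps) / max(1, total_steps - warmup_steps)
    lr = base_lr * 0.5 * (1.0 + np.cos(np.pi * progress))
    return max(lr, floor)


class EMA:
    """Exponential moving average of a parameter tree (decay 0.999 default)."""

    def __init__(self, module, decay: float = 0.999):
        if not 0.0 <= decay <= 1.0:
            raise ValueError("decay must be in [0, 1]")
        self.decay = float(decay)
        self.shadow = {k: v.copy() for k, v in module.state_dict().items()}

    def update(self, module):
        state = dict(module.named_parameters())
        if set(state) != set(self.shadow):
            raise ValueError("parameter tree mismatch between EMA shadow and module")
        d = self.decay
        for k, p in state.items():
            self.shadow[k] = d * self.shadow[k] + (1.0 - d) * p.data

    def copy_to(self, module):
        module.load_state_dict(self.shadow)

    def state_dict(self):
        return {k: v.copy() for k, v in self.shadow.items()}
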