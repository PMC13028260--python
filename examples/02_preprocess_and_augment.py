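"""Image conditioning and online augmentation on one synthetic mammogram.

Shows the deterministic path (CLAHE -> min-max -> resize) and one stochastic
training draw (geometric + RandAugment), then a MixUp pair.  Every printed
range stays inside [0, 1], the model's input contract.
"""

import numpy as np

from mammofuse import (AugmentationPolicy, generate_breast_image, mixup,
                       preprocess_pipeline)
from mammofuse.synthetic import SyntheticImageSpec

rng = np.random.default_rng(1)
raw, mask = generate_breast_image(SyntheticImageSpec(size=96, label=1), rng)
raw = raw * 4095.0  # simulate a higher dynamic range acquisition

eval_img = preprocess_pipeline(raw, train_mode=False, target_size=96)
print("deterministic path:", " -> ".join(eval_img.provenance))
print(f"  output range [{eval_img.pixels.min():.3f}, {eval_img.pixels.max():.3f}], "
      f"shape {eval_img.pixels.shape}")

policy = AugmentationPolicy()  # RandAugment N=2 M=9, rotation ±10°, flip 0.5
train_img = preprocess_pipeline(raw, train_mode=True, policy=policy,
                                rng=np.random.default_rng(7), target_size=96)
diff = np.abs(train_img.pixels - eval_img.pixels).mean()
print(f"one stochastic training draw changes mean intensity by {diff:.4f}")

batch = np.stack([eval_img.pixels, 1.0 - eval_img.pixels])
mixed = mixup(batch, np.array([0, 1]), alpha=0.3, rng=np.random.default_rng(3))
print(f"MixUp lambdas: {np.round(mixed.lambdas, 3)}; "
      f"soft labels sum to {mixed.soft_labels.sum(axis=1)}")
# Lambdas come from Beta(0.3, 0.3), so draws concentrate near 0 and 1:
# most mixed images stay close to one parent.
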