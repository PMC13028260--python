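"""Training loop and ablation harness.

Training follows the configured recipe: AdamW (decoupled weight decay 0.05),
cosine-annealed learning rate with linear warm-up (default warm-up 5% of
steps), batch size 16 (reduced automatically for smaller datasets), online
augmentation plus MixUp, composite PASH loss (CE + 0.5 x prototype pull),
and an EMA shadow of the weights (decay 0.999).  Everything is driven by a
single seed; the loss trajectory on CPU is reproducible bit-for-bit.

The ablation harness trains the six structural variants (either encoder
alone with a softmax head, passive fusion, BDCG without PASH, the full model
with and without CLAHE) under an identical seed, split and data pipeline.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import evalproto
from .model import DualStreamClassifier
from .nn import EMA, AdamW, cosine_lr, no_grad
from .preprocess import AugmentationPolicy, mixup, preprocess_pipeline, \
    rand_augment, random_geometric_augment
from .synthetic import SyntheticCohort


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 0.05
    batch_size: int = 16
    epochs: int = 80
    steps: int | None = None       # overrides epochs when set (desk-scale runs)
    warmup_frac: float = 0.05
    lr_floor: float = 0.0
    adam_beta2: float = 0.999
    ema_decay: float = 0.999
    seed: int = 42
    preset: str = "tiny"
    lambda_proto: float = 0.5
    alpha: float = 3.0
    learnable_alpha: bool = False
    augment: bool = True
    mixup: bool = True
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("rates and counts must be positive")
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValueError("ema_decay must lie in [0, 1)")


@dataclass
class TrainResult:
    model: DualStreamClassifier
    ema: EMA
    history: list
    config: TrainConfig


def ema_update(ema_weights: dict, weights: dict, decay: float) -> dict:
    """Functional EMA step: ema <- decay * ema + (1 - decay) * w per parameter."""
    if set(ema_weights) != set(weights):
        raise ValueError("parameter trees do not match")
    return {k: decay * ema_weights[k] + (1.0 - decay) * weights[k] for k in weights}


def _augment_batch(images: np.ndarray, policy: AugmentationPolicy,
                   rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(images)
    for i, img in enumerate(images):
        a = random_geometric_augment(img, policy, rng)
        out[i] = rand_augment(a, policy.n_ops, policy.magnitude, rng)
    return out


def train(model: DualStreamClassifier, images: np.ndarray, labels: np.ndarray,
          config: TrainConfig, log_path=None) -> TrainResult:
    """Seeded training of a model on preprocessed images.

    Aborts with a diagnostic if the loss becomes non-finite.  History rows
    carry step, learning rate and loss terms; a JSON-lines log is written
    when ``log_path`` is given.
    """
    rng = np.random.default_rng(config.seed)
    n = len(images)
    if n == 0:
        raise ValueError("empty training set")
    labels = np.asarray(labels)
    batch_size = min(config.batch_size, n)
    steps_per_epoch = max(1, n // batch_size)
    total_steps = config.steps if config.steps else config.epochs * steps_per_epoch
    warmup = int(round(config.warmup_frac * total_steps))

    named = list(model.named_parameters())
    no_decay = ("norm", "bias", "tau", "rel_bias", "prototypes", "alpha")
    mask = [not any(tag in name for tag in no_decay) for name, _ in named]
    opt = AdamW([p for _, p in named], lr=config.lr,
                betas=(0.9, config.adam_beta2),
                weight_decay=config.weight_decay, decay_mask=mask)
    ema = EMA(model, decay=config.ema_decay)
    history = []
    log_file = open(log_path, "w") if log_path else None

    step = 0
    t0 = time.time()
    while step < total_steps:
        perm = rng.permutation(n)
        for start in range(0, steps_per_epoch * batch_size, batch_size):
            if step >= total_steps:
                break
            idx = perm[start : start + batch_size]
            batch = images[idx]
            y = labels[idx]
            if config.augment:
                batch = _augment_batch(batch, config.policy, rng)
            if config.mixup and len(idx) >= 2:
                mb = mixup(batch, y, alpha=config.policy.mixup_alpha, rng=rng)
                batch, soft = mb.images, mb.soft_labels
            else:
                soft = np.eye(2)[y.astype(int)]
            out = model(batch)
            terms = model.loss(out, soft, lambda_proto=config.lambda_proto)
            if not np.isfinite(terms.total.data):
                raise RuntimeError(
                    f"training diverged at step {step}: loss={terms.total.data}"
                )
            model.zero_grad()
            terms.total.backward()
            opt.lr = cosine_lr(step, total_steps, config.lr, warmup, config.lr_floor)
            opt.step()
            ema.update(model)
            rec = {
                "step": step, "lr": opt.lr,
                "loss": float(terms.total.data),
                "ce": float(terms.ce.data),
                "proto": float(terms.proto.data),
            }
            history.append(rec)
            if log_file:
                log_file.write(json.dumps(rec) + "\n")
            step += 1
    if log_file:
        log_file.write(json.dumps({"seconds": time.time() - t0, "seed": config.seed}) + "\n")
        log_file.close()
    return TrainResult(model=model, ema=ema, history=history, config=config)


def evaluate(model: DualStreamClassifier, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 32) -> evalproto.FoldMetrics:
    """Hard-prediction metrics plus AUROC/AUPRC from the malignant posterior."""
    preds, scores = [], []
    with no_grad():
        for start in range(0, len(images), batch_size):
            out = model(images[start : start + batch_size])
            p = out.probs.data
            preds.append(p.argmax(axis=-1))
            scores.append(p[:, 1])
    y_pred = np.concatenate(preds)
    scores = np.concatenate(scores)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        return evalproto.evaluate_predictions(labels, y_pred)
    return evalproto.evaluate_predictions(labels, y_pred, scores)


# --------------------------------------------------------------- checkpoints
def save_checkpoint(path, model: DualStreamClassifier, ema: EMA | None = None):
    state = {f"model/{k}": v for k, v in model.state_dict().items()}
    if ema is not None:
        state.update({f"ema/{k}": v for k, v in ema.state_dict().items()})
    np.savez(path, **state)


def load_checkpoint(path, model: DualStreamClassifier, use_ema: bool = False):
    data = np.load(path)
    prefix = "ema/" if use_ema else "model/"
    wanted = {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
    model.load_state_dict(wanted)
    return model


# ------------------------------------------------------------------ ablation
@dataclass(frozen=True)
class AblationVariant:
    id: str
    use_local: bool
    use_global: bool
    use_bdcg: bool
    use_pash: bool
    use_clahe: bool


ABLATION_GRID = [
    AblationVariant("cnn_only", True, False, False, False, True),
    AblationVariant("vit_only", False, True, False, False, True),
    AblationVariant("passive_fusion", True, True, False, False, True),
    AblationVariant("bdcg_no_pash", True, True, True, False, True),
    AblationVariant("full_no_clahe", True, True, True, True, False),
    AblationVariant("full", True, True, True, True, True),
]


def build_variant(variant: AblationVariant, config: TrainConfig) -> DualStreamClassifier:
    return DualStreamClassifier(
        preset=config.preset,
        rng=np.random.default_rng(config.seed),
        use_local=variant.use_local,
        use_global=variant.use_global,
        use_bdcg=variant.use_bdcg,
        head="pash" if variant.use_pash else "softmax",
        alpha=config.alpha,
        learnable_alpha=config.learnable_alpha,
    )


def prepare_cohort(cohort: SyntheticCohort, target_size: int,
                   use_clahe: bool = True) -> np.ndarray:
    """Deterministic conditioning of every cohort image (no augmentation)."""
    return np.stack([
        preprocess_pipeline(img, train_mode=False, target_size=target_size,
                            use_clahe=use_clahe).pixels
        for img in cohort.images
    ])


def run_ablation(grid, cohort: SyntheticCohort, config: TrainConfig,
                 seeds=(0, 1, 2)) -> pd.DataFrame:
    """Train and evaluate each variant under identical seeds and splits."""
    from .backbones import get_preset

    size = get_preset(config.preset).input_size
    split = evalproto.patient_level_split(cohort.table, 0.2, seed=config.seed)
    is_test = cohort.table["patient_id"].isin(split.test_patients).to_numpy()
    labels = cohort.table["label"].to_numpy()
    prepared = {
        flag: prepare_cohort(cohort, size, use_clahe=flag)
        for flag in {v.use_clahe for v in grid}
    }
    rows = []
    for variant in grid:
        images = prepared[variant.use_clahe]
        for seed in seeds:
            cfg = TrainConfig(**{**asdict_config(config), "seed": int(seed)})
            model = build_variant(variant, cfg)
            train(model, images[~is_test], labels[~is_test], cfg)
            m = evaluate(model, images[is_test], labels[is_test])
            rows.append({"variant": variant.id, "seed": seed, **m.as_dict()})
    return pd.DataFrame(rows)


def asdict_config(config: TrainConfig) -> dict:
    d = asdict(config)
    d["policy"] = config.policy  # keep the dataclass, not its dict form
    return d
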