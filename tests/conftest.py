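import numpy as np
import pytest

from mammofuse import DualStreamClassifier, generate_cohort
from mammofuse.engine import TrainConfig, prepare_cohort, train


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    return DualStreamClassifier("tiny", rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(24, malignant_frac=0.35, seed=7, size=96)


@pytest.fixture(scope="session")
def prepared_small_cohort(small_cohort):
    images = prepare_cohort(small_cohort, 96)
    labels = small_cohort.table["label"].to_numpy()
    return images, labels


# Desk-scale training recipe for the tiny preset trained from scratch: no
# warm-up, a hotter learning rate with a floor (full cosine decay wastes the
# final steps at this run length), and a faster-adapting second moment.
OVERFIT_CONFIG = dict(steps=200, lr=3e-2, lr_floor=1e-2, adam_beta2=0.99,
                      augment=False, mixup=False, batch_size=16, warmup_frac=0.0)


@pytest.fixture(scope="session")
def overfit_run():
    """Tiny model overfit on 32 synthetic images (shared across tests)."""
    cohort = generate_cohort(24, malignant_frac=0.4, seed=42, size=96)
    images = prepare_cohort(cohort, 96)[:32]
    labels = cohort.table["label"].to_numpy()[:32]
    masks = cohort.masks[:32]
    model = DualStreamClassifier("tiny", rng=np.random.default_rng(42))
    result = train(model, images, labels, TrainConfig(seed=42, **OVERFIT_CONFIG))
    return model, images, labels, masks, result
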