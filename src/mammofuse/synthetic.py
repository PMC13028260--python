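"""Seeded generators for synthetic mammogram-like cohorts and embeddings.

The image generator emulates the gross appearance cues a screening
classifier learns from: an elliptical breast region on a dark background,
band-limited noise texture standing in for fibroglandular tissue, and for
the malignant class either a bright mass with radial spicule strokes or a
cluster of small high-intensity dots (microcalcifications).  Benign images
carry a low-contrast smooth blob or no lesion.  Every image comes with a
lesion mask, every cohort with patient structure (1-3 images per patient,
patient-consistent class, configurable malignant fraction), and everything
is deterministic under (seed, parameters).

The embedding generator draws two isotropic Gaussian clouds at a configured
separation, used to exercise the prototype head in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

LESION_KINDS = ("mass", "microcalcification_cluster", "none")


@dataclass
class SyntheticImageSpec:
    size: int = 96
    label: int = 1                      # 0 benign, 1 malignant
    lesion_kind: str = "mass"
    texture_sigma_frac: float = 1 / 24  # smoothing scale of the tissue texture
    texture_amplitude: float = 0.10
    lesion_contrast: float = 0.45       # lesion brightness over local tissue

    def __post_init__(self):
        if self.lesion_kind not in LESION_KINDS:
            raise ValueError(f"lesion_kind must be one of {LESION_KINDS}")
        if self.label == 1 and self.lesion_kind == "none":
            raise ValueError("malignant images must carry a lesion")


@dataclass
class SyntheticCohort:
    table: pd.DataFrame                  # patient_id, image_index, label
    images: np.ndarray                   # (n_images, size, size)
    masks: np.ndarray                    # (n_images, size, size) bool
    seed: int
    params: dict = field(default_factory=dict)


def _breast_region(size: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = size * (0.5 + rng.uniform(-0.04, 0.04))
    cx = size * (0.38 + rng.uniform(-0.04, 0.04))
    ry = size * rng.uniform(0.36, 0.42)
    rx = size * rng.uniform(0.30, 0.36)
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _lesion_center(breast: np.ndarray, margin: float, rng: np.random.Generator):
    eroded = ndimage.binary_erosion(breast, iterations=max(1, int(margin)))
    ys, xs = np.nonzero(eroded if eroded.any() else breast)
    i = rng.integers(len(ys))
    return ys[i], xs[i]


def _add_mass(img, breast, spec, rng):
    size = spec.size
    mask = np.zeros_like(img, dtype=bool)
    for _ in range(6):  # shrink radius until the lesion fits the area budget
        radius = size * rng.uniform(0.05, 0.10)
        cy, cx = _lesion_center(breast, radius + 2, rng)
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / radius ** 2
        blob = spec.lesion_contrast * np.exp(-1.5 * r2)
        core = (r2 <= 1.0) & breast
        area_frac = core.sum() / max(breast.sum(), 1)
        if 0.01 <= area_frac <= 0.15:
            img += blob * breast
            mask = core
            # radial spicule strokes
            n_spicules = rng.integers(6, 13)
            for k in range(n_spicules):
                theta = 2 * np.pi * k / n_spicules + rng.uniform(-0.2, 0.2)
                length = radius * rng.uniform(1.4, 2.4)
                ts = np.linspace(0, 1, int(3 * length) + 2)
                py = np.clip(np.round(cy + ts * length * np.sin(theta)), 0, size - 1).astype(int)
                px = np.clip(np.round(cx + ts * length * np.cos(theta)), 0, size - 1).astype(int)
                img[py, px] += spec.lesion_contrast * 0.5 * (1 - ts)
            return img, mask
    img += blob * breast
    return img, core


def _add_microcalcifications(img, breast, spec, rng):
    size = spec.size
    cluster_r = size * rng.uniform(0.08, 0.13)
    cy, cx = _lesion_center(breast, cluster_r + 2, rng)
    n_dots = rng.integers(5, 16)
    mask = np.zeros_like(img, dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for _ in range(n_dots):
        ang = rng.uniform(0, 2 * np.pi)
        rad = cluster_r * np.sqrt(rng.uniform(0, 1))
        dy, dx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        dot_r = rng.uniform(1.0, 2.2)
        d2 = (yy - dy) ** 2 + (xx - dx) ** 2
        dot = d2 <= dot_r ** 2
        img[dot] += spec.lesion_contrast * 1.1
        mask |= dot
    mask &= breast
    return img, mask


def _add_benign_blob(img, breast, spec, rng):
    size = spec.size
    radius = size * rng.uniform(0.05, 0.09)
    cy, cx = _lesion_center(breast, radius + 2, rng)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / radius ** 2
    img += 0.30 * spec.lesion_contrast * np.exp(-1.5 * r2) * breast
    return img, ((r2 <= 1.0) & breast)


def generate_breast_image(spec: SyntheticImageSpec, rng: np.random.Generator):
    """One synthetic mammogram-like image in [0, 1] plus its lesion mask."""
    size = spec.size
    breast = _breast_region(size, rng)
    img = np.full((size, size), 0.02)
    base = 0.30 + rng.uniform(-0.03, 0.03)
    texture = ndimage.gaussian_filter(
        rng.normal(0, 1, (size, size)), sigma=max(1.0, size * spec.texture_sigma_frac)
    )
    texture = texture / max(np.abs(texture).max(), 1e-9) * spec.texture_amplitude
    img = img + breast * (base + texture)

    if spec.label == 1:
        if spec.lesion_kind == "mass":
            img, mask = _add_mass(img, breast, spec, rng)
        else:
            img, mask = _add_microcalcifications(img, breast, spec, rng)
    else:
        if spec.lesion_kind == "none":
            mask = np.zeros_like(breast)
        else:
            img, mask = _add_benign_blob(img, breast, spec, rng)
    return np.clip(img, 0.0, 1.0), mask


def generate_cohort(n_patients: int, malignant_frac: float = 0.3,
                    seed: int = 0, size: int = 96) -> SyntheticCohort:
    """A patient-structured cohort: 1-3 images per patient (mean about 1.5),
    patient-consistent class, deterministic under the seed."""
    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    rng = np.random.default_rng(seed)
    rows, images, masks = [], [], []
    for pid in range(n_patients):
        label = int(rng.random() < malignant_frac)
        n_images = rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1])
        for _ in range(n_images):
            if label == 1:
                kind = "mass" if rng.random() < 0.6 else "microcalcification_cluster"
            else:
                kind = "mass" if rng.random() < 0.5 else "none"
            spec = SyntheticImageSpec(size=size, label=label, lesion_kind=kind)
            img, mask = generate_breast_image(spec, rng)
            rows.append({
                "patient_id": f"P{pid:05d}",
                "image_index": len(images),
                "label": label,
                "lesion_kind": kind,
            })
            images.append(img)
            masks.append(mask)
    table = pd.DataFrame(rows)
    return SyntheticCohort(
        table=table, images=np.stack(images), masks=np.stack(masks), seed=seed,
        params={"n_patients": n_patients, "malignant_frac": malignant_frac, "size": size},
    )


def cohort_to_disk(cohort: SyntheticCohort, out_dir) -> pd.DataFrame:
    """Write images/masks as PNG and the patient table as CSV; returns the
    table with file paths added."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    table = cohort.table.copy()
    paths = []
    for i in range(len(table)):
        p = out / "images" / f"img{i:05d}.png"
        iio.imwrite(p, (cohort.images[i] * 65535).astype(np.uint16))
        iio.imwrite(out / "masks" / f"mask{i:05d}.png",
                    (cohort.masks[i] * 255).astype(np.uint8))
        paths.append(str(p))
    table["image_path"] = paths
    table.to_csv(out / "patients.csv", index=False)
    return table


@dataclass
class EmbeddingFixture:
    samples: np.ndarray   # (2n, D)
    labels: np.ndarray    # (2n,)
    means: np.ndarray     # (2, D) true class means
    sigma: float


def embedding_fixture(n_per_class: int, dim: int, separation: float = 6.0,
                      sigma: float = 1.0, seed: int = 0) -> EmbeddingFixture:
    """Two isotropic Gaussians with mean distance separation * sigma."""
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    direction = rng.normal(0, 1, dim)
    direction /= np.linalg.norm(direction)
    mu0 = np.zeros(dim)
    mu1 = direction * separation * sigma
    x0 = rng.normal(0, sigma, (n_per_class, dim)) + mu0
    x1 = rng.normal(0, sigma, (n_per_class, dim)) + mu1
    samples = np.concatenate([x0, x1])
    labels = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    perm = rng.permutation(len(labels))
    return EmbeddingFixture(samples[perm], labels[perm], np.stack([mu0, mu1]), sigma)


def masked_intensity_baseline(cohort: SyntheticCohort) -> float:
    """Accuracy of the trivial threshold baseline on mean lesion-region
    intensity (breast-region mean where the mask is empty) — a floor check
    that the cohort carries learnable signal."""
    feats = []
    for img, mask in zip(cohort.images, cohort.masks):
        if mask.any():
            feats.append(img[mask].mean())
        else:
            feats.append(img[img > 0.1].mean())
    feats = np.asarray(feats)
    labels = cohort.table["label"].to_numpy()
    best = 0.0
    for t in np.quantile(feats, np.linspace(0.02, 0.98, 49)):
        acc = max(((feats > t) == labels).mean(), ((feats <= t) == labels).mean())
        best = max(best, acc)
    return float(best)
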