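"""Image conditioning and online augmentation for mammography-like inputs.

Deterministic conditioning (applied to every image):

1. CLAHE — contrast-limited adaptive histogram equalization, the standard
   per-tile equalization with clipped histograms and uniform redistribution
   of the clipped mass, with bilinear blending between tile mappings.  The
   clip limit follows the common convention of a multiple of the uniform bin
   height (default 2.0).
2. Min–max normalization to [0, 1].
3. Bilinear resize to the model input size (default 384 x 384; the tiny
   presets use 96 x 96).

Stochastic augmentation (training data only): a bounded geometric policy
(rotation, translation, shear, horizontal flip), a RandAugment-style policy
restricted to grayscale-safe, morphology-preserving operations, and batch
level MixUp with Beta(alpha, alpha) mixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------- I/O
def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF (8/16-bit) or DICOM file as a float 2-D array.

    DICOM MONOCHROME1 images (white-is-low) are inverted so that higher values
    always mean brighter tissue.
    """
    path = str(path)
    if path.lower().endswith((".dcm", ".dicom")):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
            arr = arr.max() - arr
        return arr
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:  # collapse accidental RGB to luminance
        arr = arr.mean(axis=-1)
    return arr


# ------------------------------------------------------------------ conditioning
def apply_clahe(
    image: np.ndarray,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
    n_bins: int = 256,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is quantized to ``n_bins`` levels over its own dynamic range,
    tiled into ``tile_grid`` tiles (reflect-padded to an exact multiple), and
    each tile's histogram is clipped at ``clip_limit`` times the uniform bin
    height with the excess redistributed uniformly.  Per-tile equalization
    maps level v to ``cdf(v) / tile_pixels * (n_bins - 1)``; pixel values are
    bilinearly blended between the four neighbouring tile mappings.  A
    constant image (zero dynamic range) passes through unchanged.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("apply_clahe expects a nonempty 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("apply_clahe: image contains non-finite pixels")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return img.copy()

    gh, gw = int(tile_grid[0]), int(tile_grid[1])
    h, w = img.shape
    th = -(-h // gh)  # ceil division
    tw = -(-w // gw)
    pad_h, pad_w = gh * th - h, gw * tw - w
    padded = np.pad(img, ((0, pad_h), (0, pad_w)), mode="edge")

    levels = np.clip(
        ((padded - lo) / (hi - lo) * (n_bins - 1)).round().astype(np.int64), 0, n_bins - 1
    )

    tile_pixels = th * tw
    clip = max(clip_limit * tile_pixels / n_bins, 1.0)
    luts = np.empty((gh, gw, n_bins))
    for ty in range(gh):
        for tx in range(gw):
            tile = levels[ty * th : (ty + 1) * th, tx * tw : (tx + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=n_bins).astype(np.float64)
            excess = np.maximum(hist - clip, 0.0).sum()
            hist = np.minimum(hist, clip) + excess / n_bins
            cdf = np.cumsum(hist)
            luts[ty, tx] = cdf / tile_pixels * (n_bins - 1)

    hp, wp = padded.shape
    ys = (np.arange(hp) + 0.5) / th - 0.5  # tile-grid coordinates
    xs = (np.arange(wp) + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, gh - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, gw - 1)
    y1 = np.minimum(y0 + 1, gh - 1)
    x1 = np.minimum(x0 + 1, gw - 1)
    fy = np.clip(ys - y0, 0.0, 1.0)[:, None]
    fx = np.clip(xs - x0, 0.0, 1.0)[None, :]

    yy0, xx0 = y0[:, None], x0[None, :]
    yy1, xx1 = y1[:, None], x1[None, :]
    out_levels = (
        (1 - fy) * (1 - fx) * luts[yy0, xx0, levels]
        + (1 - fy) * fx * luts[yy0, xx1, levels]
        + fy * (1 - fx) * luts[yy1, xx0, levels]
        + fy * fx * luts[yy1, xx1, levels]
    )
    out = lo + out_levels / (n_bins - 1) * (hi - lo)
    return out[:h, :w]


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Min–max scale to [0, 1]; a constant image maps to all zeros (guarded)."""
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("minmax_normalize expects a nonempty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("minmax_normalize: image contains non-finite pixels")
    lo, hi = img.min(), img.max()
    if hi == lo:
        warnings.warn("constant image: min–max normalization returns all zeros")
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def resize_bilinear(image: np.ndarray, target_size: int | tuple[int, int]) -> np.ndarray:
    """Bilinear resize with the half-pixel center convention, clipped to [0, 1]
    when the input lies in [0, 1]."""
    img = np.asarray(image, dtype=np.float64)
    if isinstance(target_size, int):
        target_size = (target_size, target_size)
    oh, ow = int(target_size[0]), int(target_size[1])
    if oh < 1 or ow < 1:
        raise ValueError("target size must be >= 1")
    h, w = img.shape
    if (oh, ow) == (h, w):
        return img.copy()
    ys = np.clip((np.arange(oh) + 0.5) * (h / oh) - 0.5, 0, h - 1)
    xs = np.clip((np.arange(ow) + 0.5) * (w / ow) - 0.5, 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    out = (
        (1 - wy) * (1 - wx) * img[np.ix_(y0, x0)]
        + (1 - wy) * wx * img[np.ix_(y0, x1)]
        + wy * (1 - wx) * img[np.ix_(y1, x0)]
        + wy * wx * img[np.ix_(y1, x1)]
    )
    if img.min() >= 0.0 and img.max() <= 1.0:
        out = np.clip(out, 0.0, 1.0)
    return out


# ------------------------------------------------------------------ augmentation
@dataclass
class AugmentationPolicy:
    """Bounded stochastic policy: RandAugment(N, M) plus rotation/flip.

    Defaults follow the training recipe: two RandAugment operations at
    magnitude 9 (of 30), rotation within ±10 degrees, horizontal flip with
    probability 0.5, small translations and shears.
    """

    n_ops: int = 2
    magnitude: int = 9
    rotation_limit_deg: float = 10.0
    hflip_prob: float = 0.5
    translate_frac: float = 0.05
    shear_deg: float = 5.0
    mixup_alpha: float = 0.3

    def __post_init__(self):
        if self.n_ops < 0:
            raise ValueError("n_ops must be >= 0")
        if not 0 <= self.magnitude <= 30:
            raise ValueError("magnitude must lie in [0, 30]")
        if self.rotation_limit_deg < 0 or self.shear_deg < 0 or self.translate_frac < 0:
            raise ValueError("geometric magnitudes must be nonnegative")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must lie in [0, 1]")


@dataclass
class MixUpBatch:
    images: np.ndarray
    soft_labels: np.ndarray
    lambdas: np.ndarray


@dataclass
class PreprocessedImage:
    pixels: np.ndarray
    provenance: list = field(default_factory=list)


def _affine(image: np.ndarray, angle_deg: float = 0.0, tx: float = 0.0, ty: float = 0.0,
            shear_x_deg: float = 0.0, shear_y_deg: float = 0.0) -> np.ndarray:
    """Apply a centered affine transform with reflection padding, bilinear."""
    theta = np.deg2rad(angle_deg)
    shx = np.tan(np.deg2rad(shear_x_deg))
    shy = np.tan(np.deg2rad(shear_y_deg))
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shear = np.array([[1.0, shy], [shx, 1.0]])
    mat = rot @ shear  # output->input mapping in (row, col) order
    center = (np.asarray(image.shape) - 1) / 2.0
    offset = center - mat @ center - np.array([ty, tx])
    return ndimage.affine_transform(image, mat, offset=offset, order=1, mode="reflect")


def random_geometric_augment(
    image: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator
) -> np.ndarray:
    """One stochastic compose of rotation, translation, shear, horizontal flip."""
    h, w = image.shape
    angle = rng.uniform(-policy.rotation_limit_deg, policy.rotation_limit_deg)
    tx = rng.uniform(-policy.translate_frac, policy.translate_frac) * w
    ty = rng.uniform(-policy.translate_frac, policy.translate_frac) * h
    sx = rng.uniform(-policy.shear_deg, policy.shear_deg)
    sy = rng.uniform(-policy.shear_deg, policy.shear_deg)
    out = image
    if angle or tx or ty or sx or sy:
        out = _affine(image, angle, tx, ty, sx, sy)
    if policy.hflip_prob > 0 and rng.random() < policy.hflip_prob:
        out = out[:, ::-1].copy()
    return np.clip(out, 0.0, 1.0)


# RandAugment op pool: grayscale-safe, morphology-preserving transforms only.
def _op_identity(img, frac, rng):
    return img


def _op_rotate(img, frac, rng):
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return _affine(img, angle_deg=sign * frac * 10.0)


def _op_translate_x(img, frac, rng):
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return _affine(img, tx=sign * frac * 0.2 * img.shape[1])


def _op_translate_y(img, frac, rng):
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return _affine(img, ty=sign * frac * 0.2 * img.shape[0])


def _op_shear_x(img, frac, rng):
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return _affine(img, shear_x_deg=sign * frac * 10.0)


def _op_shear_y(img, frac, rng):
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return _affine(img, shear_y_deg=sign * frac * 10.0)


def _op_brightness(img, frac, rng):
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return img * (1.0 + sign * frac * 0.6)


def _op_contrast(img, frac, rng):
    sign = 1.0 if rng.random() < 0.5 else -1.0
    mean = img.mean()
    return mean + (1.0 + sign * frac * 0.6) * (img - mean)


def _op_sharpness(img, frac, rng):
    sign = 1.0 if rng.random() < 0.5 else -1.0
    blurred = ndimage.gaussian_filter(img, sigma=1.0, mode="reflect")
    return img + sign * frac * 0.9 * (img - blurred)


def _op_autocontrast(img, frac, rng):
    lo, hi = img.min(), img.max()
    if hi == lo:
        return img
    return (img - lo) / (hi - lo)


def _op_equalize(img, frac, rng):
    lo, hi = img.min(), img.max()
    if hi == lo:
        return img
    n_bins = 256
    levels = np.clip(((img - lo) / (hi - lo) * (n_bins - 1)).round().astype(int), 0, n_bins - 1)
    cdf = np.cumsum(np.bincount(levels.ravel(), minlength=n_bins))
    return cdf[levels] / img.size


DEFAULT_OP_POOL = {
    "identity": _op_identity,
    "rotate": _op_rotate,
    "translate_x": _op_translate_x,
    "translate_y": _op_translate_y,
    "shear_x": _op_shear_x,
    "shear_y": _op_shear_y,
    "brightness": _op_brightness,
    "contrast": _op_contrast,
    "sharpness": _op_sharpness,
    "autocontrast": _op_autocontrast,
    "equalize": _op_equalize,
}


def rand_augment(
    image: np.ndarray,
    n_ops: int = 2,
    magnitude: int = 9,
    rng: np.random.Generator | None = None,
    op_pool: dict | None = None,
) -> np.ndarray:
    """RandAugment-style policy: ``n_ops`` operations sampled uniformly with
    replacement from a grayscale-safe pool, each at shared magnitude M/30."""
    if op_pool is None:
        op_pool = DEFAULT_OP_POOL
    if not op_pool:
        raise ValueError("rand_augment: the operation pool is empty")
    if rng is None:
        rng = np.random.default_rng()
    names = sorted(op_pool)
    frac = magnitude / 30.0
    out = image
    for _ in range(int(n_ops)):
        op = op_pool[names[rng.integers(len(names))]]
        out = op(out, frac, rng)
    return np.clip(out, 0.0, 1.0)


def mixup(
    images: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.3,
    rng: np.random.Generator | None = None,
) -> MixUpBatch:
    """MixUp: convex combinations of random image pairs and their labels.

    Each sample i is paired with a random permutation partner j and mixed with
    a per-pair coefficient lambda ~ Beta(alpha, alpha) shared between the
    image pair and the label pair.
    """
    if alpha <= 0:
        raise ValueError("mixup alpha must be positive")
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if labels.ndim == 1:  # class indices -> one-hot
        eye = np.eye(2)
        labels = eye[labels.astype(int)]
    n = images.shape[0]
    if n < 2:
        warnings.warn("mixup on a batch of size 1 is a passthrough (lambda = 1)")
        return MixUpBatch(images.copy(), labels.copy(), np.ones(n))
    if rng is None:
        rng = np.random.default_rng()
    perm = rng.permutation(n)
    lam = rng.beta(alpha, alpha, size=n)
    lam_img = lam.reshape((n,) + (1,) * (images.ndim - 1))
    mixed = lam_img * images + (1.0 - lam_img) * images[perm]
    soft = lam[:, None] * labels + (1.0 - lam[:, None]) * labels[perm]
    return MixUpBatch(mixed, soft, lam)


# ---------------------------------------------------------------------- pipeline
def preprocess_pipeline(
    raw: np.ndarray,
    train_mode: bool = False,
    policy: AugmentationPolicy | None = None,
    rng: np.random.Generator | None = None,
    target_size: int = 384,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
    use_clahe: bool = True,
) -> PreprocessedImage:
    """CLAHE -> min–max -> resize; stochastic augmentation only in train mode.

    Evaluation/test images (``train_mode=False``) receive no stochastic
    transforms and the output is a deterministic function of the input.
    MixUp operates at batch level and is applied separately by the trainer.
    """
    provenance = []
    img = np.asarray(raw, dtype=np.float64)
    if use_clahe:
        img = apply_clahe(img, clip_limit=clip_limit, tile_grid=tile_grid)
        provenance.append(f"clahe(clip={clip_limit},tiles={tile_grid})")
    if img.max() == img.min():
        img = np.zeros_like(img)
        provenance.append("minmax(constant->zeros)")
    else:
        img = minmax_normalize(img)
        provenance.append("minmax")
    img = resize_bilinear(img, target_size)
    provenance.append(f"resize({target_size})")
    if train_mode:
        if policy is None:
            policy = AugmentationPolicy()
        if rng is None:
            rng = np.random.default_rng()
        img = random_geometric_augment(img, policy, rng)
        provenance.append("geometric")
        img = rand_augment(img, policy.n_ops, policy.magnitude, rng)
        provenance.append(f"randaugment(n={policy.n_ops},m={policy.magnitude})")
    return PreprocessedImage(img, provenance)
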