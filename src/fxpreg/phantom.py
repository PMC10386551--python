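"""Synthetic B-mode-like phantoms and fixed/moving training pairs.

Real B-mode ultrasound is a grayscale image whose tissue texture is dominated
by multiplicative speckle: the envelope amplitude of fully developed speckle
is Rayleigh distributed, and display units apply a log compression.  The
generator emulates exactly that structure so the registration network sees
data with realistic low-contrast, speckled statistics:

1. a smooth "anatomy" field — a sum of 3..8 random Gaussian blobs over a
   gentle background gradient;
2. multiplied by an i.i.d. Rayleigh speckle field (unit mean);
3. log-compressed and rescaled to [0, 1], replicated to 3 channels.

Pair generation mirrors the augmentation study design: each source phantom is
augmented with one random similarity transform (scale in [1.4, 3.2], rotation
in [-25, 25] deg, translation in [-30, 30] px per axis), resized to 32x16x3,
and turned into one fixed/moving pair.  The ground truth stored with a pair
is the *registering* motion (the one that maps moving back onto fixed),
drawn uniformly with rot in [-11, 11] deg and dx, dy in [-10, 10] px; the
moving image is created by warping the fixed image with the inverse of that
motion.  Targets are normalized to [-1, 1] by the generation bounds
(11, 10, 10).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .rigid import (
    NORM_DIVISORS,
    RigidParams,
    image_center,
    invert,
    params_to_matrix,
    warp_image,
)

__all__ = [
    "PAIR_SHAPE",
    "ROT_RANGE_DEG",
    "SHIFT_RANGE_PX",
    "AUG_SCALE_RANGE",
    "AUG_ROT_RANGE_DEG",
    "AUG_SHIFT_RANGE_PX",
    "ImagePair",
    "DatasetSplit",
    "generate_phantom",
    "speckle_field",
    "augment",
    "make_pair",
    "normalize_inputs",
    "concat_pair",
    "split_pair",
    "split_counts",
    "build_dataset",
    "load_image_folder",
]

# Network input geometry: two 32x16x3 half-images concatenated to 32x32x3.
PAIR_SHAPE = (32, 16, 3)

# Pair-generation (ground truth) ranges; also the target normalization.
ROT_RANGE_DEG = 11.0
SHIFT_RANGE_PX = 10.0

# Augmentation draw ranges.
AUG_SCALE_RANGE = (1.4, 3.2)
AUG_ROT_RANGE_DEG = 25.0
AUG_SHIFT_RANGE_PX = 30.0

# Default split fractions: train / val / test, mirroring 8184/1842/204 of
# 10,230 pairs.
DEFAULT_SPLIT = (0.80, 0.18, 0.02)
DEFAULT_N_IMAGES = 10230


@dataclass(frozen=True)
class ImagePair:
    """A fixed/moving image pair with its registering ground truth."""

    fixed: np.ndarray
    moving: np.ndarray
    gt: RigidParams
    seed: int = -1

    @property
    def gt_norm(self) -> np.ndarray:
        return self.gt.normalized()


@dataclass
class DatasetSplit:
    train: list = field(default_factory=list)
    val: list = field(default_factory=list)
    test: list = field(default_factory=list)
    seed: int = 0

    def __iter__(self):
        yield from (self.train, self.val, self.test)


def speckle_field(shape, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean Rayleigh speckle (envelope-amplitude model)."""
    sigma = 1.0 / np.sqrt(np.pi / 2.0)  # Rayleigh mean = sigma*sqrt(pi/2)
    return rng.rayleigh(scale=sigma, size=shape)


def generate_phantom(seed: int, height: int = 96, width: int = 64) -> np.ndarray:
    """Deterministic ultrasound-like phantom, ``height x width x 3`` in [0, 1].

    Smooth anatomy (3..8 Gaussian blobs on a depth gradient) times Rayleigh
    speckle, log-compressed. Raises for dimensions below 32 px.
    """
    if height < 32 or width < 32:
        raise ValueError("phantom dimensions must be at least 32 px")
    rng = np.random.default_rng(seed)
    ys, xs = np.mgrid[0:height, 0:width].astype(float)

    # Gentle depth-dependent background, as in time-gain-compensated B-mode.
    anatomy = 0.25 + 0.1 * (1.0 - ys / height)
    n_blobs = rng.integers(3, 9)
    for _ in range(n_blobs):
        cx = rng.uniform(0, width)
        cy = rng.uniform(0, height)
        sx = rng.uniform(width / 10, width / 3)
        sy = rng.uniform(height / 10, height / 3)
        amp = rng.uniform(0.3, 1.0) * rng.choice([-0.5, 1.0])
        anatomy = anatomy + amp * np.exp(
            -(((xs - cx) / sx) ** 2 + ((ys - cy) / sy) ** 2) / 2.0
        )
    anatomy = np.clip(anatomy, 0.02, None)

    envelope = anatomy * speckle_field((height, width), rng)
    alpha = 30.0  # display log-compression strength
    img = np.log1p(alpha * envelope) / np.log1p(alpha)
    img -= img.min()
    img /= img.max()
    return np.repeat(img[:, :, None], 3, axis=2)


def normalize_inputs(img: np.ndarray) -> np.ndarray:
    """Map image intensities to [0, 1] floats; 8-bit inputs divide by 255."""
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    img = img.astype(float)
    if img.size and img.max() > 1.0:  # other integer-coded inputs
        return img / 255.0
    return img


def _similarity_matrix(scale, rot_deg, tx, ty, center) -> np.ndarray:
    rot = params_to_matrix(RigidParams(rot_deg, tx, ty), center)
    s = np.diag([scale, scale, 1.0])
    cx, cy = center
    zoom = (
        np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
        @ s
        @ np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    )
    return rot @ zoom


def augment(img: np.ndarray, rng: np.random.Generator, draw=None) -> np.ndarray:
    """One random similarity augmentation, then resize to 32x16x3.

    Scale in [1.4, 3.2], rotation in [-25, 25] deg, translation in
    [-30, 30] px per axis, all uniform.  ``draw`` forces the tuple
    ``(scale, rot_deg, tx, ty)`` (used in tests).
    """
    img = normalize_inputs(img)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if draw is None:
        draw = (
            rng.uniform(*AUG_SCALE_RANGE),
            rng.uniform(-AUG_ROT_RANGE_DEG, AUG_ROT_RANGE_DEG),
            rng.uniform(-AUG_SHIFT_RANGE_PX, AUG_SHIFT_RANGE_PX),
            rng.uniform(-AUG_SHIFT_RANGE_PX, AUG_SHIFT_RANGE_PX),
        )
    scale, rot_deg, tx, ty = draw
    T = _similarity_matrix(scale, rot_deg, tx, ty, image_center(img))
    warped = warp_image(img, T)
    out = resize(warped, PAIR_SHAPE[:2], order=1, anti_aliasing=True)
    return np.clip(out, 0.0, 1.0)


def make_pair(
    fixed: np.ndarray, rng: np.random.Generator, draw=None, seed: int = -1
) -> ImagePair:
    """Draw a ground-truth rigid motion and synthesize the moving image.

    The stored ground truth is the registering motion (moving -> fixed),
    drawn uniformly with rot in [-11, 11] deg, dx/dy in [-10, 10] px, so its
    normalized form lies in [-1, 1]^3 exactly.  The moving image is the fixed
    image warped by the inverse of that motion.
    """
    fixed = np.asarray(fixed, dtype=float)
    if fixed.shape != PAIR_SHAPE:
        raise ValueError(f"fixed image must have shape {PAIR_SHAPE}")
    if draw is None:
        draw = (
            rng.uniform(-ROT_RANGE_DEG, ROT_RANGE_DEG),
            rng.uniform(-SHIFT_RANGE_PX, SHIFT_RANGE_PX),
            rng.uniform(-SHIFT_RANGE_PX, SHIFT_RANGE_PX),
        )
    gt = RigidParams(*draw)
    center = image_center(fixed)
    moving = warp_image(fixed, invert(params_to_matrix(gt, center)))
    return ImagePair(fixed=fixed, moving=moving, gt=gt, seed=seed)


def concat_pair(fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Concatenate along width: fixed in columns 0-15, moving in 16-31."""
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != PAIR_SHAPE or moving.shape != PAIR_SHAPE:
        raise ValueError(f"both images must have shape {PAIR_SHAPE}")
    return np.concatenate([fixed, moving], axis=1)


def split_pair(x: np.ndarray):
    """Inverse of :func:`concat_pair`."""
    w = PAIR_SHAPE[1]
    return x[:, :w, :].copy(), x[:, w:, :].copy()


def split_counts(n: int, fractions=DEFAULT_SPLIT) -> tuple[int, int, int]:
    """Train/val/test counts for ``n`` pairs.

    Train is rounded, test is rounded down, validation takes the remainder;
    this reproduces 8184/1842/204 at n=10,230 and 80/18/2 at n=100.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("split must be three non-negative fractions")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    n_train = int(round(fractions[0] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_val = n - n_train - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("degenerate split")
    return n_train, n_val, n_test


def build_dataset(
    n_images: int = DEFAULT_N_IMAGES,
    pairs_per_image: int = 1,
    seed: int = 0,
    split=DEFAULT_SPLIT,
    phantom_size=(96, 64),
) -> DatasetSplit:
    """Generate phantoms, augment, pair, and split deterministically.

    Each augmented image spawns ``pairs_per_image`` pairs (default one, so
    the default configuration yields 10,230 pairs split 8184/1842/204).
    Every source phantom's seed is recorded on its pairs; phantoms are never
    shared across splits, so test pairs are unseen during training.
    """
    n_total = n_images * pairs_per_image
    n_train, n_val, n_test = split_counts(n_total, split)
    ss = np.random.SeedSequence(seed)
    phantom_seeds = ss.generate_state(n_images).astype(np.int64)
    rng = np.random.default_rng(ss.spawn(1)[0])

    pairs = []
    for i in range(n_images):
        src = generate_phantom(int(phantom_seeds[i]), *phantom_size)
        fixed = augment(src, rng)
        for _ in range(pairs_per_image):
            pairs.append(make_pair(fixed, rng, seed=int(phantom_seeds[i])))
    return DatasetSplit(
        train=pairs[:n_train],
        val=pairs[n_train : n_train + n_val],
        test=pairs[n_train + n_val :],
        seed=seed,
    )


def export_dataset(ds: DatasetSplit, out_dir) -> None:
    """Write PNG pairs plus a JSON manifest of ids, params and seeds."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": ds.seed, "pairs": []}
    for split_name, pairs in zip(("train", "val", "test"), ds):
        d = out / split_name
        d.mkdir(exist_ok=True)
        for i, pair in enumerate(pairs):
            for tag, img in (("fixed", pair.fixed), ("moving", pair.moving)):
                arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
                Image.fromarray(arr).save(d / f"{i:06d}_{tag}.png")
            manifest["pairs"].append(
                {
                    "split": split_name,
                    "id": i,
                    "rot_deg": pair.gt.rot_deg,
                    "dx_px": pair.gt.dx_px,
                    "dy_px": pair.gt.dy_px,
                    "gt_norm": pair.gt_norm.tolist(),
                    "phantom_seed": pair.seed,
                }
            )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_image_folder(folder, seed: int = 0, pairs_per_image: int = 1) -> list:
    """Apply the resize/augment/pair pipeline to a folder of PNG/JPEG images.

    Resampling uses bilinear interpolation with anti-aliasing (the choice is
    this loader's own; see the methods note).
    """
    from pathlib import Path

    from PIL import Image

    rng = np.random.default_rng(seed)
    pairs = []
    files = sorted(
        p
        for p in Path(folder).iterdir()
        if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    for f in files:
        img = normalize_inputs(np.asarray(Image.open(f).convert("RGB")))
        fixed = augment(img, rng)
        for _ in range(pairs_per_image):
            pairs.append(make_pair(fixed, rng))
    return pairs
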