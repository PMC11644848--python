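"""Synthetic endoscopy-like images and feature tables with known structure.

Real gastrointestinal image collections (Kvasir-style folders of labeled
endoscopy frames) are large downloads; every stage of this package is
instead testable against generated stand-ins whose ground truth is known
by construction:

* images carry one localized class signature — a colored, textured
  Gaussian blob at a class-specific position — so that attribution maps
  can be checked against the known signature location;
* feature matrices contain a planted set of informative columns
  (class-mean-shifted Gaussians) among pure-noise columns, so feature
  rankers and iterative selectors can be checked for signal recovery.

All generators are pure functions of their arguments, including the seed.
"""

from __future__ import annotations

import colorsys
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticImageSet",
    "SyntheticFeatureSet",
    "make_images",
    "make_features",
    "write_image_folder",
]


@dataclass
class SyntheticImageSet:
    """Labeled synthetic RGB images in [0, 1] with known class signatures.

    ``blob_centers`` holds the class-signature center of every class in
    fractional (row, col) coordinates and ``blob_radius`` the signature's
    Gaussian radius as a fraction of image size; downstream tests use
    them to check that attribution maps localize the signature.
    """

    images: np.ndarray  # (n, H, W, 3) float in [0, 1]
    labels: np.ndarray  # (n,) int
    class_names: list[str]
    seed: int
    blob_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    blob_radius: float = 0.0

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class SyntheticFeatureSet:
    """Feature matrix with a planted set of informative columns."""

    X: np.ndarray  # (n, p)
    y: np.ndarray  # (n,) int
    informative_idx: np.ndarray  # sorted planted column indices
    seed: int


def _class_palette(n_classes: int) -> np.ndarray:
    """Evenly spaced fully saturated hues, one RGB triple per class."""
    return np.array(
        [colorsys.hsv_to_rgb(c / n_classes, 1.0, 1.0) for c in range(n_classes)]
    )


def make_images(n_classes: int, n_per_class: int, size: int = 224, seed: int = 0) -> SyntheticImageSet:
    """Generate a balanced labeled image set with localized class signatures.

    Each class has a deterministic visual signature: a Gaussian blob of a
    class-specific hue at a class-specific position on a ring around the
    image center, overlaid with a sinusoidal texture whose frequency and
    orientation are also class-specific.  Backgrounds are gray Gaussian
    noise.  Blob centers jitter slightly per image, staying well inside
    the signature region recorded in ``blob_centers``.

    Parameters
    ----------
    n_classes : number of classes (>= 2).
    n_per_class : images generated per class (> 0).
    size : square image side in pixels (>= 32).
    seed : RNG seed; identical arguments give bit-identical output.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(seed)
    palette = _class_palette(n_classes)
    # half-step angular offset keeps signatures off the principal axes,
    # where they would straddle coarse pooling-grid boundaries
    angles = 2.0 * np.pi * (np.arange(n_classes) + 0.5) / n_classes
    centers = 0.5 + 0.27 * np.stack([np.sin(angles), np.cos(angles)], axis=1)
    radius = 0.16  # fraction of image side

    yy, xx = np.mgrid[0:size, 0:size] / size
    images = np.empty((n_classes * n_per_class, size, size, 3), dtype=np.float32)
    labels = np.empty(n_classes * n_per_class, dtype=np.int64)
    i = 0
    for c in range(n_classes):
        freq = 4 + 3 * c  # texture cycles across the image
        theta = np.pi * c / n_classes  # texture orientation
        for _ in range(n_per_class):
            bg = 0.45 + 0.08 * rng.standard_normal((size, size, 3))
            jitter = rng.uniform(-0.03, 0.03, size=2)
            cy, cx = centers[c] + jitter
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            w = np.exp(-d2 / (2.0 * radius**2 / 4.0))  # sigma = radius/2
            tex = 0.5 + 0.5 * np.sin(
                2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta))
            )
            fg = palette[c][None, None, :] * (0.55 + 0.45 * tex[..., None])
            img = bg * (1.0 - w[..., None]) + fg * w[..., None]
            images[i] = np.clip(img, 0.0, 1.0)
            labels[i] = c
            i += 1
    class_names = [f"class_{c:02d}" for c in range(n_classes)]
    return SyntheticImageSet(images=images, labels=labels, class_names=class_names,
                             seed=seed, blob_centers=centers, blob_radius=radius)


def make_features(
    n: int,
    p: int,
    n_informative: int,
    n_classes: int = 2,
    effect: float = 1.0,
    seed: int = 0,
) -> SyntheticFeatureSet:
    """Generate a feature matrix with planted class-informative columns.

    Informative columns are class-mean-shifted Gaussians: for a column
    with random sign s, class c has mean ``s * effect * (c/(K-1) - 1/2)``,
    so the total span of class means is exactly ``effect`` standard
    deviations.  All other columns are label-independent standard normal
    noise.  With ``effect=0`` every column is exchangeable noise.
    """
    if n_informative > p:
        raise ValueError("n_informative cannot exceed p")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    y = rng.permutation(np.arange(n) % n_classes).astype(np.int64)
    X = rng.standard_normal((n, p))
    informative = np.sort(rng.choice(p, size=n_informative, replace=False))
    class_offsets = np.arange(n_classes) / (n_classes - 1) - 0.5
    for j in informative:
        s = rng.choice([-1.0, 1.0])
        X[:, j] += s * effect * class_offsets[y]
    return SyntheticFeatureSet(X=X, y=y, informative_idx=informative, seed=seed)


def write_image_folder(image_set: SyntheticImageSet, root_path) -> None:
    """Write the image set as a class-per-subdirectory folder of 8-bit PNGs."""
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    counters = {c: 0 for c in range(image_set.n_classes)}
    for img, label in zip(image_set.images, image_set.labels):
        cls_dir = root / image_set.class_names[int(label)]
        cls_dir.mkdir(exist_ok=True)
        arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(cls_dir / f"img_{counters[int(label)]:05d}.png")
        counters[int(label)] += 1
    logger.info("wrote %d images to %s", len(image_set.images), root)
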