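"""Grad-CAM explanation, ROI thresholding, and deep feature extraction.

The feature-extraction phase of the pipeline is explainability-driven:
for each image a Grad-CAM score map is computed against the model's
predicted class, thresholded at mean x sqrt(2) into a region-of-interest
mask, and the masked image is passed back through the network so the
global-average-pooling (GAP) layer yields a deep feature vector whose
length equals the final stage's channel count (2048 for the full
architecture).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from . import _nn
from .arch import TrainedModel

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreMap",
    "ROIMask",
    "FeatureVector",
    "FeatureTable",
    "grad_cam",
    "threshold_mask",
    "extract_features",
    "build_feature_table",
    "save_feature_table",
    "load_feature_table",
]

SQRT2 = math.sqrt(2.0)


@dataclass
class ScoreMap:
    """Per-pixel Grad-CAM relevance for one image and one target class."""

    values: np.ndarray  # (H, W), >= 0, image resolution
    target_class: int
    source_layer: str = "pre_gap"

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score map contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("score map must be non-negative")


@dataclass
class ROIMask:
    """Boolean region-of-interest mask from mean x sqrt(2) thresholding."""

    mask: np.ndarray  # (H, W) bool
    threshold: float
    fallback: bool = False  # True when an empty mask fell back to full image

    @property
    def coverage(self) -> float:
        return float(self.mask.mean())


@dataclass
class FeatureVector:
    """One GAP-layer deep feature vector for one (masked) image."""

    values: np.ndarray
    image_id: int = -1
    target_class_used: int = -1

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


@dataclass
class FeatureTable:
    """n_samples x n_features matrix with labels, one row per image."""

    X: np.ndarray
    y: np.ndarray
    target_classes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    fallback_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")


def grad_cam(model: TrainedModel, image: np.ndarray, target_class="predicted") -> ScoreMap:
    """Standard Grad-CAM score map for one image.

    Channel weights are the spatial means of the target-class logit's
    gradient with respect to the final pre-GAP activated map (after the
    attention combination); the map is the ReLU of the weighted channel
    sum, bilinearly upsampled to image resolution.

    ``target_class`` may be an integer label or ``"predicted"`` (the
    default), in which case the model's own argmax prediction is used so
    test labels never leak into the explanation.
    """
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape[:2]
    if (h, w) != tuple(model.spec.input_size[:2]):
        raise ValueError(
            f"image size {(h, w)} does not match model input {model.spec.input_size[:2]}"
        )
    out = model.forward(image[None], training=False)
    logits, source = out["logits"], out["pre_gap"]
    if target_class == "predicted":
        target = int(np.argmax(logits.data[0]))
    else:
        target = int(target_class)
        if not 0 <= target < model.n_classes:
            raise ValueError(f"target class {target} out of range")
    seed = np.zeros_like(logits.data)
    seed[0, target] = 1.0
    logits.backward(seed)
    activations = source.data[0]  # (C, h, w)
    grads = source.grad[0]
    model.net.zero_grad()  # parameter grads from this sweep are not reused
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * activations).sum(axis=0), 0.0)
    if cam.shape != (h, w):
        cam = _sk_resize(cam, (h, w), order=1, mode="edge", anti_aliasing=False,
                         preserve_range=True)
    return ScoreMap(values=np.ascontiguousarray(cam, dtype=np.float64),
                    target_class=target)


def threshold_mask(score_map: ScoreMap) -> ROIMask:
    """Threshold a score map at mean x sqrt(2) into an ROI mask.

    Pixels strictly above the threshold form the region of interest.  A
    constant map can never exceed its own mean x sqrt(2), so an empty
    mask falls back to the full-image mask (logged, flagged).
    """
    values = score_map.values
    threshold = float(values.mean() * SQRT2)
    mask = values > threshold
    if not mask.any():
        logger.warning(
            "empty ROI mask (threshold %.6g); falling back to full image", threshold
        )
        return ROIMask(mask=np.ones_like(mask), threshold=threshold, fallback=True)
    return ROIMask(mask=mask, threshold=threshold)


def _apply_mask(image: np.ndarray, roi: ROIMask, mode: str, side: int) -> np.ndarray:
    if mode == "mask":
        return image * roi.mask[..., None]
    if mode == "crop":
        rows = np.flatnonzero(roi.mask.any(axis=1))
        cols = np.flatnonzero(roi.mask.any(axis=0))
        crop = image[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
        return _sk_resize(crop, (side, side), order=1, mode="edge",
                          anti_aliasing=False, preserve_range=True).astype(np.float32)
    raise ValueError("roi mode must be 'mask' or 'crop'")


def extract_features(model: TrainedModel, image: np.ndarray, roi: ROIMask,
                     roi_mode: str = "mask") -> FeatureVector:
    """GAP-layer deep features of the ROI-restricted image.

    ``mask`` mode zeroes pixels outside the ROI at their native position
    (preserving spatial registration with the GAP layer); ``crop`` mode
    crops the ROI bounding box and resizes it to the model input.
    """
    image = np.asarray(image, dtype=np.float32)
    if roi.mask.shape != image.shape[:2]:
        raise ValueError("mask and image dimensions do not match")
    masked = _apply_mask(image, roi, roi_mode, model.input_side)
    gap = model.forward(masked[None], training=False)["gap"]
    return FeatureVector(values=gap.data[0].astype(np.float64))


def build_feature_table(model: TrainedModel, images: np.ndarray, labels: np.ndarray,
                        target_class="predicted", roi_mode: str = "mask") -> FeatureTable:
    """Grad-CAM -> threshold -> masked GAP features for a stack of images.

    Row order equals input order.  Any single-image failure aborts with
    the offending image index; empty-mask fallbacks are recorded per
    image, not dropped.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("no images given")
    rows, targets, fallbacks = [], [], []
    for i in range(len(images)):
        try:
            smap = grad_cam(model, images[i], target_class=target_class)
            roi = threshold_mask(smap)
            fv = extract_features(model, images[i], roi, roi_mode=roi_mode)
        except Exception as exc:  # re-raise with image context
            raise RuntimeError(f"feature extraction failed on image {i}: {exc}") from exc
        if roi.fallback:
            fallbacks.append(i)
        rows.append(fv.values)
        targets.append(smap.target_class)
    if fallbacks:
        logger.info("full-image fallback used for %d/%d images", len(fallbacks), len(images))
    return FeatureTable(
        X=np.vstack(rows),
        y=labels.copy(),
        target_classes=np.asarray(targets),
        fallback_ids=fallbacks,
    )


def save_feature_table(table: FeatureTable, path) -> None:
    np.savez(
        path,
        X=table.X,
        y=table.y,
        target_classes=table.target_classes,
        fallback_ids=np.asarray(table.fallback_ids, dtype=int),
    )


def load_feature_table(path) -> FeatureTable:
    with np.load(path) as npz:
        return FeatureTable(
            X=npz["X"],
            y=npz["y"],
            target_classes=npz["target_classes"],
            fallback_ids=[int(i) for i in npz["fallback_ids"]],
        )
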