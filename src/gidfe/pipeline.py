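"""End-to-end orchestration: data -> model -> features -> selection -> fusion.

``run_pipeline`` executes the whole deep-feature-engineering chain on a
class-per-subdirectory image folder or on generated synthetic data:

1. train (or load) the network;
2. Grad-CAM -> mean x sqrt(2) ROI mask -> GAP features per image;
3. iterative feature selection with each configured ranker;
4. kNN and SVM cross-validated outcomes per selected feature matrix;
5. iterative majority voting and greedy selection of the final outcome.

Every stage's artifact is persisted (NPZ/CSV/JSON) and a run manifest —
config echo, per-stage seeds and timings, all outcome accuracies, the
winner — is written alongside, sufficient to re-run bit-identically.
A master seed fans out to per-stage seeds by fixed offsets so stages can
also be re-run standalone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .arch import ArchitectureSpec, TrainConfig, TrainedModel, build_model, load_model, train_model
from .explain import build_feature_table, save_feature_table
from .fixtures import make_images
from .fuse import FusionResult, greedy_final, imv, knn_outcome, make_folds, svm_outcome
from .select import RANKERS, iterative_select, save_selection

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "load_image_folder",
]

# fixed fan-out offsets from the master seed, one per stage
SEED_OFFSETS = {"model": 11, "select": 23, "folds": 37}

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Either ``data_root`` (a class-per-subdirectory image folder) or
    ``fixture`` (keyword arguments for :func:`gidfe.fixtures.make_images`)
    must be given.  At the defaults the selector x classifier product is
    8 outcomes and voting adds 6 more.
    """

    data_root: str | None = None
    fixture: dict | None = None
    model_path: str | None = None  # load this checkpoint instead of training
    arch: ArchitectureSpec = field(default_factory=ArchitectureSpec.tiny)
    train: TrainConfig = field(default_factory=TrainConfig)
    roi_mode: str = "mask"
    selectors: tuple[str, ...] = RANKERS
    sv: int = 100
    fv: int = 768
    classifiers: tuple[str, ...] = ("knn", "svm")
    imv_range: tuple[int, int] = (3, 8)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.data_root is None and self.fixture is None:
            raise ValueError("either data_root or fixture must be configured")
        unknown = set(self.selectors) - set(RANKERS)
        if unknown:
            raise ValueError(f"unknown selectors: {sorted(unknown)}")
        if set(self.classifiers) - {"knn", "svm"}:
            raise ValueError("classifiers must be a subset of ('knn', 'svm')")
        if not (3 <= self.imv_range[0] <= self.imv_range[1] <= 8):
            raise ValueError("imv_range must lie within [3, 8]")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load a YAML/JSON config file; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "arch" in raw and isinstance(raw["arch"], dict):
            raw["arch"] = ArchitectureSpec.from_dict(raw["arch"])
        if "train" in raw and isinstance(raw["train"], dict):
            raw["train"] = TrainConfig(**raw["train"])
        for key in ("selectors", "classifiers", "imv_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["arch"] = self.arch.to_dict()
        return d


@dataclass
class RunManifest:
    """Everything needed to reproduce a run and audit its outcome."""

    config: dict
    seeds: dict
    timings: dict
    accuracies: list[dict]
    winner: dict
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seeds": self.seeds,
                "timings": self.timings,
                "accuracies": self.accuracies,
                "winner": self.winner,
                "warnings": self.warnings,
            },
            indent=2,
        )


def load_image_folder(root, size: int | None = None):
    """Read a class-per-subdirectory image folder.

    Deterministic ordering (class directory name, then file name, both
    lexicographic); images converted to RGB, optionally resized with
    bilinear interpolation to ``size`` x ``size``, scaled to [0, 1].
    Grayscale images are replicated to three channels by the RGB
    conversion; non-image files are ignored with a warning.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"{root} must contain at least 2 class subdirectories")
    images, labels = [], []
    class_names = [d.name for d in class_dirs]
    for ci, d in enumerate(class_dirs):
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in IMAGE_SUFFIXES:
                logger.warning("ignoring non-image file %s", f)
                continue
            try:
                with Image.open(f) as im:
                    im = im.convert("RGB")
                    if size is not None and im.size != (size, size):
                        im = im.resize((size, size), Image.BILINEAR)
                    images.append(np.asarray(im, dtype=np.float32) / 255.0)
            except Exception as exc:
                raise RuntimeError(f"unreadable image file {f}: {exc}") from exc
            labels.append(ci)
    if not images:
        raise ValueError(f"no readable images under {root}")
    return np.stack(images), np.asarray(labels, dtype=np.int64), class_names


def _prepare_data(cfg: PipelineConfig):
    side = cfg.arch.input_size[0]
    if cfg.data_root is not None:
        images, labels, class_names = load_image_folder(cfg.data_root, size=side)
        return images, labels, class_names
    fixture = dict(cfg.fixture)
    fixture.setdefault("size", side)
    fixture.setdefault("seed", cfg.seed)
    image_set = make_images(**fixture)
    if image_set.images.shape[1] != side:
        raise ValueError("fixture image size must match the architecture input size")
    return image_set.images, image_set.labels, image_set.class_names


def _prepare_model(cfg: PipelineConfig, images, labels, class_names) -> TrainedModel:
    if cfg.model_path is not None:
        model = load_model(cfg.model_path)
        if model.spec.input_size != cfg.arch.input_size:
            raise ValueError("checkpoint input size does not match configured arch")
        return model
    n_classes = len(class_names)
    model = build_model(cfg.arch, n_classes, seed=cfg.seed + SEED_OFFSETS["model"])
    model.class_names = list(class_names)
    train_cfg = dataclasses.replace(cfg.train, seed=cfg.seed + SEED_OFFSETS["model"])
    return train_model(model, images, labels, train_cfg)


def run_pipeline(cfg: PipelineConfig) -> tuple[FusionResult, RunManifest]:
    """Execute the full pipeline; returns the fusion result and manifest."""
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings_log: list[str] = []

    t0 = time.perf_counter()
    images, labels, class_names = _prepare_data(cfg)
    timings["data"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    model = _prepare_model(cfg, images, labels, class_names)
    timings["model"] = time.perf_counter() - t0
    if out_dir and cfg.model_path is None:
        model.save(out_dir / "model.npz")

    t0 = time.perf_counter()
    table = build_feature_table(model, images, labels, roi_mode=cfg.roi_mode)
    timings["extract"] = time.perf_counter() - t0
    if table.fallback_ids:
        warnings_log.append(
            f"full-image ROI fallback on images {table.fallback_ids}"
        )
    if out_dir:
        save_feature_table(table, out_dir / "features.npz")

    select_seed = cfg.seed + SEED_OFFSETS["select"]
    selections = {}
    t0 = time.perf_counter()
    for ranker in cfg.selectors:
        selections[ranker] = iterative_select(
            table.X, table.y, ranker, sv=cfg.sv, fv=cfg.fv, seed=select_seed
        )
        if out_dir:
            save_selection(selections[ranker], out_dir / f"sel_{ranker}.npz")
    timings["select"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    folds = make_folds(table.y, seed=cfg.seed + SEED_OFFSETS["folds"])
    outcomes = []
    for clf_name in cfg.classifiers:  # classifier-major: 4 kNN then 4 SVM
        for ranker in cfg.selectors:
            s = selections[ranker].s
            if clf_name == "knn":
                outcomes.append(knn_outcome(s, table.y, folds=folds,
                                            source=(ranker, "knn")))
            else:
                outcomes.append(svm_outcome(s, table.y, folds=folds,
                                            source=(ranker, "svm")))
    timings["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    lo, hi = cfg.imv_range
    if hi > len(outcomes):
        warnings_log.append(
            f"IMV range clipped from {cfg.imv_range} to (min({lo},{len(outcomes)}), "
            f"{len(outcomes)}) for {len(outcomes)} outcomes"
        )
        hi = len(outcomes)
        lo = min(lo, hi)
    voted = imv(outcomes, table.y, i_range=(lo, hi))
    result = greedy_final(outcomes + voted, table.y, n_classes=len(class_names))
    timings["fuse"] = time.perf_counter() - t0

    accuracies = [
        {"source": list(map(str, o.source)), "kind": o.kind, "accuracy": o.accuracy}
        for o in result.outcomes
    ]
    winner = result.winner
    manifest = RunManifest(
        config=cfg.to_dict(),
        seeds={"master": cfg.seed,
               **{k: cfg.seed + v for k, v in SEED_OFFSETS.items()}},
        timings=timings,
        accuracies=accuracies,
        winner={
            "index": result.winner_index,
            "source": list(map(str, winner.source)),
            "accuracy": winner.accuracy,
            "f1": result.metrics.f1,
            "geometric_mean": result.metrics.geometric_mean,
        },
        warnings=warnings_log,
    )
    if out_dir:
        (out_dir / "manifest.json").write_text(manifest.to_json())
        (out_dir / "result.json").write_text(json.dumps(
            {
                "accuracies": accuracies,
                "winner": manifest.winner,
                "confusion": result.metrics.confusion.tolist(),
            },
            indent=2,
        ))
        np.savetxt(out_dir / "final_predictions.csv",
                   np.column_stack([table.y, result.final_predictions]),
                   fmt="%d", delimiter=",", header="y_true,y_pred", comments="")
        np.savetxt(out_dir / "confusion.csv", result.metrics.confusion,
                   fmt="%d", delimiter=",")
    logger.info("pipeline winner %s accuracy %.2f%%", winner.source, winner.accuracy)
    return result, manifest
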