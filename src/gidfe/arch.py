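"""ResNet50* — a ResNet-50 variant with convolution-based residual
shortcuts and a pooling-based attention head.

The network is the standard bottleneck ResNet-50 layout (stem of a 7x7
stride-2 convolution and 3x3 stride-2 max pool; four stages of 3/4/6/3
bottleneck blocks with 256/512/1024/2048 output channels), modified in
two ways:

* **ResNet\\* block** — every block's shortcut path is a 1x1 convolution
  plus batch norm (a "convolution-based residual"), not an identity,
  including blocks where the shapes would permit an identity shortcut.
* **Pooling attention** — each stage output is average-pooled to the
  final 7x7 grid (pool sizes 8/4/2/1 for a 224 input), mapped to 2048
  channels by a 1x1 convolution, and passed through a sigmoid to form a
  gate in (0, 1); the gates modulate the stage-4 feature map (elementwise
  product by default) before the BN -> ReLU -> GAP -> FC -> softmax head.

Ablation variants: ``resnet50`` (identity shortcuts, no attention),
``case1_attention_only`` (standard blocks + attention) and
``case2_block_only`` (ResNet* blocks, no attention).

Everything runs on the package's own NumPy autodiff engine, so the same
code supports the full 224x224 geometry and small configurations used
for fast CPU training on synthetic data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import _nn
from ._nn import BatchNorm2d, Conv2d, Linear, Module, Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "ArchitectureSpec",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "train_model",
    "load_model",
]

VARIANTS = ("resnet50_star", "resnet50", "case1_attention_only", "case2_block_only")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of the network from which a model is built.

    Defaults give the full 224-input geometry.  ``tiny`` returns a scaled
    configuration (same topology, fewer channels, smaller input) for fast
    CPU experiments; pooling sizes are derived from stage geometry, so
    each stage's attention map always lands on the final stage's grid.
    """

    input_size: tuple[int, int, int] = (224, 224, 3)
    stem_filters: int = 64
    stages: tuple[tuple[int, int], ...] = ((3, 256), (4, 512), (6, 1024), (3, 2048))
    combine_mode: str = "multiply"  # "multiply" | "add"
    variant: str = "resnet50_star"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.combine_mode not in ("multiply", "add"):
            raise ValueError("combine_mode must be 'multiply' or 'add'")

    @property
    def channel_match(self) -> int:
        """Channel width the attention gates are mapped to (final stage width)."""
        return self.stages[-1][1]

    @property
    def stage_spatial_sizes(self) -> tuple[int, ...]:
        """Spatial side of each stage output (stage 1 keeps the post-pool size)."""
        side = self.input_size[0] // 4  # stem conv /2, max pool /2
        sizes = [side]
        for _ in self.stages[1:]:
            side //= 2
            sizes.append(side)
        return tuple(sizes)

    @property
    def attention_pool_sizes(self) -> tuple[int, ...]:
        """Average-pool size per stage taking every stage to the final grid."""
        sizes = self.stage_spatial_sizes
        return tuple(s // sizes[-1] for s in sizes)

    @property
    def uses_star_blocks(self) -> bool:
        return self.variant in ("resnet50_star", "case2_block_only")

    @property
    def uses_attention(self) -> bool:
        return self.variant in ("resnet50_star", "case1_attention_only")

    @classmethod
    def tiny(cls, input_size: int = 64, variant: str = "resnet50_star",
             combine_mode: str = "multiply") -> "ArchitectureSpec":
        return cls(
            input_size=(input_size, input_size, 3),
            stem_filters=8,
            stages=((1, 32), (1, 64), (1, 128), (1, 256)),
            combine_mode=combine_mode,
            variant=variant,
        )

    def with_variant(self, variant: str) -> "ArchitectureSpec":
        return replace(self, variant=variant)

    def to_dict(self) -> dict:
        return {
            "input_size": list(self.input_size),
            "stem_filters": self.stem_filters,
            "stages": [list(s) for s in self.stages],
            "combine_mode": self.combine_mode,
            "variant": self.variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            input_size=tuple(d["input_size"]),
            stem_filters=int(d["stem_filters"]),
            stages=tuple((int(a), int(b)) for a, b in d["stages"]),
            combine_mode=d["combine_mode"],
            variant=d["variant"],
        )


@dataclass(frozen=True)
class TrainConfig:
    """SGD-with-momentum training hyper-parameters."""

    initial_lr: float = 0.01
    batch_size: int = 128
    max_epochs: int = 25
    l2: float = 1e-4
    momentum: float = 0.9
    val_fraction: float = 0.2  # 80:20 stratified train/validation split
    augment: bool = False  # flips and 90-degree rotations of training images
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        for name in ("initial_lr", "batch_size", "max_epochs"):
            if getattr(self, name) <= 0 and name != "initial_lr":
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# blocks


class BottleneckBlock(Module):
    """Bottleneck residual block (1x1 -> 3x3 -> 1x1, BN+ReLU between).

    With ``conv_shortcut=True`` this is the ResNet* block: the shortcut is
    always a 1x1 convolution + BN.  Otherwise the shortcut is an identity
    whenever shapes permit, falling back to a projection convolution when
    channels or stride change (standard ResNet-50 behaviour).
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int, conv_shortcut: bool,
                 rng: np.random.Generator):
        if out_ch % 4:
            raise ValueError("block output channels must be divisible by 4")
        mid = out_ch // 4
        self.conv1 = Conv2d(in_ch, mid, 1, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, mid, 3, stride=stride, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.conv3 = Conv2d(mid, out_ch, 1, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        self.has_projection = conv_shortcut or in_ch != out_ch or stride != 1
        if self.has_projection:
            self.shortcut_conv = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.shortcut_bn = BatchNorm2d(out_ch)
        elif stride != 1:
            raise ValueError("identity shortcut cannot change spatial size")

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = _nn.relu(self.bn1(self.conv1(x), training))
        h = _nn.relu(self.bn2(self.conv2(h), training))
        h = self.bn3(self.conv3(h), training)
        if self.has_projection:
            s = self.shortcut_bn(self.shortcut_conv(x), training)
        else:
            s = x
        return _nn.relu(_nn.add(h, s))


def resnet_star_block(in_ch: int, out_ch: int, downsample: bool = False,
                      seed: int = 0) -> BottleneckBlock:
    """Construct a single ResNet* block (convolution-based shortcut)."""
    return BottleneckBlock(in_ch, out_ch, stride=2 if downsample else 1,
                           conv_shortcut=True, rng=np.random.default_rng(seed))


class PoolingAttention(Module):
    """Pooling-based attention head over the four stage outputs.

    Each stage output is average-pooled to the final stage's spatial grid,
    mapped to ``channel_match`` channels by a 1x1 convolution, and passed
    through a sigmoid, yielding one gate per stage with values in (0, 1).
    ``multiply`` mode returns the stage-4 map times the product of all
    gates; ``add`` mode returns the stage-4 map plus the sum of the gates.
    Either way the output keeps the stage-4 spatial size and channel count.
    """

    def __init__(self, stage_channels: tuple[int, ...], pool_sizes: tuple[int, ...],
                 channel_match: int, combine_mode: str, rng: np.random.Generator):
        if len(stage_channels) != len(pool_sizes):
            raise ValueError("one pool size per stage required")
        self.pool_sizes = tuple(pool_sizes)
        self.combine_mode = combine_mode
        self.gate_convs = [
            Conv2d(c, channel_match, 1, bias=True, rng=rng) for c in stage_channels
        ]

    def gates(self, stage_outputs: list[Tensor], training: bool) -> list[Tensor]:
        gates = []
        target = None
        for x, pool, conv in zip(stage_outputs, self.pool_sizes, self.gate_convs):
            pooled = _nn.avg_pool2d(x, pool) if pool > 1 else x
            if target is None:
                target = pooled.data.shape[2:]
            elif pooled.data.shape[2:] != target:
                raise ValueError(
                    f"pooled stage map {pooled.data.shape[2:]} does not match {target}"
                )
            gates.append(_nn.sigmoid(conv(pooled)))
        return gates

    def __call__(self, stage_outputs: list[Tensor], training: bool) -> Tensor:
        gates = self.gates(stage_outputs, training)
        out = stage_outputs[-1]
        if self.combine_mode == "multiply":
            for g in gates:
                out = _nn.mul(out, g)
        else:
            for g in gates:
                out = _nn.add(out, g)
        return out


def pooling_attention(stage_outputs: list[np.ndarray], combine_mode: str = "multiply",
                      channel_match: int | None = None, seed: int = 0) -> np.ndarray:
    """Apply a freshly initialized pooling-attention head to raw stage maps.

    Convenience wrapper used for inspecting the attention geometry outside
    a full network; the in-network head is ``PoolingAttention``.
    """
    tensors = [Tensor(np.asarray(a, dtype=np.float32)) for a in stage_outputs]
    sides = [t.data.shape[2] for t in tensors]
    pools = tuple(s // sides[-1] for s in sides)
    channels = tuple(t.data.shape[1] for t in tensors)
    channel_match = channel_match or channels[-1]
    head = PoolingAttention(channels, pools, channel_match, combine_mode,
                            np.random.default_rng(seed))
    return head(tensors, training=False).data


# ---------------------------------------------------------------------------
# network


class ResNetStarNet(Module):
    """The composed network: stem -> stages -> (attention) -> head."""

    def __init__(self, spec: ArchitectureSpec, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.n_classes = n_classes
        self.stem_conv = Conv2d(spec.input_size[2], spec.stem_filters, 7, stride=2,
                                pad=3, rng=rng)
        self.stem_bn = BatchNorm2d(spec.stem_filters)
        blocks: list[BottleneckBlock] = []
        self.stage_slices: list[tuple[int, int]] = []
        in_ch = spec.stem_filters
        for stage_idx, (n_blocks, out_ch) in enumerate(spec.stages):
            start = len(blocks)
            for b in range(n_blocks):
                stride = 2 if (stage_idx > 0 and b == 0) else 1
                blocks.append(
                    BottleneckBlock(in_ch, out_ch, stride,
                                    conv_shortcut=spec.uses_star_blocks, rng=rng)
                )
                in_ch = out_ch
            self.stage_slices.append((start, len(blocks)))
        self.blocks = blocks
        if spec.uses_attention:
            self.attention = PoolingAttention(
                tuple(f for _, f in spec.stages),
                spec.attention_pool_sizes,
                spec.channel_match,
                spec.combine_mode,
                rng,
            )
        else:
            self.attention = None
        self.head_bn = BatchNorm2d(spec.channel_match)
        self.fc = Linear(spec.channel_match, n_classes, rng=rng)

    def forward(self, x: np.ndarray, training: bool = False) -> dict[str, Tensor]:
        """Run the network; returns logits plus named intermediate tensors.

        ``x`` is (N, H, W, 3) in [0, 1]; internally NCHW.  The returned
        ``pre_gap`` tensor is the final activated map the GAP layer
        summarizes — the source layer for class-activation mapping.
        """
        xt = Tensor(np.ascontiguousarray(np.transpose(x, (0, 3, 1, 2))))
        h = _nn.relu(self.stem_bn(self.stem_conv(xt), training))
        h = _nn.max_pool2d(h, 3, stride=2, pad=1)
        stage_outputs: list[Tensor] = []
        for start, stop in self.stage_slices:
            for blk in self.blocks[start:stop]:
                h = blk(h, training)
            stage_outputs.append(h)
        if self.attention is not None:
            h = self.attention(stage_outputs, training)
        h = _nn.relu(self.head_bn(h, training))
        gap = _nn.global_avg_pool(h)
        logits = self.fc(gap)
        return {
            "logits": logits,
            "gap": gap,
            "pre_gap": h,
            "stage_outputs": stage_outputs,
        }


# ---------------------------------------------------------------------------
# trained model wrapper


@dataclass
class TrainedModel:
    """A network plus its spec, label metadata and training history."""

    spec: ArchitectureSpec
    net: ResNetStarNet
    n_classes: int
    class_names: list[str]
    history: list[dict] = field(default_factory=list)

    @property
    def input_side(self) -> int:
        return self.spec.input_size[0]

    @property
    def feature_length(self) -> int:
        """Length of the GAP feature vector (final stage channel count)."""
        return self.spec.channel_match

    def forward(self, images: np.ndarray, training: bool = False) -> dict[str, Tensor]:
        return self.net.forward(images, training=training)

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch_size):
            logits = self.net.forward(images[i : i + batch_size]).get("logits")
            out.append(_nn.softmax(logits.data))
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(images, batch_size).argmax(axis=1)

    def save(self, path) -> None:
        """Write weights as NPZ with a JSON sidecar echoing the spec."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **self.net.state_arrays())
        sidecar = {
            "spec": self.spec.to_dict(),
            "n_classes": self.n_classes,
            "class_names": self.class_names,
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = ArchitectureSpec.from_dict(sidecar["spec"])
    model = build_model(spec, sidecar["n_classes"])
    model.class_names = list(sidecar["class_names"])
    model.history = list(sidecar["history"])
    with np.load(path) as npz:
        model.net.load_state_arrays(dict(npz))
    return model


def build_model(spec: ArchitectureSpec, n_classes: int, seed: int = 0) -> TrainedModel:
    """Build an untrained model for the given spec and class count."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    net = ResNetStarNet(spec, n_classes, seed=seed)
    return TrainedModel(spec=spec, net=net, n_classes=n_classes,
                        class_names=[f"class_{c:02d}" for c in range(n_classes)])


# ---------------------------------------------------------------------------
# training


def _augment_batch(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal/vertical flips and 90-degree rotations."""
    out = batch.copy()
    for i in range(len(out)):
        if rng.random() < 0.5:
            out[i] = out[i, :, ::-1]
        if rng.random() < 0.5:
            out[i] = out[i, ::-1]
        k = int(rng.integers(0, 4))
        if k:
            out[i] = np.rot90(out[i], k)
    return out


def _bn_modules(mod: Module) -> list[BatchNorm2d]:
    found: list[BatchNorm2d] = []
    for v in mod.__dict__.values():
        if isinstance(v, BatchNorm2d):
            found.append(v)
        elif isinstance(v, Module):
            found.extend(_bn_modules(v))
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, Module):
                    found.extend(_bn_modules(item))
    return found


def finalize_batch_norm(net: ResNetStarNet, images: np.ndarray,
                        max_images: int = 256) -> None:
    """Replace running batch-norm statistics with population statistics.

    After short training runs the exponentially averaged statistics lag
    the network badly; one training-mode pass over (a sample of) the
    training images with momentum 1 sets each layer's running stats to
    the actual population values, the standard finalization step.
    """
    bns = _bn_modules(net)
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0
    try:
        net.forward(images[:max_images], training=True)
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m


def _accuracy(model_net: ResNetStarNet, images: np.ndarray, labels: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    """Evaluation-mode accuracy and mean cross-entropy loss."""
    correct = 0
    losses = []
    for i in range(0, len(images), batch_size):
        xb, yb = images[i : i + batch_size], labels[i : i + batch_size]
        logits = model_net.forward(xb).get("logits")
        p = _nn.softmax(logits.data.astype(np.float64))
        correct += int((p.argmax(axis=1) == yb).sum())
        losses.append(-np.log(np.maximum(p[np.arange(len(yb)), yb], 1e-12)))
    return correct / len(images), float(np.mean(np.concatenate(losses)))


def train_model(model: TrainedModel, images, labels: np.ndarray | None = None,
                cfg: TrainConfig = TrainConfig()) -> TrainedModel:
    """Train in place with SGD-momentum and an 80:20 stratified split.

    ``images`` may be a ``SyntheticImageSet`` or an (n, H, W, 3) array with
    ``labels`` given separately.  Per-epoch train/validation accuracy and
    loss are appended to ``model.history``.
    """
    if labels is None:  # SyntheticImageSet-like
        labels = images.labels
        model.class_names = list(images.class_names)
        images = images.images
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to train")
    counts = np.bincount(labels)
    if (counts[counts > 0] < 2).any() and cfg.val_fraction > 0:
        raise ValueError("every class needs >= 2 images for a stratified split")
    if cfg.val_fraction > 0:
        tr_idx, va_idx = train_test_split(
            np.arange(len(labels)), test_size=cfg.val_fraction,
            stratify=labels, random_state=cfg.seed,
        )
    else:
        tr_idx, va_idx = np.arange(len(labels)), np.array([], dtype=int)
    x_tr, y_tr = images[tr_idx], labels[tr_idx]
    x_va, y_va = images[va_idx], labels[va_idx]
    rng = np.random.default_rng(cfg.seed)
    opt = _nn.SGD(model.net.parameters(), lr=cfg.initial_lr, momentum=cfg.momentum,
                  l2=cfg.l2)
    batch = min(cfg.batch_size, len(x_tr))
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        for i in range(0, len(order), batch):
            idx = order[i : i + batch]
            xb = _augment_batch(x_tr[idx], rng) if cfg.augment else x_tr[idx]
            out = model.net.forward(xb, training=True)
            loss = _nn.softmax_cross_entropy(out.get("logits"), y_tr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
        finalize_batch_norm(model.net, x_tr)
        train_acc, train_loss = _accuracy(model.net, x_tr, y_tr, batch)
        if len(x_va):
            val_acc, val_loss = _accuracy(model.net, x_va, y_va, batch)
        else:
            val_acc, val_loss = float("nan"), float("nan")
        model.history.append(
            {
                "epoch": epoch + 1,
                "train_acc": train_acc,
                "val_acc": val_acc,
                "train_loss": train_loss,
                "val_loss": val_loss,
            }
        )
        logger.info("epoch %d: train_acc=%.3f val_acc=%.3f train_loss=%.4f",
                    epoch + 1, train_acc, val_acc, train_loss)
    return model
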