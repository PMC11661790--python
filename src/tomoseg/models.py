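"""The model zoo: compact 2D segmentation CNNs and slice-wise inference.

A registry maps architecture names to builders.  Three families ship by
default:

* ``eman2_like`` — a shallow three-convolution encoder/decoder in the spirit
  of the default EMAN2 segmentation network; cheap, large 13x13 receptive
  field, no downsampling.
* ``vgg_small`` — a VGG-style stack of 3x3 convolutions with two pooling
  stages and a nearest-neighbour upsampling decoder.
* ``unet`` — a depth-2 U-Net with skip connections.

The registry is extensible: any Python file dropped into a plugins directory
that defines ``ARCH_NAME``, ``DOWNSAMPLE`` and ``build(box_size, rng)`` is
auto-registered by :func:`load_plugins`.

Training minimises pixel-wise binary cross-entropy (Adam, 1e-3 by default)
for a fixed number of epochs; by default no validation split is applied so
that every annotated patch contributes to the fit, and the per-epoch
training loss is recorded.  With ``validation_split > 0`` the recorded
history holds validation losses instead.

Whole volumes are segmented slice by slice: each z-slice is tiled into
box-sized patches on a stride grid, every patch is normalised exactly like
the training patches, and overlapping predictions are blended by uniform
averaging (optionally by cropping patch margins).
"""

from __future__ import annotations

import importlib.util
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .annotate import TrainingSet, normalize_patch
from .core import Volume3D
from .nn import Adam, Conv2D, MaxPool2, ReLU, Sequential, UNet, Upsample2, bce_with_logits
from .nn.net import Network

__all__ = [
    "ArchitectureSpec",
    "SegModel",
    "TrainConfig",
    "register_architecture",
    "available_architectures",
    "load_plugins",
    "build_model",
    "count_parameters",
    "train_model",
    "segment_volume",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    builder: Callable[[int, np.random.Generator], Network]
    downsample: int = 1


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    validation_split: float = 0.0
    seed: int = 0
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 <= self.validation_split < 1.0:
            raise ValueError("validation_split must be in [0, 1)")


@dataclass
class SegModel:
    """An architecture instance plus trained state and provenance metadata."""

    architecture: ArchitectureSpec
    network: Network
    box_size: int
    feature_name: str = ""
    training_pixel_size: float = 0.0
    default_threshold: float = 0.5
    loss_history: list[float] = field(default_factory=list)

    @property
    def epochs_trained(self) -> int:
        return len(self.loss_history)


_REGISTRY: dict[str, ArchitectureSpec] = {}


def register_architecture(name: str, builder, downsample: int = 1, replace: bool = False) -> None:
    if name in _REGISTRY and not replace:
        raise ValueError(f"architecture {name!r} already registered")
    _REGISTRY[name] = ArchitectureSpec(name, builder, downsample)


def available_architectures() -> list[str]:
    return sorted(_REGISTRY)


def _build_eman2_like(box_size: int, rng: np.random.Generator) -> Network:
    # Shallow 3-conv stack with 5x5 kernels; no pooling, so any even box works.
    return Sequential(
        [
            Conv2D(1, 8, 5, rng), ReLU(),
            Conv2D(8, 8, 5, rng), ReLU(),
            Conv2D(8, 1, 5, rng),
        ],
        downsample=1,
    )


def _build_vgg_small(box_size: int, rng: np.random.Generator) -> Network:
    return Sequential(
        [
            Conv2D(1, 8, 3, rng), ReLU(),
            Conv2D(8, 8, 3, rng), ReLU(),
            MaxPool2(),
            Conv2D(8, 16, 3, rng), ReLU(),
            Conv2D(16, 16, 3, rng), ReLU(),
            MaxPool2(),
            Conv2D(16, 16, 3, rng), ReLU(),
            Upsample2(),
            Conv2D(16, 8, 3, rng), ReLU(),
            Upsample2(),
            Conv2D(8, 8, 3, rng), ReLU(),
            Conv2D(8, 1, 3, rng),
        ],
        downsample=4,
    )


def _build_unet(box_size: int, rng: np.random.Generator) -> Network:
    return UNet(rng, base=8)


register_architecture("eman2_like", _build_eman2_like, downsample=1)
register_architecture("vgg_small", _build_vgg_small, downsample=4)
register_architecture("unet", _build_unet, downsample=4)


def load_plugins(directory) -> list[str]:
    """Auto-register every architecture plugin found in ``directory``.

    A plugin is a ``.py`` file defining module-level ``ARCH_NAME`` (str),
    ``DOWNSAMPLE`` (int) and ``build(box_size, rng) -> Network``.
    Returns the names registered.
    """
    directory = Path(directory)
    names = []
    for pyfile in sorted(directory.glob("*.py")):
        spec = importlib.util.spec_from_file_location(f"tomoseg_plugin_{pyfile.stem}", pyfile)
        mod = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(mod)
        missing = [a for a in ("ARCH_NAME", "DOWNSAMPLE", "build") if not hasattr(mod, a)]
        if missing:
            raise ValueError(f"plugin {pyfile.name} lacks {', '.join(missing)}")
        register_architecture(mod.ARCH_NAME, mod.build, int(mod.DOWNSAMPLE), replace=True)
        names.append(mod.ARCH_NAME)
        log.info("registered plugin architecture %r from %s", mod.ARCH_NAME, pyfile)
    return names


def build_model(
    arch_name: str,
    box_size: int = 64,
    seed: int = 0,
    feature_name: str = "",
    training_pixel_size: float = 0.0,
) -> SegModel:
    """Instantiate an untrained model with seeded weight initialisation."""
    if arch_name not in _REGISTRY:
        raise KeyError(
            f"unknown architecture {arch_name!r}; available: {', '.join(available_architectures())}"
        )
    spec = _REGISTRY[arch_name]
    if box_size % spec.downsample:
        raise ValueError(
            f"{arch_name!r} downsamples by {spec.downsample}; box_size must be a "
            f"multiple of {spec.downsample}, got {box_size}"
        )
    rng = np.random.default_rng(seed)
    net = spec.builder(box_size, rng)
    return SegModel(
        architecture=spec,
        network=net,
        box_size=box_size,
        feature_name=feature_name,
        training_pixel_size=training_pixel_size,
    )


def count_parameters(model: SegModel) -> int:
    """Total number of trainable scalar weights."""
    return model.network.n_parameters()


def train_model(model: SegModel, ts: TrainingSet, cfg: TrainConfig | None = None) -> SegModel:
    """Fit ``model`` on a training set by minimising pixel-wise BCE.

    Shuffling is reseeded from ``cfg.seed`` so runs are reproducible on one
    device.  A NaN loss aborts with the offending epoch named.
    """
    cfg = cfg or TrainConfig()
    if len(ts) == 0:
        raise ValueError("training set is empty")
    if ts.box_size != model.box_size:
        raise ValueError(f"training set box {ts.box_size} != model box {model.box_size}")

    x = ts.images[..., None].astype(np.float32)  # (N, H, W, 1) channels-last
    y = ts.labels[..., None].astype(np.float32)

    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.validation_split * len(x)))
    if n_val:
        order = rng.permutation(len(x))
        x, y = x[order], y[order]
        x_val, y_val = x[:n_val], y[:n_val]
        x, y = x[n_val:], y[n_val:]
        if len(x) == 0:
            raise ValueError("validation split leaves no training data")

    opt = Adam(model.network.params(), lr=cfg.learning_rate)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        epoch_losses = []
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.network.forward_logits(x[idx])
            loss, grad = bce_with_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch + 1}"
                )
            model.network.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        if n_val:
            val_logits = model.network.forward_logits(x_val)
            val_loss, _ = bce_with_logits(val_logits, y_val)
            model.loss_history.append(val_loss)
        else:
            model.loss_history.append(float(np.mean(epoch_losses)))

    if ts.feature_name and not model.feature_name:
        model.feature_name = ts.feature_name
    if ts.pixel_size and not model.training_pixel_size:
        model.training_pixel_size = ts.pixel_size
    return model


def _tile_starts(extent: int, box: int, stride: int) -> list[int]:
    starts = list(range(0, extent - box + 1, stride))
    if not starts or starts[-1] != extent - box:
        starts.append(extent - box)
    return starts


def segment_volume(
    model: SegModel,
    volume: Volume3D,
    stride: int | None = None,
    blend: str = "average",
    batch_size: int = 32,
) -> Volume3D:
    """Slice-wise tiled prediction over a whole volume.

    Each z-slice is covered by box-sized tiles every ``stride`` pixels (the
    final row/column is shifted flush with the edge); tiles are per-patch
    normalised and predicted in batches.  ``blend='average'`` averages
    overlapping predictions uniformly; ``blend='crop'`` keeps only the
    central ``stride x stride`` region of interior tiles.  Slices smaller
    than the box are reflect-padded and cropped back.
    """
    box = model.box_size
    stride = box if stride is None else int(stride)
    if not 0 < stride <= box:
        raise ValueError(f"stride must be in 1..box_size ({box}), got {stride}")
    if blend not in ("average", "crop"):
        raise ValueError(f"unknown blend mode {blend!r}")

    nz, ny, nx = volume.shape
    pad_y, pad_x = max(0, box - ny), max(0, box - nx)
    data = volume.data
    if pad_y or pad_x:
        data = np.pad(data, ((0, 0), (0, pad_y), (0, pad_x)), mode="reflect")
    _, py, px = data.shape

    ys, xs = _tile_starts(py, box, stride), _tile_starts(px, box, stride)
    out = np.zeros_like(data, dtype=np.float64)
    weight = np.zeros((py, px), dtype=np.float64)

    margin = (box - stride) // 2
    tiles = [(y0, x0) for y0 in ys for x0 in xs]
    for z in range(nz):
        patches = np.empty((len(tiles), box, box, 1), dtype=np.float32)
        for i, (y0, x0) in enumerate(tiles):
            patches[i, :, :, 0] = normalize_patch(data[z, y0 : y0 + box, x0 : x0 + box])
        preds = np.empty((len(tiles), box, box), dtype=np.float64)
        for start in range(0, len(tiles), batch_size):
            preds[start : start + batch_size] = model.network.predict(
                patches[start : start + batch_size]
            )[..., 0]
        for i, (y0, x0) in enumerate(tiles):
            if blend == "average" or margin == 0:
                out[z, y0 : y0 + box, x0 : x0 + box] += preds[i]
                if z == 0:
                    weight[y0 : y0 + box, x0 : x0 + box] += 1.0
            else:
                m_y0 = margin if y0 > 0 else 0
                m_y1 = margin if y0 + box < py else 0
                m_x0 = margin if x0 > 0 else 0
                m_x1 = margin if x0 + box < px else 0
                out[z, y0 + m_y0 : y0 + box - m_y1, x0 + m_x0 : x0 + box - m_x1] += preds[
                    i, m_y0 : box - m_y1, m_x0 : box - m_x1
                ]
                if z == 0:
                    weight[y0 + m_y0 : y0 + box - m_y1, x0 + m_x0 : x0 + box - m_x1] += 1.0

    out /= np.maximum(weight, 1.0)[None, :, :]
    out = out[:, :ny, :nx]
    return Volume3D(np.clip(out, 0.0, 1.0).astype(np.float32), volume.voxel_size,
                    volume.origin.copy())


# --- model bundles ----------------------------------------------------------

def save_model(model: SegModel, directory) -> Path:
    """Write a self-describing bundle: weights (.npz) + JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    weights = {f"w{i}": w for i, (w, _) in enumerate(model.network.params())}
    np.savez(directory / "weights.npz", **weights)
    meta = {
        "architecture": model.architecture.name,
        "box_size": model.box_size,
        "feature_name": model.feature_name,
        "training_pixel_size": model.training_pixel_size,
        "default_threshold": model.default_threshold,
        "loss_history": model.loss_history,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_model(directory) -> SegModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    model = build_model(
        meta["architecture"],
        box_size=meta["box_size"],
        feature_name=meta.get("feature_name", ""),
        training_pixel_size=meta.get("training_pixel_size", 0.0),
    )
    with np.load(directory / "weights.npz") as npz:
        model.network.set_weights([npz[f"w{i}"] for i in range(len(npz.files))])
    model.default_threshold = meta.get("default_threshold", 0.5)
    model.loss_history = list(meta.get("loss_history", []))
    return model
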