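"""From sparse manual annotations to balanced, augmented training sets.

A user annotates a feature by marking boxes on individual tomogram slices:
positive boxes carry a binary label mask, negative boxes show confusable
content (other features, artefacts, background) and carry an all-zero label.
Because positives are typically scarce, the training set is rebalanced:
every positive patch is copied a number of times and negatives are drawn
with replacement to a fixed negative:positive ratio, each emitted patch in a
random orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Volume3D

__all__ = [
    "AnnotationBox",
    "TrainingSet",
    "extract_boxes",
    "resample_training_set",
    "normalize_patch",
    "dihedral",
    "write_annotation_manifest",
    "read_annotation_manifest",
]

log = logging.getLogger(__name__)

STD_FLOOR = 1e-9


@dataclass
class AnnotationBox:
    """One annotated box on one tomogram slice.

    ``center`` is the (x, y) pixel position on slice ``slice_index``;
    ``label_mask`` a box-sized binary grid (all zero for negative boxes).
    """

    dataset_id: str
    slice_index: int
    center: tuple[int, int]
    positive: bool
    label_mask: np.ndarray

    def __post_init__(self) -> None:
        self.label_mask = np.asarray(self.label_mask)
        nonzero = int(np.count_nonzero(self.label_mask))
        if self.positive and nonzero == 0:
            raise ValueError("positive annotation box has an all-zero label mask")
        if not self.positive and nonzero > 0:
            raise ValueError("negative annotation box has nonzero label pixels")


@dataclass
class TrainingSet:
    """Resampled, oriented patch/label pairs for one feature."""

    feature_name: str
    box_size: int
    images: np.ndarray  # (n, box, box) float32, per-patch normalised
    labels: np.ndarray  # (n, box, box) float32 binary
    pixel_size: float = 1.0  # A per pixel of the source data
    counts: tuple[int, int] = (0, 0)  # (n_positive_out, n_negative_out)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.float32)
        if self.images.shape != self.labels.shape:
            raise ValueError("images and labels must have identical shapes")
        if len(self.images) and self.images.shape[1:] != (self.box_size, self.box_size):
            raise ValueError(
                f"patches are {self.images.shape[1:]}, expected {(self.box_size,) * 2}"
            )

    def __len__(self) -> int:
        return len(self.images)


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance normalisation; constant patches map to zeros."""
    patch = np.asarray(patch, dtype=np.float32)
    # statistics in float64: a constant float32 patch must yield std == 0
    std = patch.std(dtype=np.float64)
    if std < STD_FLOOR:
        return np.zeros_like(patch)
    return ((patch - patch.mean(dtype=np.float64)) / std).astype(np.float32)


def _clamp_center(c: int, half: int, dim: int) -> int:
    return int(min(max(c, half), dim - half))


def extract_boxes(
    volume: Volume3D,
    boxes: list[AnnotationBox],
    box_size: int = 64,
) -> list[tuple[np.ndarray, np.ndarray, bool]]:
    """Crop normalised patches for each annotation box.

    Crops span ``[c - box_size/2, c + box_size/2)`` on the box's slice.
    Centers too close to the slice edge are shifted inward so the crop fits
    (logged, never dropped).  Label masks pass through unchanged.
    """
    if box_size % 2:
        raise ValueError(f"box_size must be even, got {box_size}")
    half = box_size // 2
    nz, ny, nx = volume.shape
    if nx < box_size or ny < box_size:
        raise ValueError(f"slice ({ny}x{nx}) smaller than box_size {box_size}")

    out = []
    for box in boxes:
        if not 0 <= box.slice_index < nz:
            raise ValueError(
                f"annotation slice {box.slice_index} outside volume with {nz} slices"
            )
        cx, cy = (int(round(c)) for c in box.center)
        ccx, ccy = _clamp_center(cx, half, nx), _clamp_center(cy, half, ny)
        if (ccx, ccy) != (cx, cy):
            log.info(
                "box at (%d, %d) on slice %d shifted to (%d, %d) to fit the %dpx crop",
                cx, cy, box.slice_index, ccx, ccy, box_size,
            )
        patch = volume.data[box.slice_index, ccy - half : ccy + half, ccx - half : ccx + half]
        label = np.asarray(box.label_mask, dtype=np.float32)
        if label.shape != (box_size, box_size):
            raise ValueError(
                f"label mask {label.shape} does not match box_size {box_size}"
            )
        out.append((normalize_patch(patch), label, box.positive))
    return out


def dihedral(patch: np.ndarray, index: int) -> np.ndarray:
    """Apply one of the 8 square symmetries (4 rotations x optional flip)."""
    if not 0 <= index < 8:
        raise ValueError("dihedral index must be in 0..7")
    out = np.rot90(patch, k=index % 4)
    if index >= 4:
        out = np.fliplr(out)
    return np.ascontiguousarray(out)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def resample_training_set(
    samples: list[tuple[np.ndarray, np.ndarray, bool]],
    copies: int = 10,
    neg_ratio: float = 1.3,
    seed: int = 0,
    feature_name: str = "",
    pixel_size: float = 1.0,
    arbitrary_rotation: bool = False,
) -> TrainingSet:
    """Rebalance and augment extracted patches into a :class:`TrainingSet`.

    Every positive is copied ``copies`` times; negatives are drawn uniformly
    with replacement to ``round(neg_ratio * n_positive_out)``.  Each emitted
    patch gets a random orientation applied identically to image and label —
    by default one of the 8 dihedral transforms (exact for binary labels);
    ``arbitrary_rotation`` instead rotates by a uniform random angle with
    nearest-neighbour label interpolation.  Fully reproducible from ``seed``.
    """
    positives = [(im, lb) for im, lb, pos in samples if pos]
    negatives = [(im, lb) for im, lb, pos in samples if not pos]
    if not positives:
        raise ValueError("resampling requires at least one positive sample")

    n_pos_out = copies * len(positives)
    n_neg_out = _round_half_up(neg_ratio * n_pos_out)
    if not negatives and neg_ratio > 0:
        log.warning("no negative samples available; emitting positives only")
        n_neg_out = 0

    rng = np.random.default_rng(seed)
    emitted: list[tuple[np.ndarray, np.ndarray]] = []
    for im, lb in positives:
        emitted.extend((im, lb) for _ in range(copies))
    if n_neg_out:
        picks = rng.integers(len(negatives), size=n_neg_out)
        emitted.extend(negatives[i] for i in picks)

    box = emitted[0][0].shape[0]
    images = np.empty((len(emitted), box, box), dtype=np.float32)
    labels = np.empty_like(images)
    for i, (im, lb) in enumerate(emitted):
        if arbitrary_rotation:
            from scipy.ndimage import rotate

            angle = float(rng.uniform(0.0, 360.0))
            images[i] = rotate(im, angle, reshape=False, order=1, mode="reflect")
            labels[i] = rotate(lb, angle, reshape=False, order=0, mode="constant")
        else:
            k = int(rng.integers(8))
            images[i] = dihedral(im, k)
            labels[i] = dihedral(lb, k)

    order = rng.permutation(len(emitted))
    return TrainingSet(
        feature_name=feature_name,
        box_size=box,
        images=images[order],
        labels=labels[order],
        pixel_size=pixel_size,
        counts=(n_pos_out, n_neg_out),
    )


# --- annotation manifest (tab-separated) -----------------------------------
#
# Schema, one box per line:
#   dataset_id <TAB> z <TAB> x <TAB> y <TAB> positive(0|1) <TAB> mask_path
# mask_path is an MRC raster (1 x box x box) relative to the manifest,
# or "-" for an all-zero negative label.

def write_annotation_manifest(boxes: list[AnnotationBox], path, box_size: int = 64) -> Path:
    from . import io as _io

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, box in enumerate(boxes):
        if box.positive:
            mask_name = f"{path.stem}_mask{i:05d}.mrc"
            _io.write_mrc(
                Volume3D(box.label_mask.reshape(1, *box.label_mask.shape)),
                path.parent / mask_name,
            )
        else:
            mask_name = "-"
        lines.append(
            f"{box.dataset_id}\t{box.slice_index}\t{box.center[0]}\t{box.center[1]}"
            f"\t{int(box.positive)}\t{mask_name}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_annotation_manifest(path, box_size: int = 64) -> list[AnnotationBox]:
    from . import io as _io

    path = Path(path)
    boxes = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        dataset_id, z, x, y, positive, mask_name = line.split("\t")
        if mask_name == "-":
            mask = np.zeros((box_size, box_size), dtype=np.float32)
        else:
            mask = _io.read_mrc(path.parent / mask_name).data[0]
        boxes.append(
            AnnotationBox(dataset_id, int(z), (int(x), int(y)), bool(int(positive)), mask)
        )
    return boxes
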