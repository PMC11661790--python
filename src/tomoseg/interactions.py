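"""Conditional combination of per-feature prediction volumes.

Two mechanisms refine multi-model segmentations:

* **Interactions** between a parent and a child feature.  A binary mask is
  made by thresholding the parent's predictions, then dilated with a
  circular kernel of interaction radius R.  For *colocalization* the child
  is multiplied by the mask (only predictions near the parent survive); for
  *avoidance* by its complement (predictions near the parent are removed).
* **Competition** among features: models can *emit* and/or *absorb*.  An
  absorbing feature's value at a voxel is zeroed whenever any other emitting
  feature's value there is strictly higher; comparisons always use the
  original inputs (simultaneous update).

Both mechanisms only ever suppress: output <= input voxel-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.morphology import ball, disk

from .core import Volume3D

__all__ = [
    "InteractionSpec",
    "CompetitionConfig",
    "radius_to_pixels",
    "apply_interaction",
    "apply_competition",
    "apply_pipeline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionSpec:
    """One parent->child suppression rule with interaction radius R (nm)."""

    parent_feature: str
    child_feature: str
    kind: str  # "colocalize" | "avoid"
    parent_threshold: float = 0.5
    radius_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("colocalize", "avoid"):
            raise ValueError(f"interaction kind must be 'colocalize' or 'avoid', got {self.kind!r}")
        if self.parent_feature == self.child_feature:
            raise ValueError("parent and child feature must differ")
        if not 0.0 <= self.parent_threshold <= 1.0:
            raise ValueError("parent_threshold must be in [0, 1]")
        if self.radius_nm < 0:
            raise ValueError("radius_nm must be >= 0")


@dataclass(frozen=True)
class CompetitionConfig:
    """Feature names that emit and/or absorb competition (sets may overlap)."""

    emitting: frozenset[str] = frozenset()
    absorbing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "emitting", frozenset(self.emitting))
        object.__setattr__(self, "absorbing", frozenset(self.absorbing))


def radius_to_pixels(radius_nm: float, pixel_size: float) -> int:
    """Convert an interaction radius in nm to pixels (round half up)."""
    import math

    return int(math.floor(radius_nm * 10.0 / pixel_size + 0.5))


def _dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    # binary dilation == thresholded convolution with the kernel; FFT keeps
    # large interaction radii tractable (footprints grow as R^2)
    if footprint.size <= 7 ** mask.ndim:
        return binary_dilation(mask, structure=footprint)
    from scipy.signal import fftconvolve

    return fftconvolve(mask.astype(np.float32), footprint.astype(np.float32),
                       mode="same") > 0.5


def _dilate_mask(mask: np.ndarray, radius_px: int, mode: str) -> np.ndarray:
    if radius_px <= 0:
        if radius_px == 0:
            log.debug("interaction radius resolves to 0 px; no dilation applied")
        return mask
    if mode == "2d":
        footprint = disk(radius_px)
        out = np.empty_like(mask)
        for z in range(mask.shape[0]):
            out[z] = _dilate(mask[z], footprint)
        return out
    if mode == "3d":
        return _dilate(mask, ball(radius_px))
    raise ValueError(f"unknown kernel mode {mode!r} (expected '2d' or '3d')")


def _dilated_parent_mask(
    parent: np.ndarray, threshold: float, radius_px: int, mode: str
) -> np.ndarray:
    return _dilate_mask(parent >= threshold, radius_px, mode)


def apply_interaction(
    child: Volume3D,
    parent: Volume3D,
    spec: InteractionSpec,
    pixel_size: float | None = None,
    mode: str = "2d",
    avoid_complement: str = "after_dilation",
) -> Volume3D:
    """Apply one colocalization/avoidance rule to a child prediction volume.

    The parent mask is thresholded at ``spec.parent_threshold`` and dilated
    slice-wise with a disk of ``round(radius_nm * 10 / pixel_size)`` pixels
    (``mode='3d'`` uses a ball instead).  Colocalization multiplies the
    child by the mask, avoidance by its complement.

    ``avoid_complement`` selects where the complement is taken for
    avoidance: ``"after_dilation"`` (default) suppresses everything within
    R of an above-threshold parent voxel; ``"before_dilation"`` instead
    keeps everything within R of a below-threshold parent voxel.  The two
    readings differ only in a border band of width R around the parent
    mask.
    """
    if child.data.shape != parent.data.shape:
        raise ValueError(
            f"child shape {child.data.shape} != parent shape {parent.data.shape}"
        )
    pixel_size = child.voxel_size if pixel_size is None else float(pixel_size)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if avoid_complement not in ("after_dilation", "before_dilation"):
        raise ValueError(f"unknown avoid_complement {avoid_complement!r}")

    radius_px = radius_to_pixels(spec.radius_nm, pixel_size)
    if spec.kind == "colocalize":
        mask = _dilated_parent_mask(parent.data, spec.parent_threshold, radius_px, mode)
        new = child.data * mask
    elif avoid_complement == "after_dilation":
        mask = _dilated_parent_mask(parent.data, spec.parent_threshold, radius_px, mode)
        new = child.data * ~mask
    else:
        # keep-region = dilation of the below-threshold parent region
        below = parent.data < spec.parent_threshold
        keep = _dilate_mask(below, radius_px, mode)
        new = child.data * keep
    return Volume3D(new.astype(np.float32), child.voxel_size, child.origin.copy())


def apply_competition(
    preds: Mapping[str, Volume3D], cfg: CompetitionConfig
) -> dict[str, Volume3D]:
    """Pixel-wise winner-take-all among emitting models, applied to absorbers.

    For each absorbing feature f the output is zero wherever
    ``max over emitting g != f of preds[g]`` is strictly greater than
    ``preds[f]``; ties survive.  All comparisons read the original inputs.
    """
    shapes = {v.data.shape for v in preds.values()}
    if len(shapes) > 1:
        raise ValueError(f"prediction volumes differ in shape: {sorted(shapes)}")
    emitting = [f for f in cfg.emitting if f in preds]
    if not cfg.emitting:
        log.debug("empty emitting set; competition is the identity")

    out: dict[str, Volume3D] = {}
    for name, vol in preds.items():
        if name not in cfg.absorbing or not emitting:
            out[name] = vol.copy()
            continue
        rivals = [preds[g].data for g in emitting if g != name]
        if not rivals:
            out[name] = vol.copy()
            continue
        rival_max = np.maximum.reduce(rivals)
        new = np.where(rival_max > vol.data, 0.0, vol.data)
        out[name] = Volume3D(new.astype(np.float32), vol.voxel_size, vol.origin.copy())
    return out


def apply_pipeline(
    preds: Mapping[str, Volume3D],
    competition: CompetitionConfig | None = None,
    interactions: list[InteractionSpec] | None = None,
    pixel_size: float | None = None,
    mode: str = "2d",
) -> dict[str, Volume3D]:
    """Competition first (simultaneous), then interactions in list order.

    Each interaction consumes the current state, so an ordered chain like
    "membrane avoids carbon" followed by "platform colocalizes with
    membrane" composes left to right.
    """
    interactions = interactions or []
    referenced = {s.parent_feature for s in interactions} | {
        s.child_feature for s in interactions
    }
    missing = sorted(referenced - set(preds))
    if missing:
        raise KeyError(f"interaction references missing feature(s): {', '.join(missing)}")

    state = (
        apply_competition(preds, competition)
        if competition is not None
        else {k: v.copy() for k, v in preds.items()}
    )
    for spec in interactions:
        state[spec.child_feature] = apply_interaction(
            state[spec.child_feature], state[spec.parent_feature], spec,
            pixel_size=pixel_size, mode=mode,
        )
    return state
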