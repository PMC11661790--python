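"""Particle picking from segmented probability volumes.

The procedure converts a per-voxel prediction volume into a list of particle
coordinates in six steps:

1. threshold the volume at a user-chosen level;
2. compute the Euclidean distance transform of the binary foreground
   (distance of each foreground voxel to the nearest background voxel);
3. watershed the negated distance transform, seeded at its local maxima, so
   every foreground voxel joins the group of its ruling maximum;
4. discard groups smaller than a minimum volume (nm^3);
5. weight each remaining group by the sum of prediction values over its
   voxels, then greedily discard the lower-weighted of any two groups whose
   centroids are closer than the minimum particle spacing;
6. report each surviving group's centroid, rounded to integer voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .core import ParticleSet, Volume3D

__all__ = [
    "PickConfig",
    "ParticleGroup",
    "group_segmentation",
    "filter_min_volume",
    "suppress_close_groups",
    "pick_particles",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PickConfig:
    threshold: float = 0.5
    min_volume_nm3: float = 0.0
    min_spacing_nm: float = 0.0
    pixel_size: float = 10.0  # Angstrom per voxel

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.min_volume_nm3 < 0 or self.min_spacing_nm < 0:
            raise ValueError("min_volume_nm3 and min_spacing_nm must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class ParticleGroup:
    """One watershed group of foreground voxels."""

    voxels_zyx: np.ndarray  # (n, 3) int, array order
    weight: float  # sum of prediction values over the group
    centroid_xyz: np.ndarray  # (3,) float, unweighted mean in (x, y, z)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels_zyx)

    @property
    def voxel_indices(self) -> set[tuple[int, int, int]]:
        """Group voxels as 0-based (x, y, z) tuples."""
        return {(int(x), int(y), int(z)) for z, y, x in self.voxels_zyx}


def _watershed_labels(binary: np.ndarray, edt: np.ndarray) -> np.ndarray:
    """Label foreground voxels by their ruling distance-transform maximum.

    Local maxima are voxels matching a 3x3x3 maximum filter; each connected
    plateau of maxima (26-connectivity) contributes one seed, placed at its
    lowest flat voxel index for determinism.
    """
    maxfilt = ndimage.maximum_filter(edt, footprint=_CONN26, mode="constant")
    peaks = (edt >= maxfilt) & binary
    plateau_labels, n_plateaus = ndimage.label(peaks, structure=_CONN26)
    markers = np.zeros_like(plateau_labels)
    if n_plateaus:
        flat = plateau_labels.ravel()
        # first (lowest flat index) voxel of each plateau is its seed
        first = np.full(n_plateaus + 1, -1, dtype=np.int64)
        idx = np.flatnonzero(flat)
        lab = flat[idx]
        # reverse order so earlier indices overwrite later ones
        first[lab[::-1]] = idx[::-1]
        markers.ravel()[first[1:]] = np.arange(1, n_plateaus + 1)
    return watershed(-edt, markers=markers, mask=binary, connectivity=3)


def group_segmentation(pred: Volume3D, cfg: PickConfig) -> list[ParticleGroup]:
    """Steps 1-3 plus weighting: threshold, distance transform, watershed.

    Returns one :class:`ParticleGroup` per watershed region; the groups
    partition the thresholded foreground.  Empty foreground yields ``[]``.
    """
    pred.require_prediction()
    binary = pred.data >= cfg.threshold
    if not binary.any():
        return []
    edt = ndimage.distance_transform_edt(binary)
    labels = _watershed_labels(binary, edt)

    groups: list[ParticleGroup] = []
    objects = ndimage.find_objects(labels)
    for i, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        local = labels[slc] == i
        zz, yy, xx = np.nonzero(local)
        zz = zz + slc[0].start
        yy = yy + slc[1].start
        xx = xx + slc[2].start
        voxels = np.stack([zz, yy, xx], axis=1)
        weight = float(pred.data[zz, yy, xx].sum())
        centroid = np.array([xx.mean(), yy.mean(), zz.mean()])
        groups.append(ParticleGroup(voxels, weight, centroid))
    return groups


def filter_min_volume(groups: list[ParticleGroup], cfg: PickConfig) -> list[ParticleGroup]:
    """Drop groups whose physical volume is below ``min_volume_nm3``."""
    voxel_nm3 = (cfg.pixel_size / 10.0) ** 3
    return [g for g in groups if g.n_voxels * voxel_nm3 >= cfg.min_volume_nm3]


def suppress_close_groups(groups: list[ParticleGroup], cfg: PickConfig) -> list[ParticleGroup]:
    """Greedy non-maximum suppression by weight at ``min_spacing_nm``.

    Groups are visited in descending weight (ties broken by centroid,
    lexicographically); a group survives iff its centroid lies at least the
    minimum spacing from every already-retained centroid.
    """
    if cfg.min_spacing_nm <= 0 or len(groups) < 2:
        return list(groups)
    order = sorted(
        groups, key=lambda g: (-g.weight, tuple(g.centroid_xyz))
    )
    spacing_px = cfg.min_spacing_nm * 10.0 / cfg.pixel_size
    kept: list[ParticleGroup] = []
    for g in order:
        if all(
            np.linalg.norm(g.centroid_xyz - k.centroid_xyz) >= spacing_px for k in kept
        ):
            kept.append(g)
    return kept


def _round_half_up(arr: np.ndarray) -> np.ndarray:
    return np.floor(arr + 0.5).astype(np.int64)


def pick_particles(pred: Volume3D, cfg: PickConfig, feature_name: str = "",
                   source: str = "") -> ParticleSet:
    """Full picking pipeline: group, filter, suppress, report centroids.

    Centroids are the unweighted means of group voxel indices, rounded half
    up to integers; particles are sorted by descending weight.
    """
    groups = group_segmentation(pred, cfg)
    groups = filter_min_volume(groups, cfg)
    groups = suppress_close_groups(groups, cfg)
    groups.sort(key=lambda g: (-g.weight, tuple(g.centroid_xyz)))
    if not groups:
        return ParticleSet(np.empty((0, 3), dtype=np.int64), np.empty(0),
                           feature_name=feature_name, source_volume=source)
    coords = _round_half_up(np.stack([g.centroid_xyz for g in groups]))
    weights = np.array([g.weight for g in groups])
    ps = ParticleSet(coords, weights, feature_name=feature_name, source_volume=source)
    ps.validate_bounds(pred)
    return ps
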