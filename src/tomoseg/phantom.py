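"""Synthetic tomogram phantoms with per-feature ground truth.

The generator emulates the recurring scene of segmentation benchmarks on
vesicle samples: spherical-shell *membranes*, a carbon-film-like half-space
slab with a straight edge, membrane-bound *platform* discs hovering at a
fixed offset outside the membrane surface (antibody Fc-platform analogue),
solid-sphere *granules* and cylindrical *filaments*, over a flat background
with additive Gaussian noise.  Every feature also yields a binary
ground-truth volume, so training, interactions, picking and meshing are all
testable without any external data.

Geometry is voxel-painted; objects are placed with bounded rejection
sampling so that ground-truth volumes are pairwise disjoint (platforms never
touch membrane voxels — they sit ``platform_offset_nm`` outside the shell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .annotate import AnnotationBox
from .core import Volume3D

__all__ = ["PhantomConfig", "generate_phantom", "generate_training_boxes"]


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (96, 160, 160)  # (nz, ny, nx)
    pixel_size: float = 10.0  # Angstrom per voxel (1 nm)
    n_vesicles: int = 3
    vesicle_radius_range: tuple[float, float] = (12.0, 18.0)  # nm
    membrane_thickness_nm: float = 5.0
    n_platforms: int = 0
    platform_offset_nm: float = 22.0  # membrane surface -> platform centre
    platform_radius_nm: float = 4.0
    platform_thickness_nm: float = 3.0
    # platforms sit near the vesicle equator (|z-component| of the outward
    # normal scaled by this factor) so that the z-slice through a platform
    # also cuts its host membrane — the geometry in which slice-wise
    # proximity rules between platform and membrane are meaningful
    platform_axial_fraction: float = 0.15
    carbon_slab: bool = False
    n_granules: int = 0
    granule_radius_range: tuple[float, float] = (4.0, 8.0)  # nm
    n_filaments: int = 0
    filament_radius_nm: float = 2.0
    filament_length_range: tuple[float, float] = (30.0, 60.0)  # nm
    noise_sigma: float = 0.2
    contrast: float = 1.0
    invert: bool = False
    z_blur_sigma: float = 0.0  # optional anisotropic blur (voxels)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 1:
            raise ValueError("phantom shape must be positive in all dimensions")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for name in ("n_vesicles", "n_platforms", "n_granules", "n_filaments"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_platforms and not self.n_vesicles:
            raise ValueError("platforms require at least one vesicle to bind to")

    def nm_to_px(self, nm: float) -> float:
        return nm * 10.0 / self.pixel_size


class PlacementError(RuntimeError):
    """An object could not be placed without overlap within bounded retries."""


_MAX_TRIES = 200


def _ball_voxels(shape, center, radius):
    """Indices (z, y, x arrays) of voxels within ``radius`` of ``center``."""
    lo = [max(0, int(np.floor(c - radius - 1))) for c in center]
    hi = [min(s, int(np.ceil(c + radius + 2))) for s, c in zip(shape, center)]
    if any(l >= h for l, h in zip(lo, hi)):
        return tuple(np.empty(0, dtype=np.int64) for _ in range(3))
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    sel = d2 <= radius * radius
    return zz[sel], yy[sel], xx[sel]


def _shell_voxels(shape, center, r_outer, thickness):
    lo = [max(0, int(np.floor(c - r_outer - 1))) for c in center]
    hi = [min(s, int(np.ceil(c + r_outer + 2))) for s, c in zip(shape, center)]
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    sel = (d <= r_outer) & (d >= r_outer - thickness)
    return zz[sel], yy[sel], xx[sel]


def _disc_voxels(shape, center, normal, radius, half_thickness):
    reach = np.sqrt(radius**2 + half_thickness**2)
    lo = [max(0, int(np.floor(c - reach - 1))) for c in center]
    hi = [min(s, int(np.ceil(c + reach + 2))) for s, c in zip(shape, center)]
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    dz, dy, dx = zz - center[0], yy - center[1], xx - center[2]
    axial = dz * normal[0] + dy * normal[1] + dx * normal[2]
    rad2 = dz**2 + dy**2 + dx**2 - axial**2
    sel = (np.abs(axial) <= half_thickness) & (rad2 <= radius * radius)
    return zz[sel], yy[sel], xx[sel]


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def generate_phantom(cfg: PhantomConfig) -> tuple[Volume3D, dict[str, Volume3D]]:
    """Build the phantom density volume and its per-feature ground truth.

    Returns ``(density, ground_truth)`` where ``ground_truth`` maps feature
    name ("membrane", "carbon", "platform", "granule", "filament") to a
    binary :class:`Volume3D`; only requested features appear.  Fully
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.shape
    shape = cfg.shape
    occupied = np.zeros(shape, dtype=bool)
    gt: dict[str, np.ndarray] = {}

    # Carbon film analogue: half-space slab with a straight edge at 3/4 nx.
    x_limit = nx
    if cfg.carbon_slab:
        x_edge = (3 * nx) // 4
        carbon = np.zeros(shape, dtype=bool)
        carbon[:, :, x_edge:] = True
        gt["carbon"] = carbon
        occupied |= carbon
        x_limit = x_edge

    thickness = cfg.nm_to_px(cfg.membrane_thickness_nm)
    offset = cfg.nm_to_px(cfg.platform_offset_nm)
    p_rad = cfg.nm_to_px(cfg.platform_radius_nm)

    vesicles: list[tuple[np.ndarray, float]] = []  # (center, outer radius px)
    if cfg.n_vesicles:
        membrane = np.zeros(shape, dtype=bool)
        # platforms pick their own direction later by rejection sampling, so
        # only the shell itself must fit; a platform-sized clearance keeps
        # neighbouring vesicles from walling each other in completely
        clearance = (offset + p_rad + 2.0) if cfg.n_platforms else 1.0
        for i in range(cfg.n_vesicles):
            for attempt in range(_MAX_TRIES):
                r = cfg.nm_to_px(rng.uniform(*cfg.vesicle_radius_range))
                if 2 * r + 4 >= min(nz, ny, x_limit):
                    continue
                center = np.array([
                    rng.uniform(r + 1, nz - r - 1),
                    rng.uniform(r + 1, ny - r - 1),
                    rng.uniform(r + 1, x_limit - r - 1),
                ])
                if any(np.linalg.norm(center - c) < r + rv + clearance
                       for c, rv in vesicles):
                    continue
                idx = _shell_voxels(shape, center, r, thickness)
                if occupied[idx].any():
                    continue
                membrane[idx] = True
                occupied[idx] = True
                vesicles.append((center, r))
                break
            else:
                raise PlacementError(
                    f"could not place vesicle {i + 1}/{cfg.n_vesicles} without overlap "
                    f"in shape {shape}"
                )
        gt["membrane"] = membrane

    if cfg.n_platforms:
        platform = np.zeros(shape, dtype=bool)
        half_t = cfg.nm_to_px(cfg.platform_thickness_nm) / 2.0
        for i in range(cfg.n_platforms):
            for attempt in range(_MAX_TRIES):
                center_v, r_v = vesicles[int(rng.integers(len(vesicles)))]
                n_z = rng.uniform(-cfg.platform_axial_fraction, cfg.platform_axial_fraction)
                phi = rng.uniform(0.0, 2.0 * np.pi)
                lat = np.sqrt(1.0 - n_z * n_z)
                normal = np.array([n_z, lat * np.sin(phi), lat * np.cos(phi)])
                center = center_v + normal * (r_v + offset)
                if ((center < 1).any()
                        or (center > np.array(shape) - 2).any()
                        or center[2] >= x_limit - 1):
                    continue
                idx = _disc_voxels(shape, center, normal, p_rad, half_t)
                if len(idx[0]) == 0 or occupied[idx].any() or platform[idx].any():
                    continue
                platform[idx] = True
                break
            else:
                raise PlacementError(
                    f"could not place platform {i + 1}/{cfg.n_platforms}: no free "
                    f"membrane-adjacent site at offset {cfg.platform_offset_nm} nm"
                )
        occupied |= platform
        gt["platform"] = platform

    if cfg.n_granules:
        granule = np.zeros(shape, dtype=bool)
        for i in range(cfg.n_granules):
            for attempt in range(_MAX_TRIES):
                r = cfg.nm_to_px(rng.uniform(*cfg.granule_radius_range))
                center = np.array([
                    rng.uniform(r + 1, nz - r - 1),
                    rng.uniform(r + 1, ny - r - 1),
                    rng.uniform(r + 1, x_limit - r - 1),
                ])
                idx = _ball_voxels(shape, center, r)
                if occupied[idx].any():
                    continue
                granule[idx] = True
                occupied[idx] = True
                break
            else:
                raise PlacementError(
                    f"could not place granule {i + 1}/{cfg.n_granules} without overlap"
                )
        gt["granule"] = granule

    if cfg.n_filaments:
        filament = np.zeros(shape, dtype=bool)
        r_f = cfg.nm_to_px(cfg.filament_radius_nm)
        for i in range(cfg.n_filaments):
            for attempt in range(_MAX_TRIES):
                length = cfg.nm_to_px(rng.uniform(*cfg.filament_length_range))
                direction = _random_unit(rng)
                start = np.array([
                    rng.uniform(r_f + 1, nz - r_f - 1),
                    rng.uniform(r_f + 1, ny - r_f - 1),
                    rng.uniform(r_f + 1, x_limit - r_f - 1),
                ])
                end = start + direction * length
                if ((end < r_f + 1).any()
                        or (end > np.array(shape) - r_f - 2).any()
                        or end[2] > x_limit - r_f - 2):
                    continue
                # paint overlapping balls along the axis
                steps = max(2, int(np.ceil(length / max(r_f / 2.0, 0.5))) + 1)
                zz_all, yy_all, xx_all = [], [], []
                for t in np.linspace(0.0, 1.0, steps):
                    idx = _ball_voxels(shape, start + t * (end - start), r_f)
                    zz_all.append(idx[0]); yy_all.append(idx[1]); xx_all.append(idx[2])
                idx = tuple(np.concatenate(a) for a in (zz_all, yy_all, xx_all))
                if occupied[idx].any():
                    continue
                filament[idx] = True
                occupied[idx] = True
                break
            else:
                raise PlacementError(
                    f"could not place filament {i + 1}/{cfg.n_filaments} without overlap"
                )
        gt["filament"] = filament

    density = np.zeros(shape, dtype=np.float32)
    for mask in gt.values():
        density[mask] = cfg.contrast
    if cfg.z_blur_sigma > 0:
        density = ndimage.gaussian_filter1d(density, cfg.z_blur_sigma, axis=0)
    if cfg.invert:
        density = -density
    if cfg.noise_sigma > 0:
        density = density + rng.normal(0.0, cfg.noise_sigma, size=shape).astype(np.float32)

    vol = Volume3D(density.astype(np.float32), cfg.pixel_size)
    gt_vols = {k: Volume3D(v.astype(np.float32), cfg.pixel_size) for k, v in gt.items()}
    return vol, gt_vols


def generate_training_boxes(
    phantom: tuple[Volume3D, dict[str, Volume3D]],
    feature: str,
    n_pos: int,
    n_neg: int,
    box_size: int = 64,
    seed: int = 0,
) -> list[AnnotationBox]:
    """Sample annotation boxes for one feature from a generated phantom.

    Positive boxes are centred on random foreground voxels of the feature
    (centres clamped so the crop fits) with ground-truth label crops;
    negative boxes are centred at least one box-width away from any
    foreground voxel of the feature and carry all-zero labels.
    """
    volume, gt = phantom
    if feature not in gt:
        raise KeyError(
            f"feature {feature!r} not in phantom ground truth "
            f"(available: {', '.join(sorted(gt))})"
        )
    rng = np.random.default_rng(seed)
    fg = gt[feature].data > 0.5
    nz, ny, nx = fg.shape
    half = box_size // 2

    def _clamp(c, dim):
        return int(min(max(c, half), dim - half))

    boxes: list[AnnotationBox] = []

    pos_candidates = np.argwhere(fg)
    if len(pos_candidates) < n_pos:
        raise ValueError(
            f"requested {n_pos} positive boxes but only {len(pos_candidates)} "
            f"foreground voxels of {feature!r} exist"
        )
    for z, y, x in pos_candidates[rng.choice(len(pos_candidates), n_pos, replace=False)]:
        cx, cy = _clamp(x, nx), _clamp(y, ny)
        label = fg[z, cy - half : cy + half, cx - half : cx + half].astype(np.float32)
        boxes.append(AnnotationBox("phantom", int(z), (cx, cy), True, label))

    if n_neg:
        dist = ndimage.distance_transform_edt(~fg)
        neg_candidates = np.argwhere(dist >= box_size)
        if len(neg_candidates) < n_neg:
            raise ValueError(
                f"requested {n_neg} negative boxes but only {len(neg_candidates)} voxels "
                f"lie >= {box_size} px from {feature!r} foreground"
            )
        zeros = np.zeros((box_size, box_size), dtype=np.float32)
        for z, y, x in neg_candidates[rng.choice(len(neg_candidates), n_neg, replace=False)]:
            boxes.append(
                AnnotationBox("phantom", int(z), (_clamp(x, nx), _clamp(y, ny)), False, zeros)
            )
    return boxes
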