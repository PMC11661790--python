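"""Isosurface extraction and dust removal for segmented volumes."""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .core import Mesh, Volume3D

__all__ = ["volume_to_mesh", "filter_dust"]

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def volume_to_mesh(pred: Volume3D, iso_level: float = 0.5, feature_name: str = "") -> Mesh:
    """Triangulate the isosurface of a prediction volume (marching cubes).

    Vertices are returned in Angstrom, ``(x, y, z)``, scaled by the voxel
    size and shifted by the volume origin; faces are consistently wound
    triangles.  If no voxel crosses ``iso_level`` an empty mesh is returned.
    """
    data = pred.data
    if not (data.min() < iso_level <= data.max()):
        log.info("no voxel crosses iso level %g; returning an empty mesh", iso_level)
        return Mesh(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64), feature_name)
    verts, faces, _, _ = marching_cubes(
        data, level=iso_level, spacing=(pred.voxel_size,) * 3
    )
    # marching_cubes yields (z, y, x); flip to (x, y, z) and re-orient faces
    # so the winding convention is preserved under the axis swap.
    verts_xyz = verts[:, ::-1] + pred.origin[None, :]
    faces = faces[:, ::-1]
    return Mesh(verts_xyz, faces.astype(np.int64), feature_name)


def filter_dust(pred: Volume3D, iso_level: float = 0.5, min_volume_nm3: float = 0.0) -> Volume3D:
    """Zero out small connected components ("dust") of the thresholded volume.

    Components of ``pred >= iso_level`` (26-connectivity, matching picking)
    whose physical volume is below ``min_volume_nm3`` are set to zero in the
    returned copy; retained components are untouched.
    """
    out = pred.copy()
    if min_volume_nm3 <= 0:
        return out
    binary = pred.data >= iso_level
    labels, n = ndimage.label(binary, structure=_CONN26)
    if n == 0:
        return out
    voxel_nm3 = (pred.voxel_size / 10.0) ** 3
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts * voxel_nm3 < min_volume_nm3)
    small = small[small != 0]
    if len(small):
        out.data[np.isin(labels, small)] = 0.0
    return out
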