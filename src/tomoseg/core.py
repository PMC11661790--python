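"""Core domain containers shared across the toolkit.

Conventions used throughout:

* Volumes are numpy arrays indexed ``[z][y][x]`` (slice-major, matching the
  on-disk MRC layout with x fastest).
* Particle and voxel coordinates in user-facing records are 0-based
  ``(x, y, z)`` integer voxel indices.  Some extraction tools expect 1-based
  coordinates; :func:`tomoseg.io.write_particles` has a ``one_based`` flag.
* Physical lengths are Angstrom unless a name says ``_nm`` (1 nm = 10 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume3D", "ParticleSet", "Mesh"]


@dataclass
class Volume3D:
    """A 3D scalar grid with an isotropic voxel size.

    Parameters
    ----------
    data:
        float32 array indexed ``[z][y][x]``.
    voxel_size:
        Edge length of one voxel in Angstrom.
    origin:
        Physical origin of voxel (0, 0, 0) in Angstrom, ``(x, y, z)``.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.float64))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume data must be 3D with all dimensions >= 1, got shape {self.data.shape}"
            )
        self.voxel_size = float(self.voxel_size)
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # (nz, ny, nx)

    def is_prediction(self, atol: float = 0.0) -> bool:
        """True if every value lies in [0, 1] (within ``atol``)."""
        return bool(self.data.min() >= -atol and self.data.max() <= 1.0 + atol)

    def require_prediction(self) -> None:
        if not self.is_prediction(atol=1e-6):
            raise ValueError(
                "expected a prediction volume with values in [0, 1]; "
                f"got range [{self.data.min():g}, {self.data.max():g}]"
            )

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.voxel_size, self.origin.copy())


@dataclass
class ParticleSet:
    """Picked particle coordinates with per-particle weights.

    ``coordinates`` is an ``(n, 3)`` integer array of 0-based ``(x, y, z)``
    voxel indices; ``weights`` the summed prediction value of each particle's
    voxel group.
    """

    coordinates: np.ndarray
    weights: np.ndarray
    feature_name: str = ""
    source_volume: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.int64).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        if len(self.weights) != len(self.coordinates):
            raise ValueError(
                f"{len(self.weights)} weights for {len(self.coordinates)} coordinates"
            )
        if len(self.weights) and self.weights.min() < 0:
            raise ValueError("particle weights must be non-negative")

    def __len__(self) -> int:
        return len(self.coordinates)

    def validate_bounds(self, volume: Volume3D) -> None:
        """Raise if any coordinate falls outside ``volume``."""
        if len(self) == 0:
            return
        nz, ny, nx = volume.shape
        limits = np.array([nx, ny, nz])
        if (self.coordinates < 0).any() or (self.coordinates >= limits).any():
            raise ValueError("particle coordinates outside the source volume bounds")


@dataclass
class Mesh:
    """A triangulated surface in physical (Angstrom) coordinates."""

    vertices: np.ndarray  # (n, 3) float, (x, y, z) in Angstrom
    faces: np.ndarray  # (m, 3) int, 0-based vertex indices
    feature_name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.validate()

    def validate(self) -> None:
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError(
                    f"face index out of range: mesh has {len(self.vertices)} vertices "
                    f"but faces reference up to {self.faces.max()}"
                )

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0
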