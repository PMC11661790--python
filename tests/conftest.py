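import numpy as np
import pytest

from tomoseg.core import Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    """A small random prediction volume in [0, 1]."""
    return Volume3D(rng.random((12, 20, 24), dtype=np.float32), voxel_size=10.0)


def make_sphere_volume(shape, centers, radii, value=1.0, voxel_size=10.0, soft=False):
    """Paint solid spheres; with ``soft`` the edge is anti-aliased so the 0.5
    isosurface sits exactly at the nominal radius."""
    data = np.zeros(shape, dtype=np.float32)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    for (cz, cy, cx), r in zip(centers, radii):
        d = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
        if soft:
            data = np.maximum(data, np.clip(r - d + 0.5, 0.0, 1.0) * value)
        else:
            data = np.maximum(data, (d <= r).astype(np.float32) * value)
    return Volume3D(data, voxel_size=voxel_size)
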