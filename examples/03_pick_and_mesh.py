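"""Pick particles from a segmented volume and export a surface mesh.

Builds a prediction volume with two blobs plus a touching dumbbell pair,
runs the watershed picking procedure (threshold, distance transform,
watershed, volume filter, spacing suppression, centroid report) and writes
the coordinates as tab-separated text and the surface as Wavefront OBJ.
"""

import numpy as np

from tomoseg import PickConfig, Volume3D, pick_particles, volume_to_mesh
from tomoseg import write_mesh_obj, write_particles

shape = (40, 64, 64)
zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
data = np.zeros(shape, dtype=np.float32)
# two isolated blobs and a dumbbell (two spheres sharing a neck)
for center, r in [((12, 16, 16), 4), ((28, 48, 48), 4),
                  ((20, 44, 14), 5), ((20, 44, 23), 5)]:
    d = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    data = np.maximum(data, np.clip(r - d + 0.5, 0, 1))
pred = Volume3D(data, voxel_size=10.0)  # 10 A / voxel = 1 nm

cfg = PickConfig(threshold=0.5, min_volume_nm3=20.0, min_spacing_nm=5.0,
                 pixel_size=10.0)
particles = pick_particles(pred, cfg, feature_name="granule")
print(f"picked {len(particles)} particles (x, y, z; weight):")
for coord, w in zip(particles.coordinates, particles.weights):
    print(f"  {tuple(int(c) for c in coord)}  {w:.1f}")
# the dumbbell contributes two particles: the watershed splits it at the neck

write_particles(particles, "particles.txt", dialect="tsv")
mesh = volume_to_mesh(pred, iso_level=0.5, feature_name="granule")
write_mesh_obj(mesh, "granule.obj")
print(f"wrote particles.txt and granule.obj "
      f"({len(mesh.vertices)} vertices, {len(mesh.faces)} triangles)")
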