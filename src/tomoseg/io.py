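"""Reading and writing the interchange formats of the cryoET field.

Volumes travel as MRC2014 files, particle coordinate lists as tab-separated
text or minimal RELION-style STAR files, and surfaces as Wavefront OBJ.

The MRC implementation covers the MRC2014 standard: modes 0 (int8),
1 (int16), 2 (float32) and 6 (uint16) on read, mode 2 on write, with the
voxel size taken from ``cella / (mx, my, mz)`` and axis order normalised to
``[z][y][x]`` using the ``mapc/mapr/maps`` header words.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np

from .core import Mesh, ParticleSet, Volume3D

__all__ = [
    "MRCFormatError",
    "read_mrc",
    "write_mrc",
    "write_particles",
    "read_particles",
    "write_mesh_obj",
    "read_mesh_obj",
]

log = logging.getLogger(__name__)

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: "i1", 1: "i2", 2: "f4", 6: "u2"}


class MRCFormatError(ValueError):
    """Raised for malformed or unsupported MRC files."""


def _machine_stamp_little(stamp: bytes) -> bool:
    # 0x44 0x44 (or 0x44 0x41) => little endian; 0x11 0x11 => big endian.
    if stamp[:1] == b"\x44":
        return True
    if stamp[:1] == b"\x11":
        return False
    # Unwritten stamps are common in old files; assume little endian.
    return True


def read_mrc(path) -> Volume3D:
    """Read an MRC2014 volume, normalising axis order to ``[z][y][x]``.

    Supports modes 0, 1, 2 and 6; data is cast to float32.  The voxel size is
    ``cella.x / mx`` (x spacing); anisotropic headers trigger a warning.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise MRCFormatError(f"{path}: file too short for an MRC header ({len(raw)} bytes)")

    header = raw[:_HEADER_SIZE]
    little = _machine_stamp_little(header[212:214])
    end = "<" if little else ">"

    nx, ny, nz, mode = struct.unpack(end + "4i", header[0:16])
    mx, my, mz = struct.unpack(end + "3i", header[28:40])
    cella = struct.unpack(end + "3f", header[40:52])
    mapc, mapr, maps = struct.unpack(end + "3i", header[64:76])
    nsymbt = struct.unpack(end + "i", header[92:96])[0]
    origin = struct.unpack(end + "3f", header[196:208])

    if mode not in _MODE_DTYPES:
        raise MRCFormatError(f"{path}: unsupported MRC mode {mode} (supported: 0, 1, 2, 6)")
    if min(nx, ny, nz) < 1:
        raise MRCFormatError(f"{path}: invalid dimensions ({nx}, {ny}, {nz})")

    dtype = np.dtype(end + _MODE_DTYPES[mode])
    count = nx * ny * nz
    offset = _HEADER_SIZE + max(nsymbt, 0)
    if len(raw) < offset + count * dtype.itemsize:
        raise MRCFormatError(
            f"{path}: truncated data section (expected {count} mode-{mode} values)"
        )
    flat = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)

    # On disk the mapc axis varies fastest, maps slowest: shape (n_maps, n_mapr, n_mapc).
    axes = (mapc, mapr, maps)
    if sorted(axes) != [1, 2, 3]:
        raise MRCFormatError(f"{path}: invalid axis correspondence mapc/mapr/maps = {axes}")
    dims = {1: nx, 2: ny, 3: nz}
    data = flat.reshape(dims[maps], dims[mapr], dims[mapc])
    if axes != (1, 2, 3):
        # Transpose so that array axis 0 = z (axis 3), 1 = y (2), 2 = x (1).
        disk_axes = (maps, mapr, mapc)  # slowest..fastest
        data = np.transpose(data, [disk_axes.index(a) for a in (3, 2, 1)])

    spacings = [cella[i] / d if d > 0 else 0.0 for i, d in enumerate((mx, my, mz))]
    voxel_size = spacings[0] if spacings[0] > 0 else 1.0
    if any(abs(s - voxel_size) > 1e-4 * voxel_size for s in spacings[1:] if s > 0):
        log.warning(
            "%s: anisotropic voxel size %s; using x spacing %.4g A", path, spacings, voxel_size
        )

    return Volume3D(
        # astype(copy=True): the frombuffer view is read-only
        data=data.astype(np.float32, copy=True),
        voxel_size=voxel_size,
        origin=np.asarray(origin, dtype=np.float64),
    )


def write_mrc(volume: Volume3D, path) -> Path:
    """Write ``volume`` as an MRC2014 mode-2 (float32) file."""
    path = Path(path)
    data = np.ascontiguousarray(volume.data, dtype="<f4")
    nz, ny, nx = data.shape
    vs = volume.voxel_size

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)  # nx ny nz mode
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart nystart nzstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx my mz
    struct.pack_into("<3f", header, 40, nx * vs, ny * vs, nz * vs)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc mapr maps
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )  # dmin dmax dmean
    struct.pack_into("<2i", header, 88, 1, 0)  # ispg, nsymbt
    struct.pack_into("<3f", header, 196, *volume.origin)  # origin x y z
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))  # rms
    struct.pack_into("<i", header, 220, 1)  # nlabl
    label = b"tomoseg: MRC2014 mode 2"
    header[224 : 224 + len(label)] = label

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data.tobytes())
    return path


def write_particles(particles: ParticleSet, path, dialect: str = "tsv", one_based: bool = False) -> Path:
    """Serialise particle coordinates.

    ``tsv``: one ``x<TAB>y<TAB>z`` line per particle, integers, no header.
    ``star``: a single ``data_`` block with a loop over
    ``_rlnCoordinateX/Y/Z``.  ``one_based`` adds 1 to every coordinate for
    downstream extraction tools that index from 1.
    """
    path = Path(path)
    coords = particles.coordinates + (1 if one_based else 0)
    if dialect == "tsv":
        lines = [f"{x}\t{y}\t{z}" for x, y, z in coords]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif dialect == "star":
        head = (
            "\ndata_particles\n\nloop_\n"
            "_rlnCoordinateX #1\n_rlnCoordinateY #2\n_rlnCoordinateZ #3\n"
        )
        body = "".join(f"{x}\t{y}\t{z}\n" for x, y, z in coords)
        path.write_text(head + body)
    else:
        raise ValueError(f"unknown particle dialect {dialect!r} (expected 'tsv' or 'star')")
    return path


def read_particles(path, feature_name: str = "") -> ParticleSet:
    """Read a tsv or STAR coordinate file (dialect detected from content)."""
    path = Path(path)
    text = path.read_text()
    rows: list[tuple[int, int, int]] = []
    if "loop_" in text:
        in_loop = False
        for line in text.splitlines():
            s = line.strip()
            if s == "loop_":
                in_loop = True
                continue
            if not in_loop or not s or s.startswith("_") or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) >= 3:
                rows.append(tuple(int(round(float(p))) for p in parts[:3]))
    else:
        for line in text.splitlines():
            s = line.strip()
            if s:
                x, y, z = s.split("\t")[:3]
                rows.append((int(x), int(y), int(z)))
    coords = np.array(rows, dtype=np.int64).reshape(-1, 3)
    return ParticleSet(coords, np.zeros(len(coords)), feature_name=feature_name,
                       source_volume=str(path))


def write_mesh_obj(mesh: Mesh, path) -> Path:
    """Write a Wavefront OBJ with 1-based face indices."""
    mesh.validate()
    path = Path(path)
    with open(path, "w") as fh:
        if mesh.feature_name:
            fh.write(f"# tomoseg mesh: {mesh.feature_name}\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.6g} {y:.6g} {z:.6g}\n")
        for i, j, k in mesh.faces + 1:
            fh.write(f"f {i} {j} {k}\n")
    return path


def read_mesh_obj(path) -> Mesh:
    """Parse vertex/face lines of an OBJ file (triangles only)."""
    vertices, faces = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            vertices.append([float(p) for p in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            if len(idx) != 3:
                raise ValueError(f"non-triangular face with {len(idx)} vertices")
            faces.append(idx)
    return Mesh(
        np.array(vertices, dtype=np.float64).reshape(-1, 3),
        np.array(faces, dtype=np.int64).reshape(-1, 3),
    )
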