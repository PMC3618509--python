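"""Mesh import/export: GeomView OFF, ascii PLY, MSMS .vert/.face pairs.

Imported meshes are manifold-checked (the framework's closed-surface
hypothesis); exports are plain text so round trips preserve coordinates to
printed precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .base import MeshSurface

__all__ = ["load_mesh_surface", "export_mesh"]


def _read_off(path):
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise ValueError(f"{path}: missing OFF header")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = np.array(tokens[pos:pos + 3 * nv], float).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        cnt = int(tokens[pos])
        poly = [int(v) for v in tokens[pos + 1: pos + 1 + cnt]]
        pos += 1 + cnt
        for i in range(1, cnt - 1):  # fan-triangulate polygons
            faces.append((poly[0], poly[i], poly[i + 1]))
    return verts, np.array(faces, int)


def _read_ply(path):
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        nv = nf = 0
        props = 0
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated header")
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "format" and parts[1] != "ascii":
                raise ValueError(f"{path}: only ascii PLY supported")
            if parts[0] == "element":
                in_vertex = parts[1] == "vertex"
                if in_vertex:
                    nv = int(parts[2])
                elif parts[1] == "face":
                    nf = int(parts[2])
            elif parts[0] == "property" and in_vertex:
                props += 1
            elif parts[0] == "end_header":
                break
        verts = np.empty((nv, 3))
        for i in range(nv):
            vals = fh.readline().split()
            verts[i] = [float(v) for v in vals[:3]]
        faces = []
        for _ in range(nf):
            vals = [int(v) for v in fh.readline().split()]
            poly = vals[1:1 + vals[0]]
            for i in range(1, len(poly) - 1):
                faces.append((poly[0], poly[i], poly[i + 1]))
    return verts, np.array(faces, int)


def _read_msms(stem):
    """MSMS .vert/.face pair: 3-line headers, 1-based indices."""
    stem = str(stem)
    if stem.endswith((".vert", ".face")):
        stem = stem[:-5]
    verts = []
    with open(stem + ".vert") as fh:
        lines = [ln for ln in fh if ln.strip()]
    for ln in lines[3:]:
        verts.append([float(v) for v in ln.split()[:3]])
    faces = []
    with open(stem + ".face") as fh:
        lines = [ln for ln in fh if ln.strip()]
    for ln in lines[3:]:
        a, b, c = (int(v) for v in ln.split()[:3])
        faces.append((a - 1, b - 1, c - 1))
    return np.asarray(verts, float), np.asarray(faces, int)


def load_mesh_surface(path, fmt=None, check_manifold=True) -> MeshSurface:
    path = Path(path)
    if fmt is None:
        fmt = {".off": "off", ".ply": "ply", ".vert": "msms", ".face": "msms"}.get(
            path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer mesh format of {path}")
    if fmt == "off":
        v, f = _read_off(path)
    elif fmt == "ply":
        v, f = _read_ply(path)
    elif fmt == "msms":
        v, f = _read_msms(path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
    return MeshSurface(v, f, check_manifold=check_manifold)


def export_mesh(mesh, path, fmt=None):
    """Write OFF / ascii PLY / MSMS .vert+.face (1-based indices)."""
    path = Path(path)
    if fmt is None:
        fmt = {".off": "off", ".ply": "ply", ".vert": "msms", ".face": "msms"}.get(
            path.suffix.lower(), "off")
    verts = np.asarray(mesh.vertices, float)
    faces = np.asarray(mesh.faces, int)
    if fmt == "off":
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{len(verts)} {len(faces)} 0\n")
            for v in verts:
                fh.write(f"{v[0]:.12f} {v[1]:.12f} {v[2]:.12f}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    elif fmt == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(verts)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {len(faces)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in verts:
                fh.write(f"{v[0]:.12f} {v[1]:.12f} {v[2]:.12f}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    elif fmt == "msms":
        stem = str(path)
        if stem.endswith((".vert", ".face")):
            stem = stem[:-5]
        with open(stem + ".vert", "w") as fh:
            fh.write("# vertices\n#\n" f"{len(verts)} 0 0.0 0.0\n")
            for v in verts:
                fh.write(f"{v[0]:.12f} {v[1]:.12f} {v[2]:.12f}\n")
        with open(stem + ".face", "w") as fh:
            fh.write("# faces\n#\n" f"{len(faces)} 0 0.0 0.0\n")
            for f in faces:
                fh.write(f"{f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
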