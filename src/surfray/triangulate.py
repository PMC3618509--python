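"""Grid-consistent triangulation: Analytical-Intersections Marching Cubes.

Marching Cubes is used only for its case tables: the triangle vertices are
not interpolated from a scalar field but placed at the analytic ray-surface
crossings stored on the grid edges, so every vertex lies on the surface to
numerical accuracy and no triangle crosses a cube boundary (each triangle
is owned by exactly one cube, making per-cube restricted areas a sum).

The 256-case table is derived at import time: cut edges of each
configuration are paired around the cube faces (on an ambiguous face the
two cut edges sharing an *inside* corner are paired, so diagonal inside
corners are never connected: a fixed, symmetric rule that cannot produce
cracks between neighbouring cubes), chained into closed cycles, fanned into
triangles, and oriented so normals point from material to solvent.

The Bisecting variant runs from cube-center statuses alone (one third of
the rays): vertex statuses are inferred by majority over the eight
surrounding cube centers and the triangle vertices fall back to the edge
midpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .raycast import EdgeHits, Grid3D

__all__ = [
    "MCTables", "TriMesh", "mc_analytic", "mc_bisecting", "laplacian_smooth",
    "mesh_area", "incident_ray_area", "export_mesh",
]

# cube vertex offsets (standard MC ordering is unnecessary here; the table
# is self-consistent with these definitions)
_VERTS = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
          (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
_EDGES = [(0, 1), (1, 2), (3, 2), (0, 3),
          (4, 5), (5, 6), (7, 6), (4, 7),
          (0, 4), (1, 5), (2, 6), (3, 7)]
# faces as corner quadruples (cyclic order)
_FACES = [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
          (3, 2, 6, 7), (0, 3, 7, 4), (1, 2, 6, 5)]

_EDGE_INDEX = {}
for _ei, (_a, _b) in enumerate(_EDGES):
    _EDGE_INDEX[(_a, _b)] = _ei
    _EDGE_INDEX[(_b, _a)] = _ei


def _face_edges(face):
    return [_EDGE_INDEX[(face[i], face[(i + 1) % 4])] for i in range(4)]


def _build_case(case: int):
    inside = [bool(case & (1 << v)) for v in range(8)]
    cut = [ei for ei, (a, b) in enumerate(_EDGES) if inside[a] != inside[b]]
    if not cut:
        return []
    # pair cut edges within each face
    links = {ei: [] for ei in cut}
    for face in _FACES:
        fe = [ei for ei in _face_edges(face) if ei in links]
        if len(fe) == 2:
            a, b = fe
            links[a].append(b)
            links[b].append(a)
        elif len(fe) == 4:
            # ambiguous face: pair the cut edges sharing an inside corner
            for corner in face:
                if not inside[corner]:
                    continue
                touch = [ei for ei in fe if corner in _EDGES[ei]]
                if len(touch) == 2:
                    a, b = touch
                    links[a].append(b)
                    links[b].append(a)
    # chain into closed cycles
    cycles = []
    remaining = set(cut)
    while remaining:
        start = min(remaining)
        cyc = [start]
        remaining.discard(start)
        prev, cur = None, start
        while True:
            nxts = [e for e in links[cur] if e != prev]
            nxt = nxts[0] if nxts else links[cur][0]
            if nxt == start:
                break
            cyc.append(nxt)
            remaining.discard(nxt)
            prev, cur = cur, nxt
        cycles.append(cyc)

    mids = [0.5 * (np.array(_VERTS[a], float) + np.array(_VERTS[b], float))
            for a, b in _EDGES]
    tris = []
    for cyc in cycles:
        pts = [mids[e] for e in cyc]
        # Newell normal of the polygon
        nrm = np.zeros(3)
        for i in range(len(pts)):
            p, q = pts[i], pts[(i + 1) % len(pts)]
            nrm += np.cross(p, q)
        # inside corners touched by this cycle
        corners = []
        for e in cyc:
            a, b = _EDGES[e]
            corners.append(_VERTS[a] if inside[a] else _VERTS[b])
        ref = np.mean(pts, axis=0) - np.mean(np.array(corners, float), axis=0)
        if float(nrm @ ref) < 0.0:
            cyc = cyc[::-1]
        for i in range(1, len(cyc) - 1):
            tris.append((cyc[0], cyc[i], cyc[i + 1]))
    return tris


class MCTables:
    """The 256-case -> triangle-fan lookup, built once at import."""

    def __init__(self):
        self.cases = [_build_case(c) for c in range(256)]

    def __getitem__(self, case):
        return self.cases[case]


TABLES = MCTables()


# ---------------------------------------------------------------------------

@dataclass
class TriMesh:
    """Grid-consistent triangulation with per-triangle owning cube."""

    vertices: np.ndarray
    faces: np.ndarray
    owners: np.ndarray  # (n_tri, 3) cube lattice indices
    provenance: list = None  # per-vertex: "hit" | "midpoint" | "smoothed"
    grid: Grid3D = None
    midpoint_fallbacks: int = 0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, int).reshape(-1, 3)
        self.owners = np.asarray(self.owners, int).reshape(-1, 3)

    # -- topology -----------------------------------------------------------

    def edges(self):
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self):
        return len(self.vertices) - len(self.edges()) + len(self.faces)

    def is_closed(self):
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def genus(self):
        return (2 - self.euler_characteristic()) // 2

    def triangle_normals(self):
        v = self.vertices
        f = self.faces
        return np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])

    def area(self):
        return 0.5 * float(np.linalg.norm(self.triangle_normals(), axis=1).sum())

    def enclosed_volume(self):
        """Divergence-theorem volume (positive for outward orientation)."""
        v = self.vertices
        f = self.faces
        return float(np.einsum("ij,ij->i", v[f[:, 0]],
                               np.cross(v[f[:, 1]], v[f[:, 2]])).sum()) / 6.0


# ---------------------------------------------------------------------------

def _iter_surface_cubes(vertex_status):
    """Yield (i, j, k, case) for cubes with mixed vertex statuses."""
    s = vertex_status.astype(np.uint16)
    case = np.zeros(tuple(d - 1 for d in vertex_status.shape), np.uint16)
    for bit, (dx, dy, dz) in enumerate(_VERTS):
        case |= s[dx:dx + case.shape[0],
                  dy:dy + case.shape[1],
                  dz:dz + case.shape[2]] << bit
    mixed = np.argwhere((case != 0) & (case != 255))
    for i, j, k in mixed:
        yield int(i), int(j), int(k), int(case[i, j, k])


def _edge_key(cube, edge_id):
    """Global (axis, lower-vertex index) key of a cube's local edge."""
    a, b = _EDGES[edge_id]
    va = np.array(_VERTS[a], int)
    vb = np.array(_VERTS[b], int)
    axis = int(np.nonzero(va != vb)[0][0])
    low = np.minimum(va, vb) + np.asarray(cube, int)
    return axis, (int(low[0]), int(low[1]), int(low[2]))


def _run_mc(vertex_status, grid, vertex_position):
    verts = []
    prov = []
    faces = []
    owners = []
    vert_index = {}
    fallbacks = [0]

    def vid(cube, edge_id):
        key = _edge_key(cube, edge_id)
        if key not in vert_index:
            pos, tag = vertex_position(key)
            if tag == "midpoint-fallback":
                fallbacks[0] += 1
                tag = "midpoint"
            vert_index[key] = len(verts)
            verts.append(pos)
            prov.append(tag)
        return vert_index[key]

    for i, j, k, case in _iter_surface_cubes(vertex_status):
        for tri in TABLES[case]:
            ids = [vid((i, j, k), e) for e in tri]
            if ids[0] == ids[1] or ids[1] == ids[2] or ids[0] == ids[2]:
                continue
            faces.append(ids)
            owners.append((i, j, k))

    return TriMesh(np.array(verts, float).reshape(-1, 3),
                   np.array(faces, int).reshape(-1, 3),
                   np.array(owners, int).reshape(-1, 3),
                   provenance=prov, grid=grid,
                   midpoint_fallbacks=fallbacks[0])


def mc_analytic(vertex_status, edge_hits: EdgeHits, grid: Grid3D) -> TriMesh:
    """Marching cubes with vertices at the stored analytic edge crossings.

    On an edge holding several crossings the one nearest the *outside*
    endpoint is kept (the visible crossing; sub-cell detail below grid
    resolution is smoothed away).  A mixed edge left without a hit (e.g.
    residue of cavity filling) falls back to the edge midpoint and is
    counted in ``midpoint_fallbacks``.
    """
    h = grid.spacing
    vs = vertex_status

    def position(key):
        axis, (i, j, k) = key
        lo_v = grid.origin + h * np.array([i, j, k], float)
        hi_idx = [i, j, k]
        hi_idx[axis] += 1
        hits = edge_hits.get(axis, (i, j, k))
        lo_inside = bool(vs[i, j, k])
        hi_inside = bool(vs[tuple(hi_idx)])
        if hits:
            if len(hits) == 1:
                return hits[0][0], "hit"
            # pick the hit nearest the outside endpoint
            out_coord = (lo_v[axis] if not lo_inside
                         else lo_v[axis] + h)
            best = min(hits, key=lambda pn: abs(pn[0][axis] - out_coord))
            return best[0], "hit"
        mid = lo_v.copy()
        mid[axis] += 0.5 * h
        return mid, "midpoint-fallback"

    return _run_mc(vs, grid, position)


def mc_bisecting(status, grid: Grid3D = None) -> TriMesh:
    """Bisecting Marching Cubes: cube-center statuses only (no Edge Rays).

    Cube-vertex statuses are the majority of the eight surrounding cube
    centers (ties go outside); triangle vertices sit at edge midpoints.
    """
    centers = status.centers if hasattr(status, "centers") else np.asarray(status)
    grid = grid or status.grid
    nc = centers.shape
    pad = np.zeros((nc[0] + 2, nc[1] + 2, nc[2] + 2), np.int8)
    pad[1:-1, 1:-1, 1:-1] = centers
    nv = (nc[0] + 1, nc[1] + 1, nc[2] + 1)
    votes = np.zeros(nv, np.int8)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                votes += pad[dx:dx + nv[0], dy:dy + nv[1], dz:dz + nv[2]]
    vertex_status = votes > 4  # majority of 8; ties -> outside

    h = grid.spacing

    def position(key):
        axis, (i, j, k) = key
        mid = grid.origin + h * np.array([i, j, k], float)
        mid[axis] += 0.5 * h
        return mid, "midpoint"

    return _run_mc(vertex_status, grid, position)


# ---------------------------------------------------------------------------

def laplacian_smooth(mesh: TriMesh, iterations=1, factor=0.5) -> TriMesh:
    """Low-pass mesh filter: move each vertex toward its 1-ring centroid.

    Topology (and per-cube ownership bookkeeping) is unchanged; note that
    smoothing trades the on-surface vertex property for triangle quality.
    """
    if not (0.0 < factor < 1.0) and iterations:
        raise ValueError("smoothing factor must be in (0, 1)")
    v = mesh.vertices.copy()
    e = mesh.edges()
    for _ in range(iterations):
        acc = np.zeros_like(v)
        cnt = np.zeros(len(v))
        np.add.at(acc, e[:, 0], v[e[:, 1]])
        np.add.at(acc, e[:, 1], v[e[:, 0]])
        np.add.at(cnt, e[:, 0], 1)
        np.add.at(cnt, e[:, 1], 1)
        ok = cnt > 0
        v[ok] += factor * (acc[ok] / cnt[ok, None] - v[ok])
    prov = ["smoothed"] * len(v) if iterations else list(mesh.provenance or [])
    return TriMesh(v, mesh.faces.copy(), mesh.owners.copy(), provenance=prov,
                   grid=mesh.grid, midpoint_fallbacks=mesh.midpoint_fallbacks)


def mesh_area(mesh: TriMesh):
    """Total area and the per-owning-cube area map (they sum exactly)."""
    areas = 0.5 * np.linalg.norm(mesh.triangle_normals(), axis=1)
    per_cube = {}
    for a, cube in zip(areas, map(tuple, mesh.owners)):
        per_cube[cube] = per_cube.get(cube, 0.0) + float(a)
    return float(areas.sum()), per_cube


def per_cube_area_tsv(mesh: TriMesh, path):
    _, per_cube = mesh_area(mesh)
    with open(path, "w") as fh:
        fh.write("i\tj\tk\tarea_A2\n")
        for (i, j, k), a in sorted(per_cube.items()):
            fh.write(f"{i}\t{j}\t{k}\t{a:.9f}\n")


def incident_ray_area(surface=None, grid=None, axis=None, clamp=0.1,
                      cos_hits=None, accels=None, seed=0):
    """Incident-ray area estimator from grid-ray hit angles.

    For rays of cross-sectional cell area h^2, the estimate is
    ``A = h^2 * sum_hits 1 / max(|cos theta|, clamp)`` where theta is the
    angle between the ray and the surface normal at the hit; the clamp
    guards the division.  Returns ``(per_axis dict, averaged)``; pass a
    single ``axis`` to restrict the rays used.
    """
    if cos_hits is None:
        from .raycast import build_accel, cast_grid_rays
        if accels is None:
            accels = [build_accel(surface, grid, a) for a in range(3)]
        _, _, _, cos_hits = cast_grid_rays(surface, grid, accels, seed=seed,
                                           keep_hits=True)
    h2 = grid.spacing**2
    per_axis = {}
    for a, cosines in cos_hits.items():
        if axis is not None and a != axis:
            continue
        arr = np.asarray(cosines, float)
        per_axis[a] = float(h2 * np.sum(1.0 / np.maximum(arr, clamp))) \
            if arr.size else 0.0
    averaged = float(np.mean(list(per_axis.values()))) if per_axis else 0.0
    return per_axis, averaged


def export_mesh(mesh, path, fmt=None):
    """Export a TriMesh; delegates to the mesh IO writers."""
    from .surfaces.meshio import export_mesh as _export
    _export(mesh, path, fmt)
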