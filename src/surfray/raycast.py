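"""Cubic grid construction and grid-consistent volumetric ray casting.

Two ray families are cast along each coordinate direction:

* Grid Rays through the cube centers: in/out status at cube centers and at
  the centers of the cube faces orthogonal to the casting axis, plus the
  inside intervals used for volume estimation.
* Edge Rays along the cube-edge lattice lines: in/out status at the cube
  vertices plus the analytic surface crossings stored per grid edge, which
  become the triangulation vertices.

Every ray starts and ends outside the surface, so its crossing count must
be even (the parity checksum).  Odd counts trigger recasting with a small
random transverse jitter; after the retries are exhausted the ray copies
the classification of the nearest previously completed ray (the surface is
assumed locally constant there) and the event is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid3D", "make_grid", "Accel2D", "build_accel", "StatusGrid",
    "EdgeHits", "CastReport", "cast_ray_checked", "cast_grid_rays",
    "cast_edge_rays", "classify_points",
]

MAX_GRID_VERTICES = 40_000_000


@dataclass
class Grid3D:
    """Cubic lattice: ``dims`` counts cube *vertices* per axis (odd)."""

    origin: np.ndarray  # position of vertex (0, 0, 0)
    spacing: float
    dims: tuple  # (nx, ny, nz) vertex counts
    scale: float
    perfil: float

    @property
    def n_cubes(self):
        return tuple(d - 1 for d in self.dims)

    def vertex_coord(self, axis, i):
        return self.origin[axis] + i * self.spacing

    def center_coord(self, axis, i):
        return self.origin[axis] + (i + 0.5) * self.spacing

    def span(self):
        return self.spacing * (np.asarray(self.dims) - 1)

    def contains_box(self, lo, hi):
        glo = self.origin
        ghi = self.origin + self.span()
        return bool((np.asarray(lo) > glo).all() and (np.asarray(hi) < ghi).all())


def make_grid(obj, scale=2.0, perfil=90.0, margin=0.0) -> Grid3D:
    """Cubic grid whose span is (largest bbox side) * 100 / perfil.

    ``obj`` is an AtomSet, a SurfaceModel, or an explicit ``(lo, hi)`` box;
    ``margin`` inflates the box first (e.g. by the probe radius).  Vertex
    counts are odd (even cube counts) and h = 1/scale exactly.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not (0 < perfil < 100):
        raise ValueError("perfil must be in (0, 100)")
    if hasattr(obj, "centers"):
        lo, hi = obj.bbox(inflate=margin)
    elif hasattr(obj, "bbox"):
        lo, hi = obj.bbox()
        lo, hi = np.asarray(lo) - margin, np.asarray(hi) + margin
    else:
        lo, hi = (np.asarray(v, float) for v in obj)
        lo, hi = lo - margin, hi + margin
    side = float((hi - lo).max())
    span = side * 100.0 / perfil
    h = 1.0 / scale
    n_cubes = int(math.ceil(span / h))
    if n_cubes % 2:
        n_cubes += 1
    n_cubes = max(n_cubes, 2)
    dims = (n_cubes + 1,) * 3
    if dims[0] ** 3 > MAX_GRID_VERTICES:
        raise ValueError(
            f"grid of {dims[0]}^3 vertices exceeds the configured maximum; "
            "lower the scale or raise perfil")
    center = 0.5 * (lo + hi)
    origin = center - 0.5 * n_cubes * h
    return Grid3D(origin, h, dims, scale, perfil)


# ---------------------------------------------------------------------------
# 2-D acceleration grids
# ---------------------------------------------------------------------------

class Accel2D:
    """Per casting axis: 2-D cells listing the patches whose bounding-box
    projection intersects the cell (superset guarantee)."""

    def __init__(self, axis, lo, cell, shape, cells):
        self.axis = axis
        self.lo = lo
        self.cell = cell
        self.shape = shape
        self.cells = cells

    def candidates(self, b, c):
        ib = int((b - self.lo[0]) / self.cell)
        ic = int((c - self.lo[1]) / self.cell)
        if not (0 <= ib < self.shape[0] and 0 <= ic < self.shape[1]):
            return ()
        return self.cells[ib][ic]


def build_accel(surface, grid: Grid3D, axis: int, cell_size=None) -> Accel2D:
    bx, cx = [a for a in range(3) if a != axis]
    cell = cell_size if cell_size else 2.0 * grid.spacing
    lo = np.array([grid.origin[bx], grid.origin[cx]]) - grid.spacing
    span = grid.span()
    nb = int(math.ceil((span[bx] + 2 * grid.spacing) / cell)) + 1
    nc = int(math.ceil((span[cx] + 2 * grid.spacing) / cell)) + 1
    cells = [[[] for _ in range(nc)] for _ in range(nb)]
    plo, phi = surface.patch_bboxes()
    for pid in range(len(plo)):
        b0 = int(math.floor((plo[pid][bx] - lo[0]) / cell))
        b1 = int(math.floor((phi[pid][bx] - lo[0]) / cell))
        c0 = int(math.floor((plo[pid][cx] - lo[1]) / cell))
        c1 = int(math.floor((phi[pid][cx] - lo[1]) / cell))
        for ib in range(max(b0, 0), min(b1, nb - 1) + 1):
            for ic in range(max(c0, 0), min(c1, nc - 1) + 1):
                cells[ib][ic].append(pid)
    return Accel2D(axis, lo, cell, (nb, nc), cells)


# ---------------------------------------------------------------------------
# status containers
# ---------------------------------------------------------------------------

@dataclass
class CastReport:
    """Robustness accounting for the parity-checksum protocol."""

    rays_cast: int = 0
    parity_retries: int = 0
    rays_retried: int = 0
    fallbacks: int = 0
    odd_after_protocol: int = 0
    axis_disagreements: int = 0
    events: list = field(default_factory=list)

    def merge(self, other: "CastReport"):
        self.rays_cast += other.rays_cast
        self.parity_retries += other.parity_retries
        self.rays_retried += other.rays_retried
        self.fallbacks += other.fallbacks
        self.odd_after_protocol += other.odd_after_protocol
        self.axis_disagreements += other.axis_disagreements
        self.events.extend(other.events)


@dataclass
class StatusGrid:
    """In/out flags at cube centers, face centers, and cube vertices."""

    grid: Grid3D
    centers: np.ndarray = None  # bool (ncx, ncy, ncz); True = inside
    faces: dict = None  # axis -> bool array, faces orthogonal to axis
    vertices: np.ndarray = None  # bool (nx, ny, nz)
    axis_centers: dict = None  # per-axis center classifications
    cavity_labels: np.ndarray = None

    def dump_text(self, path):
        """Debug dump: header (dims, origin, h), one status char/node,
        x-fastest."""
        with open(path, "w") as fh:
            d = self.grid.dims
            o = self.grid.origin
            fh.write(f"{d[0]} {d[1]} {d[2]} {o[0]:.6f} {o[1]:.6f} {o[2]:.6f} "
                     f"{self.grid.spacing:.6f}\n")
            flat = np.transpose(self.centers.astype(int), (2, 1, 0)).ravel()
            fh.write("".join(map(str, flat)))
            fh.write("\n")


class EdgeHits:
    """Analytic crossings on grid-cube edges, keyed by (axis, i, j, k) of
    the edge's lower vertex."""

    def __init__(self):
        self.hits = {}

    def add(self, axis, key, point, normal):
        self.hits.setdefault((axis,) + tuple(key), []).append(
            (np.asarray(point, float), np.asarray(normal, float)))

    def get(self, axis, key):
        return self.hits.get((axis,) + tuple(key), [])

    def remove_edge(self, axis, key):
        self.hits.pop((axis,) + tuple(key), None)

    def __len__(self):
        return len(self.hits)


# ---------------------------------------------------------------------------
# core casting
# ---------------------------------------------------------------------------

def _dedup(hits, tol=1e-9):
    """Collapse coincident crossings (patch-seam double reports)."""
    out = []
    for h in hits:
        if out and h[0] - out[-1][0] < tol:
            continue
        out.append(h)
    return out


def cast_ray_checked(surface, origin, direction, t_max, accel=None,
                     retries=5, jitter_eps=None, rng=None, report=None,
                     spacing=None):
    """Cast one ray; enforce even parity via the retry protocol.

    Returns the hit list (even-sized) or ``None`` when parity could not be
    restored (the caller falls back to its last stable ray).
    """
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    if report is not None:
        report.rays_cast += 1
    axis = int(np.argmax(np.abs(direction)))
    bx, cx = [a for a in range(3) if a != axis]
    if jitter_eps is None:
        jitter_eps = 0.01 * (spacing or 1.0)

    def one(o):
        cand = None
        if accel is not None:
            cand = accel.candidates(o[bx], o[cx])
        return _dedup(surface.ray_hits(o, direction, t_max, candidates=cand))

    hits = one(origin)
    if len(hits) % 2 == 0:
        return hits
    if report is not None:
        report.rays_retried += 1
    if rng is None:
        rng = np.random.default_rng(0)
    for _ in range(retries):
        if report is not None:
            report.parity_retries += 1
        delta = rng.uniform(-jitter_eps, jitter_eps, 3)
        delta[axis] = 0.0
        hits = one(origin + delta)
        if len(hits) % 2 == 0:
            return hits
    if report is not None:
        report.odd_after_protocol += 1
    return None


def _ray_frame(grid, axis):
    bx, cx = [a for a in range(3) if a != axis]
    o_a = grid.origin[axis] - grid.spacing
    t_max = grid.span()[axis] + 2.0 * grid.spacing
    direction = np.zeros(3)
    direction[axis] = 1.0
    return bx, cx, o_a, t_max, direction


def _statuses_from_hits(hit_ts, sample_ts):
    return np.searchsorted(hit_ts, sample_ts) % 2 == 1


def cast_grid_rays(surface, grid: Grid3D, accels=None, retries=5, seed=0,
                   keep_hits=False):
    """Grid Rays along all three axes.

    Returns ``(status, intervals, report[, ray_hits])`` where ``status`` is a
    StatusGrid with centers/faces filled, ``intervals[axis]`` is the total
    inside length per ray (shape = cross-section cube counts), and
    ``ray_hits[axis]`` optionally keeps (t, cos-angle) per hit for the
    incident-ray area estimator.
    """
    nc = grid.n_cubes
    report = CastReport()
    axis_centers = {}
    faces = {}
    intervals = {}
    all_hits = {a: [] for a in range(3)} if keep_hits else None
    rng = np.random.default_rng(seed)

    for axis in range(3):
        bx, cx, o_a, t_max, direction = _ray_frame(grid, axis)
        accel = accels[axis] if accels else None
        n_b, n_c = nc[bx], nc[cx]
        centers_a = np.zeros((nc[0], nc[1], nc[2]), bool)
        face_shape = [0, 0, 0]
        face_shape[axis] = grid.dims[axis]
        face_shape[bx] = n_b
        face_shape[cx] = n_c
        faces_a = np.zeros(tuple(face_shape), bool)
        lengths = np.zeros((n_b, n_c))
        center_ts = (np.arange(nc[axis]) + 0.5) * grid.spacing + grid.spacing
        vert_ts = np.arange(grid.dims[axis]) * grid.spacing + grid.spacing
        last_good = None
        for ib in range(n_b):
            for ic in range(n_c):
                o = np.empty(3)
                o[axis] = o_a
                o[bx] = grid.center_coord(bx, ib)
                o[cx] = grid.center_coord(cx, ic)
                hits = cast_ray_checked(surface, o, direction, t_max, accel,
                                        retries, rng=rng, report=report,
                                        spacing=grid.spacing)
                if hits is None:
                    if last_good is None:
                        raise RuntimeError(
                            "parity failure on the first ray: no stable "
                            "neighbour to fall back to")
                    report.fallbacks += 1
                    report.events.append(("fallback", axis, ib, ic))
                    hit_ts = last_good
                else:
                    hit_ts = np.array([h[0] for h in hits])
                    last_good = hit_ts
                    if keep_hits:
                        for t, _, n in hits:
                            all_hits[axis].append(abs(float(n[axis])))
                cstat = _statuses_from_hits(hit_ts, center_ts)
                fstat = _statuses_from_hits(hit_ts, vert_ts)
                sl = [slice(None)] * 3
                sl[bx], sl[cx] = ib, ic
                centers_a[tuple(sl)] = cstat
                faces_a[tuple(sl)] = fstat
                if len(hit_ts) >= 2:
                    lengths[ib, ic] = float(
                        (hit_ts[1::2] - hit_ts[0::2]).sum())
        axis_centers[axis] = centers_a
        faces[axis] = faces_a
        intervals[axis] = lengths

    votes = sum(axis_centers[a].astype(int) for a in range(3))
    centers = votes >= 2
    report.axis_disagreements = int(((votes != 0) & (votes != 3)).sum())
    status = StatusGrid(grid, centers=centers, faces=faces,
                        axis_centers=axis_centers)
    if keep_hits:
        return status, intervals, report, all_hits
    return status, intervals, report


def cast_edge_rays(surface, grid: Grid3D, accels=None, retries=5, seed=0):
    """Edge Rays along the vertex lattice lines of all three axes.

    Returns ``(vertex_status, edge_hits, report)``; vertex statuses are the
    majority over the three casting axes (ties go outside).
    """
    nv = grid.dims
    report = CastReport()
    votes = np.zeros(nv, dtype=np.int8)
    nvotes = np.zeros(nv, dtype=np.int8)
    edge_hits = EdgeHits()
    rng = np.random.default_rng(seed + 7)

    for axis in range(3):
        bx, cx, o_a, t_max, direction = _ray_frame(grid, axis)
        accel = accels[axis] if accels else None
        vert_ts = np.arange(nv[axis]) * grid.spacing + grid.spacing
        last_good = None
        for ib in range(nv[bx]):
            for ic in range(nv[cx]):
                o = np.empty(3)
                o[axis] = o_a
                o[bx] = grid.vertex_coord(bx, ib)
                o[cx] = grid.vertex_coord(cx, ic)
                hits = cast_ray_checked(surface, o, direction, t_max, accel,
                                        retries, rng=rng, report=report,
                                        spacing=grid.spacing)
                if hits is None:
                    if last_good is None:
                        raise RuntimeError(
                            "parity failure on the first edge ray: no stable "
                            "neighbour to fall back to")
                    report.fallbacks += 1
                    report.events.append(("fallback-edge", axis, ib, ic))
                    hit_ts, hits = last_good, []
                else:
                    hit_ts = np.array([h[0] for h in hits])
                    last_good = hit_ts
                vstat = _statuses_from_hits(hit_ts, vert_ts)
                sl = [slice(None)] * 3
                sl[bx], sl[cx] = ib, ic
                votes[tuple(sl)] += vstat
                nvotes[tuple(sl)] += 1
                for t, p, n in hits:
                    seg = int(math.floor((t - grid.spacing) / grid.spacing))
                    if 0 <= seg < nv[axis] - 1:
                        key = [0, 0, 0]
                        key[axis] = seg
                        key[bx] = ib
                        key[cx] = ic
                        edge_hits.add(axis, key, p, n)

    vertex_status = votes * 2 > nvotes  # strict majority; ties -> outside
    disagree = int(((votes > 0) & (votes < nvotes)).sum())
    report.axis_disagreements = disagree
    return vertex_status, edge_hits, report


def classify_points(surface, points, direction=(1.0, 0.0, 0.0)):
    """Parity-classify arbitrary points (True = inside), brute force.

    Oracle-grade helper: casts one unaccelerated ray per point from the
    point to beyond the surface bbox.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    lo, hi = surface.bbox()
    corner_pts = np.array([[x, y, z] for x in (lo[0], hi[0])
                           for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    out = np.zeros(len(pts), bool)
    for i, p in enumerate(pts):
        # far enough that the ray is guaranteed to exit the surface bbox
        t_max = max(float(((c - p) @ d)) for c in corner_pts) + 1.0
        if t_max <= 0:
            out[i] = False
            continue
        hits = _dedup(surface.ray_hits(p, d, t_max))
        out[i] = len(hits) % 2 == 1
    return out
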