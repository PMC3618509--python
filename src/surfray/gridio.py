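"""PDE-solver-ready grid coloring and boundary-point projection.

Finite-difference Poisson-Boltzmann solvers need the solute/solvent medium
at cube centers and at the centers of cube faces, plus, for the polarization
charges, the projection of boundary grid points (cubes whose faces sit in
different media) onto the molecular surface.  Projections use closed forms
on spheres/tori/triangles and an iterative foot-point search on quadrics,
with a sampling fallback; candidate patches come from an auxiliary 3-D cell
grid searched in expanding shells.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .geometry import QuadricPatch, SpherePatch, TorusPatch
from .raycast import StatusGrid
from .volumetrics import WATER_VOLUME, detect_cavities, fill_cavities

__all__ = ["ColorMap", "BoundaryPoint", "color_grid", "find_boundary_points",
           "Accel3D", "project_points"]


@dataclass
class ColorMap:
    """Medium labels (True = solute) at cube centers and face centers."""

    grid: object
    centers: np.ndarray
    faces: dict
    fill_policy: str = "keep-cavities"

    def cube_face_statuses(self, i, j, k):
        return (
            self.faces[0][i, j, k], self.faces[0][i + 1, j, k],
            self.faces[1][i, j, k], self.faces[1][i, j + 1, k],
            self.faces[2][i, j, k], self.faces[2][i, j, k + 1],
        )

    def dump_text(self, path_prefix):
        """Flat text voxel dumps (header dims/origin/h; x-fastest)."""
        g = self.grid
        tags = [("centers", self.centers)] + [
            (f"faces{a}", self.faces[a]) for a in range(3)]
        for tag, arr in tags:
            with open(f"{path_prefix}.{tag}.txt", "w") as fh:
                d = arr.shape
                o = g.origin
                fh.write(f"{d[0]} {d[1]} {d[2]} {o[0]:.6f} {o[1]:.6f} "
                         f"{o[2]:.6f} {g.spacing:.6f}\n")
                flat = np.transpose(arr.astype(int), (2, 1, 0)).ravel()
                fh.write("".join(map(str, flat)) + "\n")


@dataclass
class BoundaryPoint:
    grid_point: np.ndarray  # cube-center coordinates
    cube: tuple  # owning cube (i, j, k)
    projection: np.ndarray = None
    distance: float = math.nan


def color_grid(status: StatusGrid, fill_policy="keep-cavities",
               min_volume=WATER_VOLUME, edge_hits=None) -> ColorMap:
    """Apply a cavity fill policy and expose the in/out labels.

    ``fill_policy``: ``keep-cavities`` (identity), ``fill-below`` (fill
    cavities smaller than ``min_volume``), or ``fill-all``.
    """
    if status.centers is None or status.faces is None:
        raise ValueError("status grid is missing center/face classifications")
    if fill_policy not in ("keep-cavities", "fill-below", "fill-all"):
        raise ValueError(f"unknown fill policy {fill_policy!r}")
    if fill_policy != "keep-cavities":
        _, cavities = detect_cavities(status)
        fill_cavities(status, cavities, min_volume=min_volume,
                      fill_all=fill_policy == "fill-all", edge_hits=edge_hits)
    return ColorMap(status.grid, status.centers, status.faces, fill_policy)


def find_boundary_points(cmap: ColorMap):
    """Grid points of cubes whose incident faces carry mixed media,
    lexicographic by (i, j, k)."""
    out = []
    g = cmap.grid
    fx, fy, fz = cmap.faces[0], cmap.faces[1], cmap.faces[2]
    mixed = np.zeros(cmap.centers.shape, bool)
    any_in = (fx[:-1] | fx[1:] | fy[:, :-1] | fy[:, 1:]
              | fz[:, :, :-1] | fz[:, :, 1:])
    all_in = (fx[:-1] & fx[1:] & fy[:, :-1] & fy[:, 1:]
              & fz[:, :, :-1] & fz[:, :, 1:])
    mixed = any_in & ~all_in
    for i, j, k in np.argwhere(mixed):
        p = g.origin + g.spacing * (np.array([i, j, k], float) + 0.5)
        out.append(BoundaryPoint(p, (int(i), int(j), int(k))))
    return out


# ---------------------------------------------------------------------------
# auxiliary 3-D acceleration grid
# ---------------------------------------------------------------------------

class Accel3D:
    """Uniform 3-D cells listing patch ids by bounding box; queried in
    expanding shells so the true nearest patch is never missed."""

    def __init__(self, surface, cell_size):
        lo, hi = surface.bbox()
        self.lo = np.asarray(lo, float) - 1e-9
        self.cell = float(cell_size)
        self.shape = np.maximum(
            ((np.asarray(hi) - self.lo) / self.cell).astype(int) + 1, 1)
        self.cells = {}
        plo, phi = surface.patch_bboxes()
        for pid in range(len(plo)):
            i0 = np.maximum(((plo[pid] - self.lo) / self.cell).astype(int), 0)
            i1 = np.minimum(((phi[pid] - self.lo) / self.cell).astype(int),
                            self.shape - 1)
            for c in itertools.product(*(range(a, b + 1)
                                         for a, b in zip(i0, i1))):
                self.cells.setdefault(c, []).append(pid)

    def shells(self, point):
        """Yield (shell_index, patch ids) rings of increasing Chebyshev
        distance around the point's cell."""
        c0 = np.clip(((np.asarray(point) - self.lo) / self.cell).astype(int),
                     0, self.shape - 1)
        max_shell = int(self.shape.max()) + 1
        for shell in range(max_shell + 1):
            ids = set()
            for c in itertools.product(
                    range(c0[0] - shell, c0[0] + shell + 1),
                    range(c0[1] - shell, c0[1] + shell + 1),
                    range(c0[2] - shell, c0[2] + shell + 1)):
                if max(abs(c[0] - c0[0]), abs(c[1] - c0[1]),
                       abs(c[2] - c0[2])) != shell:
                    continue
                ids.update(self.cells.get(c, ()))
            yield shell, ids



# ---------------------------------------------------------------------------
# nearest-point projection
# ---------------------------------------------------------------------------

def _fibonacci_directions(n):
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z * z)
    return np.c_[r * np.cos(phi), r * np.sin(phi), z]


def _project_sphere(x, patch: SpherePatch, n_samples=512):
    c, R = patch.center, patch.radius
    v = x - c
    nv = float(np.linalg.norm(v))
    if nv > 1e-12:
        foot = c + R * v / nv
        if patch.contains_point(foot):
            return foot
    best, bd = None, math.inf
    dirs = _fibonacci_directions(n_samples)
    for d in dirs:
        p = c + R * d
        if patch.contains_point(p):
            dd = float(np.linalg.norm(p - x))
            if dd < bd:
                best, bd = p, dd
    if best is None:
        return None
    # local refinement on the sphere around the best sample
    step = 2.0 * R / math.sqrt(n_samples)
    while step > 1e-7:
        improved = False
        u = best - c
        for d in _tangent_dirs(u / R):
            p = c + R * _normalize(u + step * d * R)
            if patch.contains_point(p):
                dd = float(np.linalg.norm(p - x))
                if dd < bd:
                    best, bd, improved = p, dd, True
                    break
        if not improved:
            step *= 0.5
    return best


def _normalize(v):
    return v / np.linalg.norm(v)


def _tangent_dirs(n):
    t = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _normalize(np.cross(n, t))
    e2 = np.cross(n, e1)
    return [e1, -e1, e2, -e2]


def _torus_closed_form(x, patch: TorusPatch):
    c, a = patch.center, patch.axis
    v = x - c
    h = float(v @ a)
    radial = v - h * a
    rn = float(np.linalg.norm(radial))
    if rn < 1e-12:
        return None
    q = c + patch.major_radius * radial / rn
    w = x - q
    wn = float(np.linalg.norm(w))
    if wn < 1e-12:
        return None
    return q + patch.minor_radius * w / wn


def _project_torus(x, patch: TorusPatch, n_u=96, n_v=48):
    foot = _torus_closed_form(x, patch)
    if foot is not None and patch.contains_point(foot):
        return foot
    a = patch.axis
    e1 = _normalize(np.cross(a, [1.0, 0.0, 0.0])
                    if abs(a[0]) < 0.9 else np.cross(a, [0.0, 1.0, 0.0]))
    e2 = np.cross(a, e1)

    def pt(u, v):
        radial = math.cos(u) * e1 + math.sin(u) * e2
        q = patch.center + patch.major_radius * radial
        return q + patch.minor_radius * (math.cos(v) * radial + math.sin(v) * a)

    samples = []
    for u in np.linspace(0, 2 * math.pi, n_u, endpoint=False):
        for v in np.linspace(0, 2 * math.pi, n_v, endpoint=False):
            p = pt(u, v)
            if patch.contains_point(p):
                samples.append((float(np.linalg.norm(p - x)), u, v, p))
    if not samples:
        return None
    samples.sort(key=lambda s: s[0])
    best = None
    bd = math.inf
    # refine the few best basins by shrinking coordinate search
    for d0, u0, v0, p0 in samples[:4]:
        bu, bv, bbd, bp = u0, v0, d0, p0
        du = 2 * math.pi / n_u
        while du > 1e-8:
            improved = False
            for uu, vv in ((bu + du, bv), (bu - du, bv),
                           (bu, bv + du), (bu, bv - du),
                           (bu + du, bv + du), (bu - du, bv - du)):
                p = pt(uu, vv)
                if patch.contains_point(p):
                    dd = float(np.linalg.norm(p - x))
                    if dd < bbd:
                        bu, bv, bbd, bp = uu, vv, dd, p
                        improved = True
                        break
            if not improved:
                du *= 0.5
        if bbd < bd:
            best, bd = bp, bbd
    return best


def _project_quadric(x, patch: QuadricPatch, max_iter=60):
    """Damped foot-point iteration: walk on the surface toward x."""
    A, z = patch.A, patch.center

    def surface_point_along(p0, d):
        from .geometry import ray_quadric
        best = None
        for sgn in (1.0, -1.0):
            ts = ray_quadric(p0, sgn * d, A, z, patch.const, 1e6)
            for t in ts:
                q = p0 + sgn * t * d
                if best is None or np.linalg.norm(q - x) < np.linalg.norm(best - x):
                    best = q
        return best

    g0 = 2.0 * (A @ (x - z))
    if np.linalg.norm(g0) < 1e-12:
        g0 = np.array([1.0, 0.0, 0.0])
    p = surface_point_along(x, _normalize(g0))
    if p is None:
        return None
    lam = 1.0
    for _ in range(max_iter):
        g = 2.0 * (A @ (p - z))
        gn = float(np.linalg.norm(g))
        if gn < 1e-14:
            break
        n = g / gn
        resid = (x - p) - float((x - p) @ n) * n  # tangential misfit
        if float(np.linalg.norm(resid)) < 1e-9:
            break
        cand = p + lam * resid
        q = surface_point_along(cand, n)
        if q is None or np.linalg.norm(q - x) > np.linalg.norm(p - x) + 1e-12:
            lam *= 0.5  # damping
            if lam < 1e-6:
                break
            continue
        p = q
    if patch.contains_point(p):
        return p
    # fallback: dense sampling of the cell box, projected along the gradient
    lo, hi = patch.bbox()
    best, bd = None, math.inf
    for c in itertools.product(*(np.linspace(lo[k], hi[k], 8) for k in range(3))):
        q = surface_point_along(np.array(c), _normalize(2.0 * (A @ (np.array(c) - z))
                                                        + 1e-12))
        if q is not None and patch.contains_point(q):
            dd = float(np.linalg.norm(q - x))
            if dd < bd:
                best, bd = q, dd
    return best


def _project_patch(x, patch):
    if isinstance(patch, SpherePatch):
        return _project_sphere(x, patch)
    if isinstance(patch, TorusPatch):
        return _project_torus(x, patch)
    if isinstance(patch, QuadricPatch):
        return _project_quadric(x, patch)
    raise TypeError(f"cannot project onto {type(patch).__name__}")


def _project_triangle(x, v0, v1, v2):
    """Closed-form nearest point on a triangle (barycentric clamp)."""
    e0 = v1 - v0
    e1 = v2 - v0
    d = v0 - x
    a, b, c = float(e0 @ e0), float(e0 @ e1), float(e1 @ e1)
    d0, d1 = float(e0 @ d), float(e1 @ d)
    det = a * c - b * b
    s, t = b * d1 - c * d0, b * d0 - a * d1
    if det < 1e-20:
        return v0
    if s + t <= det:
        if s < 0:
            if t < 0:
                s = min(max(-d0 / a, 0.0), 1.0) if a > 0 else 0.0
                t = 0.0
            else:
                s = 0.0
                t = min(max(-d1 / c, 0.0), 1.0) if c > 0 else 0.0
        elif t < 0:
            t = 0.0
            s = min(max(-d0 / a, 0.0), 1.0) if a > 0 else 0.0
        else:
            s /= det
            t /= det
    else:
        if s < 0:
            t = 1.0
            s = 0.0
        elif t < 0:
            s = 1.0
            t = 0.0
        else:
            num = c + d1 - b - d0
            s = min(max(num / (a - 2 * b + c), 0.0), 1.0) if a - 2 * b + c > 0 else 0.0
            t = 1.0 - s
    return v0 + s * e0 + t * e1


def project_points(points, surface, accel_cell=None):
    """Project boundary points onto the surface (nearest valid point).

    Accepts BoundaryPoint instances or raw coordinates; returns
    BoundaryPoint objects with ``projection`` and ``distance`` filled.
    """
    cell = accel_cell
    if cell is None:
        lo, hi = surface.bbox()
        cell = max(float((np.asarray(hi) - lo).max()) / 32.0, 1e-6)
    accel = Accel3D(surface, cell)
    is_mesh = hasattr(surface, "faces") and hasattr(surface, "vertices")

    def foot(x, pid):
        if is_mesh:
            a, b, c = surface.faces[pid]
            return _project_triangle(x, surface.vertices[a],
                                     surface.vertices[b], surface.vertices[c])
        return _project_patch(x, surface.patches[pid])

    out = []
    for bp in points:
        if not isinstance(bp, BoundaryPoint):
            bp = BoundaryPoint(np.asarray(bp, float), cube=None)
        x = np.asarray(bp.grid_point, float)
        best, bd = None, math.inf
        seen = set()
        # expanding shells: a patch confined to shells >= s is at least
        # (s-1)*cell away, so stop once that bound exceeds the best foot
        for shell, ids in accel.shells(x):
            if best is not None and (shell - 1) * accel.cell > bd:
                break
            for pid in ids:
                if pid in seen:
                    continue
                seen.add(pid)
                p = foot(x, pid)
                if p is None:
                    continue
                dd = float(np.linalg.norm(p - x))
                if dd < bd:
                    best, bd = p, dd
        bp.projection = best
        bp.distance = bd if best is not None else math.nan
        out.append(bp)
    return out


def boundary_points_tsv(points, path):
    with open(path, "w") as fh:
        fh.write("i\tj\tk\tpx\tpy\tpz\tdist\n")
        for bp in points:
            i, j, k = bp.cube if bp.cube else (-1, -1, -1)
            p = bp.projection if bp.projection is not None else (math.nan,) * 3
            fh.write(f"{i}\t{j}\t{k}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}"
                     f"\t{bp.distance:.6f}\n")
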