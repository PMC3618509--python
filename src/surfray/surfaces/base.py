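"""Surface model contract: sorted ray intersections with outward normals.

Three concrete families implement it: analytic patch sets (SES/VdW/SAS and
Skin), trilinear scalar fields (Gaussian), and imported closed triangle
meshes.  Everything downstream (ray caster, triangulator, projector) talks
only to this contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..geometry import ray_triangle


class SurfaceModel:
    """Base class; subclasses provide patch bboxes and per-ray hit lists."""

    def bbox(self):
        raise NotImplementedError

    def patch_bboxes(self):
        """(lo, hi) arrays of shape (n_patches, 3) for acceleration grids."""
        raise NotImplementedError

    def ray_hits(self, origin, direction, t_max, candidates=None):
        """Ascending list of (t, point, outward_normal) crossings."""
        raise NotImplementedError


# ---------------------------------------------------------------------------

class PatchSet(SurfaceModel):
    """A collection of trimmed analytic patches forming a closed surface."""

    def __init__(self, patches, metadata=None):
        self.patches = list(patches)
        self.metadata = dict(metadata or {})
        self._lo = None
        self._hi = None

    def __len__(self):
        return len(self.patches)

    def patch_bboxes(self):
        if self._lo is None:
            los, his = [], []
            for p in self.patches:
                lo, hi = p.bbox()
                los.append(lo)
                his.append(hi)
            self._lo = np.asarray(los, float).reshape(-1, 3)
            self._hi = np.asarray(his, float).reshape(-1, 3)
        return self._lo, self._hi

    def bbox(self):
        lo, hi = self.patch_bboxes()
        if lo.size == 0:
            z = np.zeros(3)
            return z, z
        return lo.min(axis=0), hi.max(axis=0)

    def ray_hits(self, origin, direction, t_max, candidates=None):
        o = np.asarray(origin, float)
        d = np.asarray(direction, float)
        if candidates is None:
            idx = np.arange(len(self.patches))
        else:
            idx = np.asarray(list(candidates), int)
        if idx.size == 0:
            return []
        # vectorized slab (ray/AABB) pruning with a small safety margin
        lo, hi = self.patch_bboxes()
        lo = lo[idx] - 1e-9
        hi = hi[idx] + 1e-9
        t0 = np.zeros(len(idx))
        t1 = np.full(len(idx), float(t_max))
        keep = np.ones(len(idx), bool)
        for k in range(3):
            if abs(d[k]) > 1e-14:
                ta = (lo[:, k] - o[k]) / d[k]
                tb = (hi[:, k] - o[k]) / d[k]
                t0 = np.maximum(t0, np.minimum(ta, tb))
                t1 = np.minimum(t1, np.maximum(ta, tb))
            else:
                keep &= (o[k] >= lo[:, k]) & (o[k] <= hi[:, k])
        keep &= t0 <= t1
        hits = []
        for i in idx[keep]:
            hits.extend(self.patches[i].hits(o, d, t_max))
        hits.sort(key=lambda h: h[0])
        return hits

    def implicit_residual(self, point, scale_tol=1e-6):
        """Smallest patch-surface residual of ``point`` over valid patches.

        Used to verify the on-surface property of analytic intersections;
        distance-like for spheres/tori, implicit-value based for quadrics.
        """
        best = math.inf
        p = np.asarray(point, float)
        for patch in self.patches:
            if hasattr(patch, "surface_residual"):
                r = patch.surface_residual(p)
            elif hasattr(patch, "radius"):
                r = abs(float(np.linalg.norm(p - patch.center)) - patch.radius)
            else:
                g = np.linalg.norm(2.0 * (patch.A @ (p - patch.center)))
                r = abs(patch.implicit(p)) / max(g, 1e-12)
            best = min(best, r)
        return best


# ---------------------------------------------------------------------------

class ScalarFieldSurface(SurfaceModel):
    """Isosurface of a scalar field sampled at grid vertices (trilinear).

    The field is *larger than iso inside* the body.  Crossings are found by
    bracketing sign changes of the interpolant at ``h/8`` steps and bisecting
    to 1e-9; normals come from the interpolant gradient, flipped outward.
    """

    def __init__(self, grid, values, iso=1.0):
        self.grid = grid
        self.values = np.asarray(values, float)
        if self.values.shape != tuple(grid.dims):
            raise ValueError("field shape does not match grid vertex dims")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite field values")
        self.iso = float(iso)

    def bbox(self):
        lo = self.grid.origin
        hi = self.grid.origin + self.grid.spacing * (np.asarray(self.grid.dims) - 1)
        return lo.copy(), hi

    def patch_bboxes(self):
        lo, hi = self.bbox()
        return lo[None, :], hi[None, :]

    # -- field evaluation ---------------------------------------------------

    def field_at(self, points):
        """Trilinear interpolation; points outside the grid clamp to edge."""
        pts = np.atleast_2d(np.asarray(points, float))
        g = self.grid
        rel = (pts - g.origin) / g.spacing
        dims = np.asarray(g.dims)
        rel = np.clip(rel, 0.0, dims - 1.000000001)
        i0 = np.minimum(rel.astype(int), dims - 2)
        f = rel - i0
        v = self.values
        ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        c = (
            v[ix, iy, iz] * (1 - fx) * (1 - fy) * (1 - fz)
            + v[ix + 1, iy, iz] * fx * (1 - fy) * (1 - fz)
            + v[ix, iy + 1, iz] * (1 - fx) * fy * (1 - fz)
            + v[ix, iy, iz + 1] * (1 - fx) * (1 - fy) * fz
            + v[ix + 1, iy + 1, iz] * fx * fy * (1 - fz)
            + v[ix + 1, iy, iz + 1] * fx * (1 - fy) * fz
            + v[ix, iy + 1, iz + 1] * (1 - fx) * fy * fz
            + v[ix + 1, iy + 1, iz + 1] * fx * fy * fz
        )
        return c

    def gradient_at(self, point, eps=1e-6):
        p = np.asarray(point, float)
        g = np.empty(3)
        for k in range(3):
            e = np.zeros(3)
            e[k] = eps
            g[k] = (self.field_at(p + e)[0] - self.field_at(p - e)[0]) / (2 * eps)
        return g

    def ray_hits(self, origin, direction, t_max, candidates=None):
        o = np.asarray(origin, float)
        d = np.asarray(direction, float)
        step = self.grid.spacing / 8.0
        n = int(math.ceil(t_max / step)) + 1
        ts = np.linspace(0.0, t_max, n)
        vals = self.field_at(o[None, :] + ts[:, None] * d[None, :]) - self.iso
        sgn = np.where(vals >= 0.0, 1, -1)  # exact-zero samples count inside
        hits = []
        idx = np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]
        for i in idx:
            lo, hi = ts[i], ts[i + 1]
            flo = vals[i]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                fm = self.field_at(o + mid * d)[0] - self.iso
                if (flo < 0) != (fm < 0):
                    hi = mid
                else:
                    lo, flo = mid, fm
                if hi - lo < 1e-9:
                    break
            t = 0.5 * (lo + hi)
            p = o + t * d
            grad = self.gradient_at(p)
            gn = np.linalg.norm(grad)
            nrm = -grad / gn if gn > 0 else d.copy()  # field decreases outward
            hits.append((t, p, nrm))
        return hits


# ---------------------------------------------------------------------------

class NotClosedError(ValueError):
    """Mesh violates the closed-manifold hypothesis of the framework."""

    def __init__(self, bad_edges):
        self.bad_edges = list(bad_edges)
        preview = ", ".join(map(str, self.bad_edges[:10]))
        super().__init__(
            f"mesh is not a closed manifold: {len(self.bad_edges)} offending "
            f"edge(s): {preview}"
        )


class MeshSurface(SurfaceModel):
    """Closed manifold triangle mesh with per-triangle bounding boxes.

    Edge/vertex ray hits use half-open ownership: each shared edge is owned
    by exactly one incident triangle (lexicographically smallest face index)
    so a ray crossing an edge reports one hit, never zero or two.
    """

    def __init__(self, vertices, faces, check_manifold=True):
        self.vertices = np.asarray(vertices, float).reshape(-1, 3)
        self.faces = np.asarray(faces, int).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        self.edge_owner = {}
        edges = {}
        for fi, (a, b, c) in enumerate(self.faces):
            for e in ((a, b), (b, c), (c, a)):
                key = (min(e), max(e))
                edges.setdefault(key, []).append(fi)
        if check_manifold:
            bad = [e for e, fs in edges.items() if len(fs) != 2]
            if bad:
                raise NotClosedError(bad)
        self.edge_owner = {e: min(fs) for e, fs in edges.items()}
        vert_owner = {}
        for fi, tri in enumerate(self.faces):
            for vv in tri:
                vert_owner[vv] = min(vert_owner.get(vv, fi), fi)
        self.vert_owner = vert_owner
        # zero-area triangles are treated as misses and counted for diagnostics
        e1 = self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]]
        e2 = self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]]
        self._normals = np.cross(e1, e2)
        areas2 = np.linalg.norm(self._normals, axis=1)
        self.degenerate_faces = np.nonzero(areas2 < 1e-14)[0]

    # -- queries ------------------------------------------------------------

    def bbox(self):
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def patch_bboxes(self):
        tv = self.vertices[self.faces]
        return tv.min(axis=1), tv.max(axis=1)

    def area(self):
        return 0.5 * float(np.linalg.norm(self._normals, axis=1).sum())

    def euler_characteristic(self):
        return len(self.vertices) - len(self.edge_owner) + len(self.faces)

    def ray_hits(self, origin, direction, t_max, candidates=None, eps=1e-10):
        idx = range(len(self.faces)) if candidates is None else candidates
        o = np.asarray(origin, float)
        d = np.asarray(direction, float)
        hits = []
        for fi in idx:
            a, b, c = self.faces[fi]
            res = ray_triangle(o, d, self.vertices[a], self.vertices[b],
                               self.vertices[c], t_max, eps=eps)
            if res is None:
                continue
            t, u, v = res
            w = 1.0 - u - v
            onedge = [abs(w) <= eps, abs(u) <= eps, abs(v) <= eps]
            if sum(onedge) >= 2:  # vertex hit: owner triangle only
                tri = (a, b, c)
                vid = tri[int(np.argmax([w > eps, u > eps, v > eps]))]
                # the vertex actually hit is the one with barycentric ~1
                bary = [w, u, v]
                vid = tri[int(np.argmax(bary))]
                if self.vert_owner.get(vid) != fi:
                    continue
            elif any(onedge):
                if onedge[1]:  # u ~ 0: edge (a, c)
                    ekey = (min(a, c), max(a, c))
                elif onedge[2]:  # v ~ 0: edge (a, b)
                    ekey = (min(a, b), max(a, b))
                else:  # w ~ 0: edge (b, c)
                    ekey = (min(b, c), max(b, c))
                if self.edge_owner.get(ekey) != fi:
                    continue
            n = self._normals[fi]
            nn = float(np.linalg.norm(n))
            if nn < 1e-14:
                continue
            hits.append((t, o + t * d, n / nn))
        hits.sort(key=lambda h: h[0])
        return hits
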