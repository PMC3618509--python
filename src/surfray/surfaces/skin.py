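"""Skin surface: trimmed quadrics over the mixed complex.

The skin of weighted points (c_i, w_i = r_i^2) with shrink factor s is the
boundary of the union of all convex-combination balls shrunk by s.  Within
the mixed cell of a Delaunay k-simplex sigma (the Minkowski combination
(1-s)*sigma (+) s*nu(sigma) with its dual power-diagram face nu), the
surface is the quadric

    ||x_N - z||^2 / s  -  ||x_E - z||^2 / (1-s)  =  -w_z

where z is sigma's orthocenter, w_z its squared orthoradius, E the simplex
direction space and N its orthogonal complement.  This yields spheres of
radius sqrt(s)*r_i in vertex cells, spheres of squared radius (1-s)*w_z
around tetrahedron orthocenters (material outside: void bubbles), and
hyperboloids of revolution in edge/triangle cells.  Every mixed cell is
convex, so the cell clip is a pure conjunction of half-space trims.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from ..geometry import QuadricPatch, TrimPrimitive
from .atoms import AtomSet, perturb_atoms
from .base import PatchSet
from .delaunay import DegenerateInput, orthocenter, regular_triangulation

__all__ = ["SkinParams", "build_skin"]


@dataclass
class SkinParams:
    """Shrink factor in (0, 1]; weights are the squared atomic radii."""

    shrink: float = 0.45
    perturbation: float = 1e-4
    seed: int = 0
    retries: int = 3

    def __post_init__(self):
        if not (0.0 < self.shrink <= 1.0):
            raise ValueError("shrink factor must be in (0, 1]")


def build_skin(atoms: AtomSet, params: SkinParams | None = None) -> PatchSet:
    params = params or SkinParams()
    last = None
    for attempt in range(params.retries + 1):
        work = atoms
        if params.perturbation > 0:
            work = perturb_atoms(atoms, params.perturbation, params.seed + attempt)
        try:
            return _build_skin_once(work, params)
        except DegenerateInput as exc:
            last = exc
    raise DegenerateInput(f"degenerate skin input after retries: {last}")


def _half_space(n, off):
    return TrimPrimitive("half_space", tuple(np.asarray(n, float)), float(off))


def _build_skin_once(atoms: AtomSet, params: SkinParams) -> PatchSet:
    centers = atoms.centers
    weights = atoms.radii**2
    # s = 1 exactly would degenerate the non-vertex cells; clamping by 1e-7
    # reproduces the union-of-balls limit to the same tolerance
    s = min(params.shrink, 1.0 - 1e-7)
    rt = regular_triangulation(centers, weights)
    nbrs = rt.vertex_neighbors()
    incident = rt.incident_tets()
    boundary = rt.boundary_simplices()

    # orthocenters of tets define the dual vertices used for cell bboxes
    tet_z = {}
    for tet in rt.tets:
        z, _ = orthocenter(centers[list(tet)], weights[list(tet)])
        tet_z[tet] = z

    glo = (centers - atoms.radii[:, None]).min(axis=0) - 1e-6
    ghi = (centers + atoms.radii[:, None]).max(axis=0) + 1e-6

    simplices = [(v,) for v in rt.vertices] + rt.edges + rt.triangles + rt.tets
    patches = []
    counts = {0: 0, 1: 0, 2: 0, 3: 0}

    for sigma in simplices:
        idx = list(sigma)
        k = len(idx) - 1
        pts = centers[idx]
        try:
            z, wz = orthocenter(pts, weights[idx])
        except DegenerateInput:
            continue
        if k == 3 and wz <= 1e-14:
            continue  # no void bubble in this tetrahedron

        # orthonormal basis of the simplex direction space E
        if k == 0:
            PE = np.zeros((3, 3))
        else:
            V = (pts[1:] - pts[0]).T
            Q, _ = np.linalg.qr(V)
            E = Q[:, :k]
            PE = E @ E.T
        A = np.eye(3) / s - (1.0 / s + 1.0 / (1.0 - s)) * PE

        trims = []
        # (a) simplex side: p(x) = z + P_E (x - z)/(1-s) has barycentric >= 0
        if k >= 1:
            M = PE / (1.0 - s)
            bvec = z - M @ z
            V = (pts[1:] - pts[0]).T
            G = np.linalg.pinv(V.T @ V) @ V.T  # p -> reduced coords y
            lam_rows = [(-G.sum(axis=0), 1.0 + G.sum(axis=0) @ pts[0])]
            for r in range(k):
                lam_rows.append((G[r], -float(G[r] @ pts[0])))
            for g, d in lam_rows:
                # lambda(x) = g.(Mx + b) + d >= 0  ->  (-M^T g).x <= g.b + d
                trims.append(_half_space(-(M.T @ g), float(g @ bvec) + d))
        # (b) power side: q(x) = z + P_N (x - z)/s in the dual face
        if k <= 2:
            PN = np.eye(3) - PE
            Mq = PN / s
            bq = z - Mq @ z
            i0 = idx[0]
            others = set()
            for v in idx:
                others.update(nbrs.get(v, ()))
            others -= set(idx)
            for l in others:
                dd = centers[i0] - centers[l]
                lhs = -2.0 * (Mq.T @ dd)
                rhs = (2.0 * float(bq @ dd)
                       - float(centers[i0] @ centers[i0]) + float(centers[l] @ centers[l])
                       + weights[i0] - weights[l])
                trims.append(_half_space(lhs, rhs))

        # bbox: (1-s)*bbox(sigma) (+) s*bbox(dual face), clipped to the
        # union-of-balls box (the skin body is contained in it)
        slo, shi = pts.min(axis=0), pts.max(axis=0)
        if sigma in boundary or (k < 3 and not incident.get(sigma)):
            # unbounded dual face: the cell cannot be bounded a priori,
            # fall back to the whole union-of-balls box
            lo, hi = glo.copy(), ghi.copy()
        else:
            if k == 3:
                nlo = nhi = tet_z[sigma]
            else:
                zs = np.array([tet_z[t] for t in incident[sigma]])
                nlo, nhi = zs.min(axis=0), zs.max(axis=0)
            lo = (1.0 - s) * slo + s * nlo
            hi = (1.0 - s) * shi + s * nhi
        if k == 0:
            r = math.sqrt(max(s * weights[idx[0]], 0.0))
            lo = np.maximum(lo, z - r)
            hi = np.minimum(hi, z + r)
        elif k == 3:
            r = math.sqrt((1.0 - s) * wz)
            lo = np.maximum(lo, z - r)
            hi = np.minimum(hi, z + r)
        lo = np.maximum(lo, glo)
        hi = np.minimum(hi, ghi)
        if (lo >= hi).any():
            continue

        patches.append(QuadricPatch(A, z, wz, trims, bbox_lo=lo, bbox_hi=hi))
        counts[k] += 1

    if not patches:
        raise DegenerateInput("skin construction produced no patches")
    return PatchSet(patches, {
        "kind": "skin", "shrink": params.shrink, "n_atoms": len(atoms),
        "n_vertex_patches": counts[0], "n_edge_patches": counts[1],
        "n_triangle_patches": counts[2], "n_tet_patches": counts[3],
    })
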