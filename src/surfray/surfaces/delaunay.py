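"""Regular (weighted) Delaunay tetrahedralization via the lifted lower hull.

Weighted points (c_i, w_i) are lifted to (c_i, |c_i|^2 - w_i) in R^4; the
lower convex hull's facets are exactly the tetrahedra of the regular
triangulation.  Qhull (scipy.spatial.ConvexHull) does the hull; degenerate
inputs surviving the caller's random perturbation raise DegenerateInput so
the builder can retry with a fresh seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError


class DegenerateInput(RuntimeError):
    """Triangulation failed on (near-)degenerate input; retry with new jitter."""


@dataclass
class RegularTriangulation:
    """Simplices of the weighted Delaunay complex, as sorted index tuples."""

    points: np.ndarray
    weights: np.ndarray
    tets: list
    triangles: list
    edges: list
    vertices: list  # non-hidden point indices
    boundary_triangles: set = field(default_factory=set)

    def incident_tets(self):
        """Map from each simplex (any dim) to the tets containing it."""
        inc = {}
        for tet in self.tets:
            for k in (1, 2, 3):
                for face in itertools.combinations(tet, k):
                    inc.setdefault(face, []).append(tet)
        return inc

    def vertex_neighbors(self):
        nbr = {v: set() for v in self.vertices}
        for a, b in self.edges:
            nbr[a].add(b)
            nbr[b].add(a)
        return nbr

    def boundary_simplices(self):
        """Simplices lying on the convex-hull boundary (unbounded dual face)."""
        bnd = set(self.boundary_triangles)
        for tri in self.boundary_triangles:
            for k in (1, 2):
                bnd.update(itertools.combinations(tri, k))
        return bnd


def _orient_volume(pts):
    return float(np.linalg.det(pts[1:] - pts[0]))


def regular_triangulation(points, weights) -> RegularTriangulation:
    points = np.asarray(points, float).reshape(-1, 3)
    weights = np.asarray(weights, float).reshape(-1)
    m = len(points)
    tets: list = []

    if m >= 5:
        lifted = np.c_[points, (points**2).sum(axis=1) - weights]
        try:
            hull = ConvexHull(lifted)
        except QhullError as exc:
            raise DegenerateInput(str(exc)) from exc
        lower = hull.equations[:, 3] < -1e-12
        tets = [tuple(sorted(map(int, s))) for s in hull.simplices[lower]]
        if not tets:
            raise DegenerateInput("no lower-hull facets (all points co-hyperplanar)")
    elif m == 4:
        if abs(_orient_volume(points)) > 1e-12:
            tets = [(0, 1, 2, 3)]

    if tets:
        triangles = sorted({f for t in tets for f in itertools.combinations(t, 3)})
        edges = sorted({e for t in tets for e in itertools.combinations(t, 2)})
        vertices = sorted({v for t in tets for v in t})
    else:
        # fewer than 4 points (or a flat quadruple): complete simplex set
        vertices = list(range(m))
        edges = list(itertools.combinations(range(m), 2))
        triangles = list(itertools.combinations(range(m), 3))

    tri_count = {}
    for t in tets:
        for f in itertools.combinations(t, 3):
            tri_count[f] = tri_count.get(f, 0) + 1
    boundary = {f for f, n in tri_count.items() if n == 1}
    if not tets:
        boundary = set(triangles)

    return RegularTriangulation(points, weights, tets, triangles, edges,
                                vertices, boundary)


def orthocenter(points, weights):
    """Orthocenter and orthoradius^2 of a weighted k-simplex (k = 0..3).

    The orthocenter z lies in the affine hull and has equal power distance
    ``|z - c_i|^2 - w_i = w_z`` to every vertex; w_z is returned (can be
    negative when the vertices' balls deeply overlap).
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    w = np.asarray(weights, float).reshape(-1)
    if len(pts) == 1:
        return pts[0].copy(), -float(w[0])
    V = (pts[1:] - pts[0]).T  # 3 x k
    b = 0.5 * ((V**2).sum(axis=0) - w[1:] + w[0])
    G = V.T @ V
    try:
        y = np.linalg.solve(G, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInput("degenerate simplex in orthocenter") from exc
    z = pts[0] + V @ y
    wz = float(((z - pts[0]) ** 2).sum()) - float(w[0])
    return z, wz
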