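"""Solvent-excluded, van der Waals and solvent-accessible surface builders.

The SES is assembled from the regular triangulation of the probe-inflated
atom balls (alpha-shape route): every exposed atom contributes a convex
spherical patch, every partly exposed inflated-intersection circle a
rolling-probe saddle torus, and every free triple-tangency a concave probe
patch.

Patch clipping is exact up to a clash tolerance and is shared by all patch
kinds.  Let Omega be the free-probe region (probe centers clearing every
inflated ball).  A candidate point p with realizing probe center q (the
tangent probe for convex patches, the circle projection for tori, the patch
center for concave patches) lies on the SES iff

* q is free, and
* p is not within the probe radius of any other part of Omega, tested per
  boundary stratum: the faces (single-sphere rolls: the radial foot on a
  nearby inflated sphere is free), the edges (free arcs of the
  intersection circles), the vertices (free triple probes), and Omega's
  interior (p itself clears every inflated ball).

This predicate is the boundary-of-the-union-of-probe-balls membership test,
so self-intersections of saddles and concave patches in crowded geometries
(deep pockets, internal cavities) are clipped correctly without
case analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..geometry import SpherePatch, TorusPatch
from .atoms import AtomSet, perturb_atoms
from .base import PatchSet
from .delaunay import DegenerateInput, regular_triangulation

__all__ = ["SESParams", "build_ses", "build_vdw", "build_sas"]

_CLASH_TOL = 1e-7  # probe-center clearance tolerance (Angstrom)


@dataclass
class SESParams:
    """Probe radius plus the degeneracy-breaking jitter configuration."""

    probe_radius: float = 1.4
    perturbation: float = 1e-4  # the largest nonsignificant digit of 3-decimal coords
    seed: int = 0
    retries: int = 3

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.perturbation < 0:
            raise ValueError("perturbation must be >= 0")


class _FreeArc:
    """Free (unblocked) angular intervals of one probe circle."""

    __slots__ = ("center", "axis", "e1", "e2", "rho", "intervals")

    def __init__(self, center, axis, e1, e2, rho, intervals):
        self.center = center
        self.axis = axis
        self.e1 = e1
        self.e2 = e2
        self.rho = rho
        self.intervals = intervals

    def point_at(self, theta):
        return (self.center + self.rho * (math.cos(theta) * self.e1
                                          + math.sin(theta) * self.e2))

    def distance(self, p):
        """Exact distance from a point to the free arcs."""
        v = p - self.center
        h = float(v @ self.axis)
        x = float(v @ self.e1)
        y = float(v @ self.e2)
        theta = math.atan2(y, x) % (2.0 * math.pi)
        best = math.inf
        for a0, a1 in self.intervals:
            if a0 <= theta <= a1 or a0 <= theta + 2 * math.pi <= a1:
                rad = math.hypot(x, y)
                return math.hypot(rad - self.rho, h)
            for th in (a0, a1):
                q = self.point_at(th)
                best = min(best, math.dist(p, q))
        return best


class _SESMembership:
    """Shared exact membership context for all SES patch validators."""

    def __init__(self, centers, inflated_radii, probe_radius):
        self.centers = centers
        self.rp_inf = inflated_radii
        self.rp = probe_radius
        self.tree = cKDTree(centers)
        self.rmax = float(inflated_radii.max())
        self.arcs = []  # list of _FreeArc
        self.arc_tree = None
        self.arc_reach = 0.0
        self.probe_centers = []
        self.probe_tree = None

    # -- probe clearance -------------------------------------------------

    def probe_valid(self, q, exclude=()):
        """True iff a probe centered at q clears every inflated ball."""
        for k in self.tree.query_ball_point(q, self.rmax - _CLASH_TOL):
            if k in exclude:
                continue
            if math.dist(q, self.centers[k]) < self.rp_inf[k] - _CLASH_TOL:
                return False
        return True

    def finalize(self):
        if self.arcs:
            self.arc_tree = cKDTree([a.center for a in self.arcs])
            self.arc_reach = max(a.rho for a in self.arcs) + self.rp + 1e-6
        if self.probe_centers:
            self.probe_tree = cKDTree(np.asarray(self.probe_centers))

    # -- the strata predicate --------------------------------------------

    def on_surface(self, p, q_real, exclude):
        """p (with realizing probe center q_real) lies on the SES."""
        if not self.probe_valid(q_real, exclude):
            return False
        rp = self.rp
        if rp <= 0.0:
            return True  # union of balls: clearance of q_real = p suffices
        # interior stratum: p itself a free probe center -> deep solvent
        if self.probe_valid(p):
            return False
        cut = rp - 1e-9
        # vertex stratum: strictly inside another triple probe ball
        if self.probe_tree is not None:
            if self.probe_tree.query_ball_point(p, cut):
                return False
        # face strata: radial roll over one inflated sphere
        for k in self.tree.query_ball_point(p, self.rmax + cut):
            dk = math.dist(p, self.centers[k])
            if dk < 1e-12 or abs(dk - self.rp_inf[k]) >= cut:
                continue
            foot = self.centers[k] + (self.rp_inf[k] / dk) * (p - self.centers[k])
            if self.probe_valid(foot, (k,)):
                return False
        # edge strata: free arcs of the probe circles
        if self.arc_tree is not None:
            for ai in self.arc_tree.query_ball_point(p, self.arc_reach):
                if self.arcs[ai].distance(p) < cut:
                    return False
        return True


class _ConvexValidator:
    """Convex atom patch: tangent-probe realization."""

    def __init__(self, ctx, i, center, radius, inflated_radius):
        self.ctx, self.i = ctx, i
        self.center, self.radius = center, radius
        self.scale = inflated_radius / radius

    def __call__(self, p):
        p = np.asarray(p, float)
        q = self.center + self.scale * (p - self.center)
        return self.ctx.on_surface(p, q, (self.i,))


class _TorusValidator:
    """Saddle patch: the realizing probe is the circle projection."""

    def __init__(self, ctx, i, j, circle_center, circle_radius, axis):
        self.ctx = ctx
        self.i, self.j = i, j
        self.o = circle_center
        self.rho = circle_radius
        self.axis = axis

    def __call__(self, p):
        p = np.asarray(p, float)
        x = p - self.o
        h = float(x @ self.axis)
        radial = x - h * self.axis
        rn = float(np.linalg.norm(radial))
        if rn < 1e-12:
            return False
        q = self.o + self.rho * radial / rn
        return self.ctx.on_surface(p, q, (self.i, self.j))


class _ProbeValidator:
    """Concave probe patch: the patch center is the realizing probe."""

    def __init__(self, ctx, q, ijk):
        self.ctx = ctx
        self.q = q
        self.ijk = ijk

    def __call__(self, p):
        return self.ctx.on_surface(np.asarray(p, float), self.q, self.ijk)


def _uncovered_arcs(o, rho, e1, e2, neighbours, centers, rp_inf):
    """Free angular intervals of the probe circle (merged, in [0, 2pi]).

    Intervals may exceed 2pi to express wrap-around; [] means fully
    covered, [(0, 2pi)] fully free.
    """
    blocked = []
    for k in neighbours:
        v = centers[k] - o
        A = rho * rho + float(v @ v)
        B1 = 2.0 * rho * float(v @ e1)
        B2 = 2.0 * rho * float(v @ e2)
        C = math.hypot(B1, B2)
        rhs = A - rp_inf[k] ** 2
        if C < 1e-15:
            if rhs < 0:
                return []  # concentric ball swallows the whole circle
            continue
        cosv = rhs / C
        if cosv >= 1.0:
            continue
        if cosv <= -1.0:
            return []
        phi = math.atan2(B2, B1)
        dth = math.acos(cosv)
        blocked.append((phi - dth, phi + dth))
    if not blocked:
        return [(0.0, 2.0 * math.pi)]
    segs = []
    for a, b in blocked:
        width = min(b - a, 2 * math.pi)
        a %= 2 * math.pi
        b = a + width
        if b > 2 * math.pi:
            segs.append((a, 2 * math.pi))
            segs.append((0.0, b - 2 * math.pi))
        else:
            segs.append((a, b))
    segs.sort()
    merged = [list(segs[0])]
    for a, b in segs[1:]:
        if a <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    free = []
    cur = 0.0
    for a, b in merged:
        if a > cur + 1e-12:
            free.append((cur, a))
        cur = max(cur, b)
    if cur < 2 * math.pi - 1e-12:
        free.append((cur, 2 * math.pi))
    return free


def _trisector_points(ci, cj, ck, ri, rj, rk):
    """The 0-2 points at distance (r_i, r_j, r_k) from the three centers."""
    u1 = cj - ci
    u2 = ck - ci
    n = np.cross(u1, u2)
    n2 = float(n @ n)
    if n2 < 1e-20:
        return []
    b1 = 0.5 * (float(u1 @ u1) + ri * ri - rj * rj)
    b2 = 0.5 * (float(u2 @ u2) + ri * ri - rk * rk)
    G = np.array([[float(u1 @ u1), float(u1 @ u2)],
                  [float(u1 @ u2), float(u2 @ u2)]])
    try:
        ab = np.linalg.solve(G, np.array([b1, b2]))
    except np.linalg.LinAlgError:
        return []
    p_plane = ab[0] * u1 + ab[1] * u2
    d2 = ri * ri - float(p_plane @ p_plane)
    if d2 <= 1e-14:
        return []
    t = math.sqrt(d2 / n2)
    return [ci + p_plane + t * n, ci + p_plane - t * n]


def _basis_perp(a):
    t = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, t)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(a, e1)


def build_ses(atoms: AtomSet, params: SESParams | None = None) -> PatchSet:
    """Build the SES patch set; see the module docstring for the pipeline."""
    params = params or SESParams()
    last_err = None
    for attempt in range(params.retries + 1):
        work = atoms
        if params.perturbation > 0:
            work = perturb_atoms(atoms, params.perturbation, params.seed + attempt)
        try:
            return _build_ses_once(work, params)
        except DegenerateInput as exc:
            last_err = exc
    raise DegenerateInput(
        f"degenerate configuration after {params.retries + 1} perturbation "
        f"attempts: {last_err}"
    )


def _build_ses_once(atoms: AtomSet, params: SESParams) -> PatchSet:
    centers = atoms.centers
    radii = atoms.radii
    rp = params.probe_radius
    rp_inf = radii + rp
    m = len(atoms)

    if m == 1:
        patch = SpherePatch(centers[0], float(radii[0]), "convex")
        return PatchSet([patch], {"kind": "ses", "probe_radius": rp,
                                  "n_atoms": 1, "n_convex": 1, "n_torus": 0,
                                  "n_probe": 0})

    ctx = _SESMembership(centers, rp_inf, rp)
    rt = regular_triangulation(centers, rp_inf**2)
    rt_vertices = set(rt.vertices)

    patches = []
    has_uncovered = np.zeros(m, bool)
    n_torus = 0

    # saddle tori from partly exposed inflated-intersection circles
    for (i, j) in rt.edges:
        ci, cj = centers[i], centers[j]
        d = math.dist(ci, cj)
        if d >= rp_inf[i] + rp_inf[j] or d <= abs(rp_inf[i] - rp_inf[j]) or d < 1e-12:
            continue
        axis = (cj - ci) / d
        a_off = (d * d + rp_inf[i] ** 2 - rp_inf[j] ** 2) / (2 * d)
        rho2 = rp_inf[i] ** 2 - a_off * a_off
        if rho2 <= 1e-14:
            continue
        rho = math.sqrt(rho2)
        o = ci + a_off * axis
        e1, e2 = _basis_perp(axis)
        nbrs = [k for k in ctx.tree.query_ball_point(o, rho + ctx.rmax)
                if k != i and k != j]
        free = _uncovered_arcs(o, rho, e1, e2, nbrs, centers, rp_inf)
        if not free:
            continue
        has_uncovered[i] = has_uncovered[j] = True
        if rp > 0:
            ctx.arcs.append(_FreeArc(o, axis, e1, e2, rho, free))
            val = _TorusValidator(ctx, i, j, o, rho, axis)
            # bbox from the free arcs only: the saddle lives within the
            # probe radius of the unblocked part of the circle
            qs = []
            for a0, a1 in free:
                n_s = max(8, int(math.ceil((a1 - a0) / 0.15)) + 1)
                th = np.linspace(a0, a1, n_s)
                qs.append(o[None, :] + rho * (np.cos(th)[:, None] * e1
                                              + np.sin(th)[:, None] * e2))
            qs = np.vstack(qs)
            pad = rp + rho * 0.15**2 / 8.0 + 1e-6
            patches.append(TorusPatch(o, axis, rho, rp, validator=val,
                                      bbox_lo=qs.min(axis=0) - pad,
                                      bbox_hi=qs.max(axis=0) + pad))
            n_torus += 1

    # concave probe patches from free triple tangencies
    if rp > 0:
        for (i, j, k) in rt.triangles:
            for q in _trisector_points(centers[i], centers[j], centers[k],
                                       rp_inf[i], rp_inf[j], rp_inf[k]):
                if not ctx.probe_valid(q, (i, j, k)):
                    continue
                val = _ProbeValidator(ctx, q, (i, j, k))
                ctx.probe_centers.append(q)
                patches.append(SpherePatch(q, rp, "concave", validator=val))
    ctx.finalize()

    # convex patches for exposed atoms
    n_convex = 0
    for i in range(m):
        if i not in rt_vertices:
            continue  # power-hidden: ball covered by the others
        buried = False
        has_cap = False
        for j in ctx.tree.query_ball_point(centers[i], rp_inf[i] + ctx.rmax):
            if j == i:
                continue
            d = math.dist(centers[i], centers[j])
            if d >= rp_inf[i] + rp_inf[j]:
                continue
            if d + rp_inf[i] <= rp_inf[j] + 1e-12:
                buried = True
                break
            if d > abs(rp_inf[i] - rp_inf[j]):
                has_cap = True
        if buried or (has_cap and not has_uncovered[i]):
            continue
        val = _ConvexValidator(ctx, i, centers[i], float(radii[i]), float(rp_inf[i]))
        patches.append(SpherePatch(centers[i], float(radii[i]), "convex",
                                   validator=val))
        n_convex += 1

    if not patches:
        raise DegenerateInput("SES construction produced no patches")
    return PatchSet(patches, {
        "kind": "ses", "probe_radius": rp, "n_atoms": m,
        "n_convex": n_convex, "n_torus": n_torus,
        "n_probe": len(ctx.probe_centers),
    })


def build_vdw(atoms: AtomSet, params: SESParams | None = None) -> PatchSet:
    """Union-of-atom-spheres boundary: the SES with null probe radius."""
    params = params or SESParams()
    p = SESParams(probe_radius=0.0, perturbation=params.perturbation,
                  seed=params.seed, retries=params.retries)
    ps = build_ses(atoms, p)
    ps.metadata["kind"] = "vdw"
    return ps


def build_sas(atoms: AtomSet, probe_radius: float = 1.4,
              params: SESParams | None = None) -> PatchSet:
    """Solvent-accessible surface: VdW of the probe-inflated radii."""
    ps = build_vdw(atoms.inflated(probe_radius), params)
    ps.metadata.update({"kind": "sas", "probe_radius": probe_radius})
    return ps
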