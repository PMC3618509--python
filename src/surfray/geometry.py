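"""Exact-as-practical geometric primitives.

Ray/patch intersection kernels for the analytic patch types a molecular
surface decomposes into (spheres, tori, quadrics, triangles), plus real-root
isolation for the low-degree polynomials those intersections reduce to.

All routines work in double precision.  Tangential contacts (discriminant or
derivative within tolerance of zero) are reported as *zero* intersections:
a grazing ray does not change in/out parity, and the ray-casting layer
depends on parity being exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Ray",
    "Polynomial",
    "sturm_roots",
    "ray_sphere",
    "ray_torus",
    "ray_quadric",
    "ray_triangle",
    "TrimPrimitive",
    "point_in_trim",
    "SpherePatch",
    "TorusPatch",
    "QuadricPatch",
]

#: tolerance under which a quadratic discriminant counts as tangency
TANGENT_EPS = 1e-12
#: absolute refinement tolerance for isolated polynomial roots (in t)
ROOT_TOL = 1e-10


# ---------------------------------------------------------------------------
# rays
# ---------------------------------------------------------------------------

@dataclass
class Ray:
    """A directed half-line with a finite extent, in Angstroms.

    Grid rays are axis aligned; arbitrary unit directions are accepted so the
    same kernels serve projections and oracle tests.
    """

    origin: np.ndarray
    direction: np.ndarray
    t_max: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(self.direction))
        if not np.isfinite(self.origin).all() or n == 0.0 or self.t_max <= 0:
            raise ValueError("invalid ray")
        self.direction = self.direction / n

    def point(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


# ---------------------------------------------------------------------------
# polynomials and Sturm sequences
# ---------------------------------------------------------------------------

class Polynomial:
    """Dense real polynomial, ascending coefficients, degree <= 4 in practice.

    Thin wrapper used as the input contract of :func:`sturm_roots`; heavier
    polynomial machinery (numpy.polynomial) would be overkill for the fixed
    quartic work the intersection kernels need.
    """

    __slots__ = ("coeffs",)

    def __init__(self, coeffs) -> None:
        c = np.atleast_1d(np.asarray(coeffs, dtype=float))
        if c.ndim != 1 or c.size == 0:
            raise ValueError("coefficients must be a 1-D sequence")
        if not np.isfinite(c).all():
            raise ValueError("non-finite polynomial coefficients")
        # strip (numerically) zero leading terms relative to the largest one
        scale = float(np.max(np.abs(c)))
        if scale == 0.0:
            c = c[:1]
        else:
            last = c.size - 1
            while last > 0 and abs(c[last]) <= 1e-14 * scale:
                last -= 1
            c = c[: last + 1]
        self.coeffs = c

    @property
    def degree(self) -> int:
        return self.coeffs.size - 1

    def __call__(self, x: float) -> float:
        # Horner; loop beats np.polyval at degree <= 4
        acc = 0.0
        for c in self.coeffs[::-1]:
            acc = acc * x + c
        return acc

    def derivative(self) -> "Polynomial":
        if self.degree == 0:
            return Polynomial([0.0])
        k = np.arange(1, self.coeffs.size)
        return Polynomial(self.coeffs[1:] * k)

    def normalized(self) -> "Polynomial":
        return Polynomial(self.coeffs / self.coeffs[-1])


def _poly_rem(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Remainder of a/b, ascending coefficient arrays."""
    r = a.astype(float).copy()
    db, lb = b.size - 1, b[-1]
    while r.size - 1 >= db and np.max(np.abs(r)) > 0.0:
        shift = r.size - 1 - db
        q = r[-1] / lb
        r[shift : shift + db + 1] -= q * b
        r = r[:-1]
        scale = float(np.max(np.abs(r))) if r.size else 0.0
        while r.size > 1 and abs(r[-1]) <= 1e-13 * max(scale, 1e-300):
            r = r[:-1]
    return r


def _sturm_chain(p: Polynomial) -> list[np.ndarray]:
    chain = [p.coeffs, p.derivative().coeffs]
    while chain[-1].size > 1:
        rem = _poly_rem(chain[-2], chain[-1])
        if rem.size == 1 and rem[0] == 0.0:
            break
        chain.append(-rem)
    return chain


def _sign_changes(chain: list[np.ndarray], x: float) -> int:
    prev, changes = 0, 0
    for c in chain:
        acc = 0.0
        for ci in c[::-1]:
            acc = acc * x + ci
        s = 0 if acc == 0.0 else (1 if acc > 0.0 else -1)
        if s != 0:
            if prev != 0 and s != prev:
                changes += 1
            prev = s
    return changes


def _square_free(p: Polynomial) -> Polynomial:
    """Divide out repeated factors using the Sturm chain's trailing gcd."""
    chain = _sturm_chain(p)
    tail = chain[-1]
    if tail.size > 1:  # non-constant gcd(p, p') -> repeated roots present
        # deflate: p / gcd via synthetic division
        g = tail / tail[-1]
        q = np.zeros(p.coeffs.size - g.size + 1)
        r = p.coeffs.copy()
        for i in range(q.size - 1, -1, -1):
            q[i] = r[i + g.size - 1] / g[-1]
            r[i : i + g.size] -= q[i] * g
        return Polynomial(q)
    return p


def sturm_roots(p: Polynomial, interval: tuple[float, float], tol: float = ROOT_TOL) -> list[float]:
    """All distinct real roots of ``p`` in ``[a, b]``, ascending.

    Sturm-sequence isolation followed by bisection refinement to ``tol``
    (absolute, in the variable).  Multiple roots are collapsed to a single
    entry; the caller decides what a tangency means.
    """
    if not isinstance(p, Polynomial):
        p = Polynomial(p)
    a, b = float(interval[0]), float(interval[1])
    if not (a < b):
        raise ValueError("interval must satisfy a < b")
    if p.degree < 1:
        return []
    p = _square_free(p.normalized())
    if p.degree < 1:
        return []
    if p.degree == 1:
        r = -p.coeffs[0] / p.coeffs[1]
        return [r] if a - tol <= r <= b + tol and a <= r <= b else ([r] if a <= r <= b else [])

    chain = _sturm_chain(p)
    roots: list[float] = []

    # endpoints: Sturm counts roots in half-open intervals, treat explicitly
    ea, eb = abs(p(a)), abs(p(b))
    scale = max(1.0, float(np.max(np.abs(p.coeffs))))

    def refine(lo: float, hi: float) -> float:
        flo = p(lo)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if hi - lo <= tol:
                break
            fm = p(mid)
            if fm == 0.0:
                return mid
            if (flo < 0) != (fm < 0):
                hi = mid
            else:
                lo, flo = mid, fm
        x = 0.5 * (lo + hi)
        dp = p.derivative()
        for _ in range(3):  # Newton polish
            d = dp(x)
            if d == 0.0:
                break
            step = p(x) / d
            if abs(step) > tol * 1e3:
                break
            x -= step
        return x

    stack = [(a, b, _sign_changes(chain, a), _sign_changes(chain, b))]
    while stack:
        lo, hi, vlo, vhi = stack.pop()
        n = vlo - vhi
        if n <= 0:
            continue
        if hi - lo <= tol:
            roots.append(0.5 * (lo + hi))
            continue
        if n == 1:
            flo, fhi = p(lo), p(hi)
            if (flo < 0) != (fhi < 0):
                roots.append(refine(lo, hi))
                continue
        mid = 0.5 * (lo + hi)
        vm = _sign_changes(chain, mid)
        stack.append((lo, mid, vlo, vm))
        stack.append((mid, hi, vm, vhi))

    if ea <= 1e-12 * scale and not any(abs(r - a) <= 10 * tol for r in roots):
        roots.append(a)
    if eb <= 1e-12 * scale and not any(abs(r - b) <= 10 * tol for r in roots):
        roots.append(b)
    roots.sort()
    # collapse clusters closer than the refinement tolerance
    out: list[float] = []
    for r in roots:
        if not out or r - out[-1] > 10 * tol:
            out.append(r)
    return out


def root_multiplicity(p: Polynomial, x: float, rel_tol: float = 1e-6) -> int:
    """Estimate the multiplicity of ``x`` as a root of ``p`` from derivatives."""
    scale = max(1.0, float(np.max(np.abs(p.coeffs))))
    q = p
    for m in range(1, p.degree + 1):
        q = q.derivative()
        if abs(q(x)) > rel_tol * scale:
            return m
    return p.degree


# ---------------------------------------------------------------------------
# ray / primitive intersections
# ---------------------------------------------------------------------------

def ray_sphere(origin, direction, center, radius, t_max=math.inf):
    """Ray-sphere crossings: 0 or 2 ascending t values.

    Tangency (discriminant within :data:`TANGENT_EPS` of zero, scaled) is
    discarded: grazing contact does not change parity.
    """
    o = np.asarray(origin, float) - np.asarray(center, float)
    d = np.asarray(direction, float)
    b = float(o @ d)
    c = float(o @ o) - radius * radius
    disc = b * b - c
    if disc <= TANGENT_EPS * max(1.0, radius * radius):
        return []
    s = math.sqrt(disc)
    ts = [-b - s, -b + s]
    return [t for t in ts if 0.0 <= t <= t_max]


def _torus_quartic(origin, direction, center, axis, R, r):
    o = np.asarray(origin, float) - np.asarray(center, float)
    d = np.asarray(direction, float)
    a = np.asarray(axis, float)
    od, oo = float(o @ d), float(o @ o)
    m, k = float(o @ a), float(d @ a)
    # A(t) = |o + t d|^2 + R^2 - r^2  (unit direction)
    A = np.array([oo + R * R - r * r, 2.0 * od, 1.0])
    A2 = np.convolve(A, A)
    # rho^2(t) = |o + t d|^2 - (m + t k)^2
    rho2 = np.array([oo - m * m, 2.0 * (od - m * k), 1.0 - k * k])
    q = A2.copy()
    q[: rho2.size] -= 4.0 * R * R * rho2
    return Polynomial(q)


def _quartic_sturm_roots(c, lo, hi, tol=ROOT_TOL):
    """Sturm isolation + bisection/Newton for a quartic, scalar fast path.

    ``c`` is ascending (c0..c4, c4 != 0).  Returns distinct real roots in
    [lo, hi]; falls back to the generic route on degenerate chains.
    """
    a0, a1, a2, a3 = c[0] / c[4], c[1] / c[4], c[2] / c[4], c[3] / c[4]
    # p2 = -rem(p, p') (closed form), p3 = -rem(p', p2), p4 = -rem(p2, p3)
    b2 = 3.0 * a3 * a3 / 16.0 - a2 / 2.0
    b1 = a2 * a3 / 8.0 - 3.0 * a1 / 4.0
    b0 = a1 * a3 / 16.0 - a0
    scale = max(abs(b2), abs(b1), abs(b0))
    if scale < 1e-13 or abs(b2) < 1e-13 * scale:
        return None  # degenerate chain: let the generic solver handle it
    # rem of cubic (4, 3a3, 2a2, a1) by quadratic (b2, b1, b0):
    q1 = 4.0 / b2
    q0 = (3.0 * a3 - q1 * b1) / b2
    d1 = 2.0 * a2 - (q1 * b0 + q0 * b1)
    d0 = a1 - q0 * b0
    dscale = max(abs(d1), abs(d0))
    if dscale < 1e-13 or abs(d1) < 1e-13 * max(dscale, 1.0):
        return None
    e1, e0 = -d1, -d0  # p3 = -(d1 x + d0)
    # rem of quadratic (b2, b1, b0) by linear (e1, e0)
    r = e0 / e1
    p4v = -(b2 * r * r - b1 * r + b0)
    if abs(p4v) < 1e-12 * max(scale, 1.0):
        return None  # repeated roots: generic (square-free) route

    def chain_signs(x):
        p = (((x + a3) * x + a2) * x + a1) * x + a0
        dp = ((4.0 * x + 3.0 * a3) * x + 2.0 * a2) * x + a1
        s2 = (b2 * x + b1) * x + b0
        s3 = e1 * x + e0
        changes = 0
        prev = 0
        for v in (p, dp, s2, s3, p4v):
            s = 0 if v == 0.0 else (1 if v > 0.0 else -1)
            if s != 0:
                if prev != 0 and s != prev:
                    changes += 1
                prev = s
        return changes

    def pval(x):
        return (((x + a3) * x + a2) * x + a1) * x + a0

    def dpval(x):
        return ((4.0 * x + 3.0 * a3) * x + 2.0 * a2) * x + a1

    roots = []
    stack = [(lo, hi, chain_signs(lo), chain_signs(hi))]
    while stack:
        xa, xb, va, vb = stack.pop()
        n = va - vb
        if n <= 0:
            continue
        if n == 1:
            fa, fb = pval(xa), pval(xb)
            if (fa < 0) != (fb < 0):
                # coarse bisection, then safeguarded Newton
                a_, b_ = xa, xb
                fa_ = fa
                coarse = max(tol, 1e-3 * (xb - xa))
                while b_ - a_ > coarse:
                    m = 0.5 * (a_ + b_)
                    fm = pval(m)
                    if fm == 0.0:
                        a_ = b_ = m
                        break
                    if (fa_ < 0) != (fm < 0):
                        b_ = m
                    else:
                        a_, fa_ = m, fm
                x = 0.5 * (a_ + b_)
                for _ in range(30):
                    dv = dpval(x)
                    if dv == 0.0:
                        break
                    step = pval(x) / dv
                    x -= step
                    if x < a_ or x > b_:  # fall back to bisection
                        while b_ - a_ > tol:
                            m = 0.5 * (a_ + b_)
                            fm = pval(m)
                            if fm == 0.0:
                                break
                            if (fa_ < 0) != (fm < 0):
                                b_ = m
                            else:
                                a_, fa_ = m, fm
                        x = 0.5 * (a_ + b_)
                        break
                    if abs(step) <= 0.25 * tol:
                        break
                roots.append(x)
                continue
        if xb - xa <= tol:
            roots.append(0.5 * (xa + xb))
            continue
        m = 0.5 * (xa + xb)
        vm = chain_signs(m)
        stack.append((xa, m, va, vm))
        stack.append((m, xb, vm, vb))
    # endpoint roots
    sc = max(1.0, abs(a0), abs(a1), abs(a2), abs(a3))
    for x in (lo, hi):
        if abs(pval(x)) <= 1e-12 * sc and not any(abs(r0 - x) <= 10 * tol
                                                  for r0 in roots):
            roots.append(x)
    roots.sort()
    out = []
    for r0 in roots:
        if not out or r0 - out[-1] > 10 * tol:
            out.append(r0)
    return out


def ray_torus(origin, direction, center, axis, major_radius, minor_radius, t_max):
    """Ray-torus crossings (0-4), via Sturm isolation of the quartic.

    Returns only transversal crossings of the *outer* sheet
    (``dist(p, major circle) = r``); spindle-sheet roots, which lie inside
    the probe-swept solid, and even-multiplicity (tangential) roots are
    dropped.
    """
    R, r = float(major_radius), float(minor_radius)
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    c = np.asarray(center, float)
    a = np.asarray(axis, float)
    ox, oy, oz = float(o[0] - c[0]), float(o[1] - c[1]), float(o[2] - c[2])
    dx, dy, dz = float(d[0]), float(d[1]), float(d[2])
    ax, ay, az = float(a[0]), float(a[1]), float(a[2])
    od = ox * dx + oy * dy + oz * dz
    oo = ox * ox + oy * oy + oz * oz
    m = ox * ax + oy * ay + oz * az
    k = dx * ax + dy * ay + dz * az
    # A(t) = |o + t d|^2 + R^2 - r^2;  quartic = A^2 - 4 R^2 rho^2(t)
    g0, g1 = oo + R * R - r * r, 2.0 * od
    c4 = 1.0
    c3 = 2.0 * g1
    c2 = g1 * g1 + 2.0 * g0 - 4.0 * R * R * (1.0 - k * k)
    c1 = 2.0 * g0 * g1 - 4.0 * R * R * 2.0 * (od - m * k)
    c0 = g0 * g0 - 4.0 * R * R * (oo - m * m)
    roots = _quartic_sturm_roots((c0, c1, c2, c3, c4), 0.0, float(t_max))
    square_free = roots is not None
    if roots is None:
        p = _torus_quartic(origin, direction, center, axis, R, r)
        if p.degree < 1:
            return []
        roots = sturm_roots(p, (0.0, float(t_max)))
    out = []
    for t in roots:
        if not square_free:
            p = _torus_quartic(origin, direction, center, axis, R, r)
            if root_multiplicity(p, t) % 2 == 0:
                continue  # tangency
        x1, x2, x3 = ox + t * dx, oy + t * dy, oz + t * dz
        h = x1 * ax + x2 * ay + x3 * az
        rho = math.sqrt(max(x1 * x1 + x2 * x2 + x3 * x3 - h * h, 0.0))
        # outer sheet test: distance to the major circle equals minor radius
        if abs(math.hypot(rho - R, h) - r) > 1e-6 * max(1.0, r):
            continue
        out.append(t)
    return out


def torus_point_normal(point, center, axis, major_radius, minor_radius):
    """Geometric (tube-outward) unit normal of a torus at an on-surface point."""
    c = np.asarray(center, float)
    a = np.asarray(axis, float)
    x = np.asarray(point, float) - c
    h = float(x @ a)
    radial = x - h * a
    rho = float(np.linalg.norm(radial))
    if rho < 1e-12:
        return a.copy()  # degenerate: on the axis
    q = c + major_radius * radial / rho  # nearest major-circle point
    n = (np.asarray(point, float) - q) / minor_radius
    nn = float(np.linalg.norm(n))
    return n / nn if nn > 0 else a.copy()


def ray_quadric(origin, direction, A, center, const, t_max):
    """Crossings with the quadric f(x) = (x-z)^T A (x-z) + const = 0.

    The restriction to the ray is a quadratic; a numerically vanishing
    restriction returns no hits.  0-2 ascending t values.
    """
    o = np.asarray(origin, float) - np.asarray(center, float)
    d = np.asarray(direction, float)
    Ad = A @ d
    a2 = float(d @ Ad)
    a1 = 2.0 * float(o @ Ad)
    a0 = float(o @ (A @ o)) + const
    scale = max(abs(a2), abs(a1), abs(a0), 1e-30)
    if abs(a2) <= 1e-14 * scale:
        if abs(a1) <= 1e-14 * scale:
            return []
        t = -a0 / a1
        return [t] if 0.0 <= t <= t_max else []
    disc = a1 * a1 - 4.0 * a2 * a0
    if disc <= TANGENT_EPS * scale * scale:
        return []
    s = math.sqrt(disc)
    ts = sorted(((-a1 - s) / (2 * a2), (-a1 + s) / (2 * a2)))
    return [t for t in ts if 0.0 <= t <= t_max]


def quadric_gradient(point, A, center):
    return 2.0 * (A @ (np.asarray(point, float) - np.asarray(center, float)))


def ray_triangle(origin, direction, v0, v1, v2, t_max=math.inf, eps=1e-12):
    """Moller-Trumbore ray/triangle test.

    Returns ``(t, u, v)`` barycentric data for a hit with ``0 <= t <= t_max``,
    else ``None``.  Zero-area triangles are treated as misses.  Hits landing
    within ``eps`` of an edge are still reported; edge ownership
    deduplication is applied one level up where mesh adjacency is known.
    """
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    e1 = np.asarray(v1, float) - v0
    e2 = np.asarray(v2, float) - v0
    pvec = np.cross(d, e2)
    det = float(e1 @ pvec)
    if abs(det) < eps:
        return None  # parallel or degenerate
    inv = 1.0 / det
    tvec = o - v0
    u = float(tvec @ pvec) * inv
    if u < -eps or u > 1.0 + eps:
        return None
    qvec = np.cross(tvec, e1)
    v = float(d @ qvec) * inv
    if v < -eps or u + v > 1.0 + eps:
        return None
    t = float(e2 @ qvec) * inv
    if t < 0.0 or t > t_max:
        return None
    return t, u, v


# ---------------------------------------------------------------------------
# trimming primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimPrimitive:
    """A pure point-membership predicate used to clip analytic patches.

    ``half_space`` keeps points with ``normal . x <= offset``;
    ``sphere_inside`` keeps the closed ball; ``sphere_outside`` its closed
    complement.  A small tolerance keeps patch seams watertight.
    """

    kind: str  # half_space | sphere_inside | sphere_outside
    center: tuple = (0.0, 0.0, 0.0)  # plane normal for half_space
    radius: float = 0.0  # plane offset for half_space
    tol: float = 1e-9

    def contains(self, point) -> bool:
        p = np.asarray(point, float)
        c = np.asarray(self.center, float)
        if self.kind == "half_space":
            return float(p @ c) <= self.radius + self.tol
        d2 = float(((p - c) ** 2).sum())
        r2 = self.radius * self.radius
        if self.kind == "sphere_inside":
            return d2 <= r2 + self.tol * max(1.0, r2)
        if self.kind == "sphere_outside":
            return d2 >= r2 - self.tol * max(1.0, r2)
        raise ValueError(f"unknown trim kind {self.kind!r}")


def point_in_trim(point, trims) -> bool:
    """True iff the point satisfies every trim predicate (conjunction)."""
    if not np.isfinite(np.asarray(point, float)).all():
        raise ValueError("non-finite point")
    return all(t.contains(point) for t in trims)


# ---------------------------------------------------------------------------
# analytic patches
# ---------------------------------------------------------------------------

@dataclass
class SpherePatch:
    """Spherical patch: convex (atom) or concave (probe) orientation.

    ``validator`` is an optional exact membership predicate supplied by the
    surface builder (e.g. probe-placement validity for SES patches) applied
    on top of the declarative ``trims``.
    """

    center: np.ndarray
    radius: float
    orientation: str = "convex"  # convex | concave
    trims: list = field(default_factory=list)
    validator: object = None

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def bbox(self):
        r = self.radius
        return self.center - r, self.center + r

    def contains_point(self, p) -> bool:
        if not point_in_trim(p, self.trims):
            return False
        return self.validator is None or bool(self.validator(p))

    def implicit(self, p) -> float:
        return float(((np.asarray(p, float) - self.center) ** 2).sum()) - self.radius ** 2

    def hits(self, origin, direction, t_max):
        out = []
        for t in ray_sphere(origin, direction, self.center, self.radius, t_max):
            p = np.asarray(origin, float) + t * np.asarray(direction, float)
            if not self.contains_point(p):
                continue
            n = (p - self.center) / self.radius
            if self.orientation == "concave":
                n = -n
            out.append((t, p, n))
        return out


@dataclass
class TorusPatch:
    """Rolling-probe saddle torus of an SES edge (tube-inward material side)."""

    center: np.ndarray
    axis: np.ndarray
    major_radius: float
    minor_radius: float
    trims: list = field(default_factory=list)
    validator: object = None
    bbox_lo: np.ndarray = None  # tighter box from the valid probe arcs
    bbox_hi: np.ndarray = None

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        a = np.asarray(self.axis, float)
        self.axis = a / np.linalg.norm(a)
        if self.major_radius <= 0 or self.minor_radius <= 0:
            raise ValueError("torus radii must be positive")

    def bbox(self):
        if self.bbox_lo is not None:
            return self.bbox_lo, self.bbox_hi
        # extent along direction e is R * sqrt(1 - (a.e)^2) + r
        a = self.axis
        e = (self.major_radius * np.sqrt(np.clip(1.0 - a * a, 0.0, 1.0))
             + self.minor_radius)
        return self.center - e, self.center + e

    def contains_point(self, p) -> bool:
        if not point_in_trim(p, self.trims):
            return False
        return self.validator is None or bool(self.validator(p))

    def implicit(self, p) -> float:
        x = np.asarray(p, float) - self.center
        h = float(x @ self.axis)
        rho2 = float(x @ x) - h * h
        s = float(x @ x) + self.major_radius ** 2 - self.minor_radius ** 2
        return s * s - 4.0 * self.major_radius ** 2 * rho2

    def surface_residual(self, p) -> float:
        """Distance-to-circle residual: |dist(p, major circle) - r|."""
        x = np.asarray(p, float) - self.center
        h = float(x @ self.axis)
        rho = math.sqrt(max(float(x @ x) - h * h, 0.0))
        return abs(math.hypot(rho - self.major_radius, h) - self.minor_radius)

    def _quick_reject(self, o, d, t_max):
        """Cheap slab + ring interval tests before the quartic solve."""
        a = self.axis
        R, r = self.major_radius, self.minor_radius
        oc = o - self.center
        ka = float(d @ a)
        ha = float(oc @ a)
        # axial slab |h(t)| <= r
        if abs(ka) < 1e-14:
            if abs(ha) > r:
                return True
            t0, t1 = 0.0, t_max
        else:
            ta = (-r - ha) / ka
            tb = (r - ha) / ka
            t0, t1 = max(0.0, min(ta, tb)), min(t_max, max(ta, tb))
            if t0 > t1:
                return True
        # radial ring (R - r)^2 <= rho^2(t) <= (R + r)^2 somewhere in [t0, t1]
        alpha = 1.0 - ka * ka
        beta = 2.0 * (float(oc @ d) - ha * ka)
        gamma = float(oc @ oc) - ha * ha
        v0 = (alpha * t0 + beta) * t0 + gamma
        v1 = (alpha * t1 + beta) * t1 + gamma
        vmin = min(v0, v1)
        vmax = max(v0, v1)
        if alpha > 1e-14:
            tv = -beta / (2.0 * alpha)
            if t0 < tv < t1:
                vmin = min(vmin, (alpha * tv + beta) * tv + gamma)
        lo2 = max(R - r, 0.0) ** 2
        hi2 = (R + r) ** 2
        return vmax < lo2 or vmin > hi2

    def hits(self, origin, direction, t_max):
        o = np.asarray(origin, float)
        d = np.asarray(direction, float)
        if self._quick_reject(o, d, t_max):
            return []
        out = []
        ts = ray_torus(origin, direction, self.center, self.axis,
                       self.major_radius, self.minor_radius, t_max)
        for t in ts:
            p = np.asarray(origin, float) + t * np.asarray(direction, float)
            if not self.contains_point(p):
                continue
            # SES saddle: solvent probe occupies the tube -> material normal
            # points from the surface point toward the tube's center circle.
            n = -torus_point_normal(p, self.center, self.axis,
                                    self.major_radius, self.minor_radius)
            out.append((t, p, n))
        return out


@dataclass
class QuadricPatch:
    """Trimmed quadric f(x) = (x-z)^T A (x-z) + c = 0 with body f <= 0.

    The skin-surface mixed-complex patches are all of this form (spheres and
    hyperboloids of revolution); A is symmetric so the restriction to any
    line is a quadratic.
    """

    A: np.ndarray
    center: np.ndarray
    const: float
    trims: list = field(default_factory=list)
    validator: object = None
    bbox_lo: np.ndarray = None
    bbox_hi: np.ndarray = None

    def __post_init__(self):
        self.A = np.asarray(self.A, float)
        self.center = np.asarray(self.center, float)
        if not np.allclose(self.A, self.A.T, atol=1e-12):
            raise ValueError("quadric matrix must be symmetric")

    @property
    def Q(self) -> np.ndarray:
        """Homogeneous 4x4 coefficient matrix of x^T Q x = 0."""
        Q = np.zeros((4, 4))
        Q[:3, :3] = self.A
        b = -self.A @ self.center
        Q[:3, 3] = b
        Q[3, :3] = b
        Q[3, 3] = float(self.center @ (self.A @ self.center)) + self.const
        return Q

    def bbox(self):
        if self.bbox_lo is None:
            raise ValueError("unbounded quadric patch without an explicit bbox")
        return self.bbox_lo, self.bbox_hi

    def implicit(self, p) -> float:
        u = np.asarray(p, float) - self.center
        return float(u @ (self.A @ u)) + self.const

    def contains_point(self, p) -> bool:
        if not point_in_trim(p, self.trims):
            return False
        return self.validator is None or bool(self.validator(p))

    def hits(self, origin, direction, t_max):
        out = []
        for t in ray_quadric(origin, direction, self.A, self.center, self.const, t_max):
            p = np.asarray(origin, float) + t * np.asarray(direction, float)
            if not self.contains_point(p):
                continue
            g = quadric_gradient(p, self.A, self.center)
            gn = float(np.linalg.norm(g))
            if gn < 1e-14:
                continue
            out.append((t, p, g / gn))  # f < 0 inside: gradient points outward
        return out
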