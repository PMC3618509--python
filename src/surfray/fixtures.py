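"""Analytic shapes and synthetic molecules with known ground truth.

Every fixture carries the truth values (areas, volumes, genus, expected
cavity counts) computed in closed form or by the stated oracle (1-D
surface-of-revolution quadrature for the two-sphere SES, Monte-Carlo
membership for the hollow-shell void), so every pipeline stage is testable
without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .surfaces.atoms import AtomSet

__all__ = [
    "Fixture", "gen_sphere_atom", "gen_two_atoms", "gen_linear_chain",
    "gen_c60", "gen_hollow_shell", "gen_random_cluster", "gen_torus_mesh",
    "gen_box_mesh", "two_sphere_ses_truth",
]


@dataclass
class Fixture:
    """An AtomSet or mesh plus its analytic ground truth."""

    kind: str
    atoms: AtomSet = None
    mesh_vertices: np.ndarray = None
    mesh_faces: np.ndarray = None
    truth: dict = field(default_factory=dict)
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def mesh_surface(self):
        from .surfaces.base import MeshSurface
        return MeshSurface(self.mesh_vertices, self.mesh_faces)


# ---------------------------------------------------------------------------
# atom fixtures
# ---------------------------------------------------------------------------

def gen_sphere_atom(radius=1.0) -> Fixture:
    """One atom: VdW/SES area 4 pi R^2, volume 4/3 pi R^3, genus 0."""
    return Fixture("sphere_atom",
                   atoms=AtomSet([[0.0, 0.0, 0.0]], [radius]),
                   truth={
                       "area": 4.0 * math.pi * radius**2,
                       "volume": 4.0 / 3.0 * math.pi * radius**3,
                       "genus": 0,
                       "cavities": 0,
                   })


def two_sphere_ses_truth(r1, r2, d, probe_radius, n_nodes=100_000):
    """SES area/volume of two overlapping atoms by axisymmetric quadrature.

    The SES of two atoms on the x axis is a surface of revolution; its
    generatrix consists of two sphere arcs joined by the rolling-probe arc.
    Area = integral 2 pi y ds, volume = integral pi y^2 dx along the
    oriented profile.  Requires a regular (non-spindle) saddle.
    """
    rp = probe_radius
    R1, R2 = r1 + rp, r2 + rp
    if d >= R1 + R2:  # no shared probe: two disjoint spheres
        a = 4 * math.pi * (r1 * r1 + r2 * r2)
        v = 4 / 3 * math.pi * (r1**3 + r2**3)
        return a, v
    a_off = (d * d + R1 * R1 - R2 * R2) / (2 * d)
    rho = math.sqrt(R1 * R1 - a_off * a_off)
    pc = np.array([a_off, rho])
    c1 = np.array([0.0, 0.0])
    c2 = np.array([d, 0.0])
    if rho <= rp:
        raise ValueError("spindle configuration: quadrature oracle not valid")
    t1 = pc + rp * (c1 - pc) / R1
    t2 = pc + rp * (c2 - pc) / R2

    def arc(center, radius, phi_from, phi_to, n):
        phi = np.linspace(phi_from, phi_to, n)
        x = center[0] + radius * np.cos(phi)
        y = center[1] + radius * np.sin(phi)
        return x, y

    n = max(n_nodes // 3, 100)
    phi1 = math.atan2(t1[1], t1[0])
    x1, y1 = arc(c1, r1, math.pi, phi1, n)  # left cap, (-r1, 0) -> contact 1
    psi1 = math.atan2(t1[1] - pc[1], t1[0] - pc[0])
    psi2 = math.atan2(t2[1] - pc[1], t2[0] - pc[0])
    # probe arc runs through the downward direction (-pi/2 in pc frame)
    psi1 = psi1 - 2 * math.pi if psi1 > -math.pi / 2 else psi1
    psi2 = psi2 + 2 * math.pi if psi2 < -math.pi / 2 else psi2
    xp, yp = arc(pc, rp, psi1, psi2, n)
    phi2 = math.atan2(t2[1], t2[0] - d)
    x2, y2 = arc(c2, r2, phi2, 0.0, n)  # contact 2 -> right cap (d + r2, 0)

    xs = np.concatenate([x1, xp, x2])
    ys = np.concatenate([y1, yp, y2])
    ys = np.maximum(ys, 0.0)
    dx = np.diff(xs)
    dy = np.diff(ys)
    ds = np.hypot(dx, dy)
    ym = 0.5 * (ys[:-1] + ys[1:])
    area = float(2 * math.pi * np.sum(ym * ds))
    volume = float(math.pi * np.sum(ym**2 * dx))
    return area, volume


def gen_two_atoms(r1=1.0, r2=1.0, d=2.5, probe_radius=1.4,
                  n_nodes=100_000) -> Fixture:
    centers = [[0.0, 0.0, 0.0], [d, 0.0, 0.0]]
    truth = {
        "vdw_area_disjoint": 4 * math.pi * (r1**2 + r2**2),
        "genus": 0,
    }
    if d > r1 + r2 + 2 * probe_radius:
        truth["ses_area"] = truth["vdw_area_disjoint"]
        truth["ses_volume"] = 4 / 3 * math.pi * (r1**3 + r2**3)
    else:
        a, v = two_sphere_ses_truth(r1, r2, d, probe_radius, n_nodes)
        truth["ses_area"] = a
        truth["ses_volume"] = v
    return Fixture("two_atoms", atoms=AtomSet(centers, [r1, r2]), truth=truth,
                   meta={"d": d, "probe_radius": probe_radius})


def gen_linear_chain(n=5, radius=1.0, overlap=0.5) -> Fixture:
    """n collinear atoms with center spacing 2 R (1 - overlap/2)."""
    if not (0 <= overlap < 2):
        raise ValueError("overlap must be in [0, 2)")
    spacing = 2 * radius * (1 - overlap / 2)
    centers = [[i * spacing, 0.0, 0.0] for i in range(n)]
    return Fixture("linear_chain", atoms=AtomSet(centers, [radius] * n),
                   truth={"cavities": 0, "genus": 0},
                   meta={"spacing": spacing})


_PHI = (1 + math.sqrt(5.0)) / 2


def _truncated_icosahedron_vertices():
    base = [(0.0, 1.0, 3 * _PHI), (1.0, 2 + _PHI, 2 * _PHI),
            (_PHI, 2.0, 2 * _PHI + 1)]
    verts = set()
    for b in base:
        for cyc in range(3):
            v = (b[cyc % 3], b[(cyc + 1) % 3], b[(cyc + 2) % 3])
            for sx in (1, -1):
                for sy in (1, -1):
                    for sz in (1, -1):
                        verts.add((sx * v[0], sy * v[1], sz * v[2]))
    return np.array(sorted(verts), float)


def gen_c60(cage_radius=3.55, atom_radius=1.9) -> Fixture:
    """Fullerene cage: 60 co-spherical carbons, one internal SES cavity.

    The co-sphericity is a stress test for the degeneracy-perturbation
    machinery; with a 1.4 A probe the interior void has radius
    cage_radius - atom_radius.
    """
    if cage_radius <= atom_radius:
        raise ValueError("cage radius must exceed the atom radius")
    v = _truncated_icosahedron_vertices()
    v = v / np.linalg.norm(v, axis=1)[:, None] * cage_radius
    assert len(v) == 60
    rv = cage_radius - atom_radius
    return Fixture("c60", atoms=AtomSet(v, [atom_radius] * 60),
                   truth={
                       "cavities": 1,
                       "cavity_volume_ses": 4 / 3 * math.pi * rv**3,
                   },
                   meta={"cage_radius": cage_radius,
                         "atom_radius": atom_radius})


def _fibonacci_sphere(n, radius):
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return radius * np.c_[r * np.cos(phi), r * np.sin(phi), z]


def gen_hollow_shell(n_atoms=150, shell_radius=3.0, atom_radius=1.0,
                     seed=0, n_mc=100_000) -> Fixture:
    """Watertight Fibonacci-lattice shell of atoms enclosing one void.

    The inner-void volume truth comes from Monte-Carlo membership sampling
    (points inside the mid-shell sphere but outside every atom ball); the
    watertightness precondition (arc spacing < 2 atom radii plus a parity
    pre-check of rays through the center) is verified before emission.
    """
    centers = _fibonacci_sphere(n_atoms, shell_radius)
    tree = cKDTree(centers)
    nn, _ = tree.query(centers, k=2)
    max_gap = float(nn[:, 1].max())
    if max_gap >= 2 * atom_radius:
        raise ValueError(
            f"shell not watertight: neighbour spacing {max_gap:.3f} >= "
            f"2 * atom radius {2 * atom_radius:.3f}")
    rng = np.random.default_rng(seed)
    # parity pre-check: radial probes must pierce the covered shell
    dirs = rng.normal(size=(128, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    mid = dirs * shell_radius
    d, _ = tree.query(mid)
    if (d >= atom_radius).any():
        raise ValueError("shell not watertight: radial pinhole detected")
    # Monte-Carlo inner-void volume
    box = shell_radius
    pts = rng.uniform(-box, box, size=(n_mc, 3))
    r = np.linalg.norm(pts, axis=1)
    dist, _ = tree.query(pts)
    void = (r < shell_radius) & (dist > atom_radius)
    void_volume = float(void.mean() * (2 * box) ** 3)
    return Fixture("hollow_shell", atoms=AtomSet(centers, [atom_radius] * n_atoms),
                   truth={"cavities": 1, "void_volume": void_volume},
                   seed=seed,
                   meta={"shell_radius": shell_radius,
                         "atom_radius": atom_radius,
                         "max_neighbour_gap": max_gap})


def gen_random_cluster(n=20, box=6.0, r_range=(1.0, 2.0), seed=0) -> Fixture:
    """Random overlapping cluster for stress tests; deterministic per seed."""
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-box / 2, box / 2, size=(n, 3))
    radii = rng.uniform(r_range[0], r_range[1], size=n)
    return Fixture("random_cluster", atoms=AtomSet(centers, radii), seed=seed,
                   meta={"box": box, "r_range": r_range})


# ---------------------------------------------------------------------------
# mesh fixtures
# ---------------------------------------------------------------------------

def gen_torus_mesh(major_radius=1.85, minor_radius=0.55, nu=48, nv=24) -> Fixture:
    """Closed genus-1 mesh; area -> 4 pi^2 R r, volume -> 2 pi^2 R r^2.

    Default radii are deliberately incommensurate with the usual grid
    spacings so that no vertex ring of the fixture coincides with a lattice
    plane (tangent-ray degeneracies are a property of such alignments, not
    of generic meshes).
    """
    if nu < 3 or nv < 3:
        raise ValueError("torus resolutions must be >= 3")
    R, r = major_radius, minor_radius
    verts = np.empty((nu * nv, 3))
    for i in range(nu):
        u = 2 * math.pi * i / nu
        for j in range(nv):
            v = 2 * math.pi * j / nv
            verts[i * nv + j] = ((R + r * math.cos(v)) * math.cos(u),
                                 (R + r * math.cos(v)) * math.sin(u),
                                 r * math.sin(v))
    faces = []
    for i in range(nu):
        for j in range(nv):
            a = i * nv + j
            b = ((i + 1) % nu) * nv + j
            c = ((i + 1) % nu) * nv + (j + 1) % nv
            d = i * nv + (j + 1) % nv
            faces.append((a, b, c))
            faces.append((a, c, d))
    return Fixture("torus_mesh", mesh_vertices=verts,
                   mesh_faces=np.array(faces, int),
                   truth={
                       "area": 4 * math.pi**2 * R * r,
                       "volume": 2 * math.pi**2 * R * r * r,
                       "genus": 1,
                       "euler_characteristic": 0,
                   },
                   meta={"nu": nu, "nv": nv})


def gen_box_mesh(a=2.0, b=2.0, c=2.0) -> Fixture:
    """Axis-aligned box mesh centered at the origin; exact truths."""
    hx, hy, hz = a / 2, b / 2, c / 2
    verts = np.array([[sx * hx, sy * hy, sz * hz]
                      for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
                     float)
    # index: bit0 = z, bit1 = y, bit2 = x (from the comprehension order)
    quads = [
        (0, 1, 3, 2),  # -x
        (4, 6, 7, 5),  # +x
        (0, 4, 5, 1),  # -y
        (2, 3, 7, 6),  # +y
        (0, 2, 6, 4),  # -z
        (1, 5, 7, 3),  # +z
    ]
    faces = []
    for q in quads:
        faces.append((q[0], q[1], q[2]))
        faces.append((q[0], q[2], q[3]))
    return Fixture("box_mesh", mesh_vertices=verts,
                   mesh_faces=np.array(faces, int),
                   truth={
                       "area": 2 * (a * b + b * c + a * c),
                       "volume": a * b * c,
                       "genus": 0,
                       "euler_characteristic": 2,
                   })
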