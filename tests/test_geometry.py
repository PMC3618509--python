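"""Ray/primitive intersection kernels and the Sturm root isolator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surfray.geometry import (Polynomial, Ray, SpherePatch, TorusPatch,
                              QuadricPatch, TrimPrimitive, point_in_trim,
                              ray_quadric, ray_sphere, ray_torus,
                              ray_triangle, sturm_roots)


# ---------------------------------------------------------------------------
# Sturm roots
# ---------------------------------------------------------------------------

class TestSturmRoots:
    def test_symmetric_quadratic(self):
        assert sturm_roots(Polynomial([-1, 0, 1]), (-2, 2)) == pytest.approx([-1, 1])

    def test_double_root_collapses(self):
        roots = sturm_roots(Polynomial([0.25, -1, 1]), (0, 1))
        assert roots == pytest.approx([0.5], abs=1e-8)

    def test_interval_restriction(self):
        assert sturm_roots(Polynomial([-1, 0, 1]), (0, 2)) == pytest.approx([1])

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            Polynomial([np.nan, 1.0])

    @given(st.lists(st.floats(-3, 3, allow_subnormal=False), min_size=4,
                    max_size=4),
           st.integers(0, 10_000))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_random_quartic_vs_eigenvalue_oracle(self, coeffs, _seed):
        """Roots agree with numpy's companion-matrix eigenvalue solver."""
        from hypothesis import assume
        # keep the coefficients on the Angstrom-ish scale the kernels see
        assume(all(c == 0 or abs(c) >= 1e-6 for c in coeffs))
        p = Polynomial(coeffs + [1.0])  # monic quartic
        ref = np.roots(p.coeffs[::-1])
        # skip near-real complex pairs: both solvers are ambiguous there
        assume(not any(1e-12 < abs(r.imag) < 1e-5 for r in ref))
        mine = sturm_roots(p, (-8.0, 8.0))
        real = sorted(float(r.real) for r in ref
                      if abs(r.imag) <= 1e-12 and -8 <= r.real <= 8)
        collapsed = []
        for r in real:
            if not collapsed or r - collapsed[-1] > 1e-5:
                collapsed.append(r)
        assert len(mine) == len(collapsed)
        for a, b in zip(mine, collapsed):
            assert a == pytest.approx(b, abs=1e-5)


# ---------------------------------------------------------------------------
# sphere / torus / quadric
# ---------------------------------------------------------------------------

class TestRaySphere:
    def test_unit_sphere_axial(self):
        assert ray_sphere([-2, 0, 0], [1, 0, 0], [0, 0, 0], 1.0, 10) == \
            pytest.approx([1.0, 3.0])

    def test_tangent_discarded(self):
        assert ray_sphere([-2, 1, 0], [1, 0, 0], [0, 0, 0], 1.0, 10) == []

    def test_miss(self):
        assert ray_sphere([-2, 2, 0], [1, 0, 0], [0, 0, 0], 1.0, 10) == []

    def test_random_vs_quadratic_formula(self, rng):
        for _ in range(100):
            o = rng.uniform(-4, 4, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            c = rng.uniform(-1, 1, 3)
            r = rng.uniform(0.3, 2.0)
            ts = ray_sphere(o, d, c, r, 20.0)
            oc = o - c
            b = float(oc @ d)
            disc = b * b - float(oc @ oc) + r * r
            if disc > 1e-10:
                expected = sorted(t for t in (-b - math.sqrt(disc),
                                              -b + math.sqrt(disc))
                                  if 0 <= t <= 20)
                assert ts == pytest.approx(expected, abs=1e-12)


class TestRayTorus:
    def test_equatorial_section(self):
        ts = ray_torus([-4, 0, 0], [1, 0, 0], [0, 0, 0], [0, 0, 1], 2.0, 0.5, 10)
        assert ts == pytest.approx([1.5, 2.5, 5.5, 6.5], abs=1e-8)

    def test_symmetry_axis_misses_hole(self):
        assert ray_torus([0, 0, -4], [0, 0, 1], [0, 0, 0], [0, 0, 1],
                         2.0, 0.5, 10) == []

    def test_random_vs_dense_scan(self, rng):
        """Hit count and positions match a sign-change scan of the
        implicit quartic (outer sheet only, R > r)."""
        def implicit(pts, c, a, R, r):
            x = pts - c
            h = x @ a
            xx = (x * x).sum(axis=1)
            s = xx + R * R - r * r
            return s * s - 4 * R * R * (xx - h * h)

        for _ in range(40):
            c = rng.uniform(-1, 1, 3)
            a = rng.normal(size=3)
            a /= np.linalg.norm(a)
            R = rng.uniform(1.0, 3.0)
            r = rng.uniform(0.1, 0.8)
            o = rng.uniform(-6, -4, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ts = np.array(ray_torus(o, d, c, a, R, r, 12.0))
            tt = np.linspace(0, 12, 60001)
            vals = implicit(o[None, :] + tt[:, None] * d[None, :], c, a, R, r)
            sgn = np.sign(vals)
            chg = np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]
            ref = tt[chg] + 0.5 * (tt[1] - tt[0])
            assert len(ts) == len(ref)
            if len(ts):
                assert np.abs(ts - ref).max() < 1e-3

    def test_rigid_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        o = np.array([-4.0, 0.3, 0.1])
        d = np.array([1.0, 0.05, -0.02])
        d /= np.linalg.norm(d)
        base = ray_torus(o, d, [0, 0, 0], [0, 0, 1], 2.0, 0.5, 12.0)
        M = Rotation.from_rotvec([0.4, -0.2, 0.9]).as_matrix()
        shift = np.array([1.0, -2.0, 0.5])
        moved = ray_torus(M @ o + shift, M @ d, M @ np.zeros(3) + shift,
                          M @ np.array([0, 0, 1.0]), 2.0, 0.5, 12.0)
        assert np.allclose(base, moved, atol=1e-9)


class TestRayQuadric:
    def test_sphere_as_quadric_matches_ray_sphere(self, rng):
        A = np.eye(3)
        for _ in range(100):
            o = rng.uniform(-4, 4, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ts_q = ray_quadric(o, d, A, np.zeros(3), -1.0, 20.0)
            ts_s = ray_sphere(o, d, np.zeros(3), 1.0, 20.0)
            assert ts_q == pytest.approx(ts_s, abs=1e-10)

    def test_hyperboloid(self):
        A = np.diag([1.0, 1.0, -1.0])
        ts = ray_quadric([-3, 0, 0], [1, 0, 0], A, np.zeros(3), -1.0, 10.0)
        assert ts == pytest.approx([2.0, 4.0])

    def test_degenerate_restriction_empty(self):
        A = np.diag([0.0, 1.0, 0.0])
        # ray along x at y=0: restriction identically -1: no crossing
        assert ray_quadric([-3, 0, 0], [1, 0, 0], A, np.zeros(3), -0.0, 10.0) == []


class TestRayTriangle:
    def test_centroid_hit(self):
        res = ray_triangle([1 / 3, 1 / 3, 0], [0, 0, 1],
                           np.array([0, 0, 1.0]), np.array([1, 0, 1.0]),
                           np.array([0, 1, 1.0]))
        assert res is not None and res[0] == pytest.approx(1.0)

    def test_parallel_miss(self):
        assert ray_triangle([0, 0, 0], [1, 0, 0],
                            np.array([0, 0, 1.0]), np.array([1, 0, 1.0]),
                            np.array([0, 1, 1.0])) is None

    def test_zero_area_is_miss(self):
        assert ray_triangle([0, 0, 0], [0, 0, 1],
                            np.array([0, 0, 1.0]), np.array([1, 0, 1.0]),
                            np.array([2, 0, 1.0])) is None

    def test_shared_edge_single_hit(self):
        """A ray through a shared edge yields exactly one hit across the
        owning-triangle rule of the mesh surface."""
        from surfray.surfaces.base import MeshSurface
        v = np.array([[0, 0, 1.0], [1, 0, 1.0], [1, 1, 1.0], [0, 1, 1.0],
                      [0.5, 0.5, 0.0]])
        f = np.array([[0, 1, 2], [0, 2, 3],
                      [0, 4, 1], [1, 4, 2], [2, 4, 3], [3, 4, 0]])
        mesh = MeshSurface(v, f)
        # ray through the diagonal edge (0, 2) interior
        hits = mesh.ray_hits([0.5, 0.5, 2.0], [0, 0, -1.0], 5.0)
        top = [h for h in hits if abs(h[0] - 1.0) < 1e-9]
        assert len(top) == 1


# ---------------------------------------------------------------------------
# trims and patch-level properties
# ---------------------------------------------------------------------------

class TestTrims:
    def test_empty_trims_accept(self):
        assert point_in_trim([0, 0, 0], []) is True

    def test_half_space(self):
        trim = TrimPrimitive("half_space", (1.0, 0.0, 0.0), 0.0)
        assert not point_in_trim([1, 0, 0], [trim])
        assert point_in_trim([-1, 0, 0], [trim])

    def test_conjunction_matches_vertex_containment(self, rng):
        """A convex polyhedral trim agrees with a direct half-space check."""
        normals = rng.normal(size=(6, 3))
        normals /= np.linalg.norm(normals, axis=1)[:, None]
        offsets = rng.uniform(0.5, 1.5, 6)
        trims = [TrimPrimitive("half_space", tuple(n), float(o))
                 for n, o in zip(normals, offsets)]
        for _ in range(200):
            p = rng.uniform(-2, 2, 3)
            direct = bool((normals @ p <= offsets + 1e-9).all())
            assert point_in_trim(p, trims) == direct

    def test_sphere_trims(self):
        inside = TrimPrimitive("sphere_inside", (0, 0, 0), 1.0)
        outside = TrimPrimitive("sphere_outside", (0, 0, 0), 1.0)
        assert point_in_trim([0.5, 0, 0], [inside])
        assert not point_in_trim([1.5, 0, 0], [inside])
        assert point_in_trim([1.5, 0, 0], [outside])


class TestParityOfClosedPrimitives:
    """Full lines crossing closed primitives make an even number of hits."""

    @pytest.mark.parametrize("kind", ["sphere", "torus", "quadric"])
    def test_even_crossings(self, kind, rng):
        for _ in range(60):
            o = rng.uniform(-6, -4, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            if kind == "sphere":
                ts = ray_sphere(o, d, rng.uniform(-1, 1, 3),
                                rng.uniform(0.3, 1.5), 20.0)
            elif kind == "torus":
                a = rng.normal(size=3)
                a /= np.linalg.norm(a)
                ts = ray_torus(o, d, rng.uniform(-1, 1, 3), a,
                               rng.uniform(1.0, 2.5), rng.uniform(0.1, 0.7),
                               20.0)
            else:
                ts = ray_quadric(o, d, np.eye(3), rng.uniform(-1, 1, 3),
                                 -rng.uniform(0.3, 2.0), 20.0)
            assert len(ts) % 2 == 0

    def test_ray_rejects_bad_input(self):
        with pytest.raises(ValueError):
            Ray([0, 0, 0], [0, 0, 0], 1.0)
        with pytest.raises(ValueError):
            Ray([0, 0, 0], [1, 0, 0], -1.0)
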