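"""Grid construction, acceleration structures, and the parity protocol."""

import numpy as np
import pytest

from surfray.fixtures import gen_box_mesh, gen_sphere_atom
from surfray.raycast import (build_accel, cast_grid_rays, cast_ray_checked,
                             cast_edge_rays, classify_points, make_grid)
from surfray.surfaces import AtomSet, SESParams, build_vdw
from surfray.surfaces.base import MeshSurface


class TestMakeGrid:
    def test_spec_arithmetic(self):
        atoms = AtomSet([[0, 0, 0]], [1.0])
        grid = make_grid(atoms, scale=2, perfil=50)
        assert grid.spacing == 0.5
        assert np.allclose(grid.span(), 4.0)
        assert all(d % 2 == 1 for d in grid.dims)

    def test_perfil_margin(self):
        atoms = AtomSet([[0, 0, 0]], [1.0])
        grid = make_grid(atoms, scale=4, perfil=90)
        lo, hi = atoms.bbox()
        span = grid.span()[0]
        margin = min(lo[0] - grid.origin[0], grid.origin[0] + span - hi[0])
        assert margin >= 0.05 * span / 2  # >= 5% per side

    def test_atoms_strictly_inside(self, rng):
        for _ in range(20):
            centers = rng.uniform(-4, 4, size=(8, 3))
            radii = rng.uniform(0.8, 2.0, 8)
            atoms = AtomSet(centers, radii)
            grid = make_grid(atoms, 2, 80, margin=1.4)
            lo, hi = atoms.bbox(inflate=1.4)
            assert grid.contains_box(lo, hi)

    def test_grid_size_cap(self):
        atoms = AtomSet([[0, 0, 0]], [1.0])
        with pytest.raises(ValueError, match="lower the scale"):
            make_grid(atoms, scale=2000, perfil=50)

    def test_bad_params(self):
        atoms = AtomSet([[0, 0, 0]], [1.0])
        with pytest.raises(ValueError):
            make_grid(atoms, scale=0)
        with pytest.raises(ValueError):
            make_grid(atoms, perfil=120)


class TestAccel2D:
    def test_brute_force_equivalence(self, two_atom_fixture, two_atom_ses, rng):
        """Hits with acceleration equal hits without, on random grid rays."""
        grid = make_grid(two_atom_fixture.atoms, 4, 90)
        accel = build_accel(two_atom_ses, grid, 0)
        o_x = grid.origin[0] - grid.spacing
        t_max = grid.span()[0] + 2 * grid.spacing
        d = np.array([1.0, 0, 0])
        for _ in range(100):
            y = rng.uniform(grid.origin[1], grid.origin[1] + grid.span()[1])
            z = rng.uniform(grid.origin[2], grid.origin[2] + grid.span()[2])
            o = np.array([o_x, y, z])
            fast = two_atom_ses.ray_hits(o, d, t_max,
                                         candidates=accel.candidates(y, z))
            slow = two_atom_ses.ray_hits(o, d, t_max, candidates=None)
            assert [h[0] for h in fast] == pytest.approx([h[0] for h in slow])

    def test_outside_patch_listed_nowhere(self):
        atoms = AtomSet([[0, 0, 0]], [1.0])
        surf = build_vdw(atoms, SESParams(seed=1))
        grid = make_grid(atoms, 2, 50)
        accel = build_accel(surf, grid, 2)
        # cells far in the corner see no patch
        assert accel.candidates(grid.origin[0] + 0.01,
                                grid.origin[1] + 0.01) == []


def _sliver_box_mesh():
    """Box mesh with a sliver pair: a vertex inserted 1e-9 off an edge."""
    bx = gen_box_mesh(2.0, 2.0, 2.0)
    V = [tuple(v) for v in bx.mesh_vertices]
    F = [tuple(t) for t in bx.mesh_faces]
    a, b, c = F[0]
    other = next(i for i, t in enumerate(F) if i != 0 and a in t and b in t)
    oc = next(v for v in F[other] if v not in (a, b))
    mid = 0.5 * (bx.mesh_vertices[a] + bx.mesh_vertices[b]) + \
        np.array([0, 1e-9, 1e-9])
    V.append(tuple(mid))
    m = len(V) - 1
    F[0] = (a, m, c)
    F.append((m, b, c))
    t = list(F[other])
    ia = t.index(a)
    if t[(ia + 1) % 3] == b:
        F[other] = (a, m, oc)
        F.append((m, b, oc))
    else:
        F[other] = (b, m, oc)
        F.append((m, a, oc))
    return MeshSurface(np.array(V), np.array(F, int))


class TestParityProtocol:
    def test_sphere_two_hits_no_retry(self, sphere_fixture):
        surf = build_vdw(sphere_fixture.atoms, SESParams(seed=1))
        from surfray.raycast import CastReport
        report = CastReport()
        hits = cast_ray_checked(surf, [-3, 0.05, 0.08], [1, 0, 0], 6.0,
                                report=report)
        assert len(hits) == 2
        assert report.parity_retries == 0

    def test_tangent_ray_even(self, sphere_fixture):
        surf = build_vdw(sphere_fixture.atoms,
                         SESParams(seed=1, perturbation=0))
        hits = cast_ray_checked(surf, [-3, 1.0, 0.0], [1, 0, 0], 6.0)
        assert hits is not None and len(hits) % 2 == 0

    def test_degenerate_sliver_mesh_all_even(self):
        """Sliver/coplanar triangles: parity restored for every ray by the
        jitter protocol; the volume stays exact."""
        mesh = _sliver_box_mesh()
        grid = make_grid(mesh, 4, 50)
        accels = [build_accel(mesh, grid, a) for a in range(3)]
        status, intervals, report = cast_grid_rays(mesh, grid, accels, seed=1)
        assert report.odd_after_protocol == 0
        assert report.fallbacks == 0
        from surfray.volumetrics import volume_from_intervals
        vol = volume_from_intervals(intervals, grid)
        assert vol.averaged == pytest.approx(8.0, rel=1e-9)

    def test_empty_surface_everything_outside(self):
        from surfray.surfaces.base import PatchSet
        empty = PatchSet([])
        grid = make_grid((np.array([-1.0] * 3), np.array([1.0] * 3)), 2, 50)
        status, intervals, report = cast_grid_rays(empty, grid, None, seed=0)
        assert not status.centers.any()


class TestGridRays:
    def test_sphere_statuses(self, sphere_fixture):
        surf = build_vdw(sphere_fixture.atoms, SESParams(seed=1))
        grid = make_grid(sphere_fixture.atoms, 4, 50)
        accels = [build_accel(surf, grid, a) for a in range(3)]
        status, intervals, report = cast_grid_rays(surf, grid, accels, seed=1)
        nc = grid.n_cubes
        centre = tuple(n // 2 for n in nc)
        assert status.centers[centre]
        assert not status.centers[0, 0, 0]

    def test_inside_fraction_matches_volume(self, sphere_fixture):
        surf = build_vdw(sphere_fixture.atoms, SESParams(seed=1))
        grid = make_grid(sphere_fixture.atoms, 8, 50)
        accels = [build_accel(surf, grid, a) for a in range(3)]
        status, _, _ = cast_grid_rays(surf, grid, accels, seed=1)
        frac = status.centers.mean()
        expect = (4 / 3 * np.pi) / grid.span().prod()
        assert frac == pytest.approx(expect, rel=0.02)

    def test_determinism(self, two_atom_ses, two_atom_fixture):
        grid = make_grid(two_atom_fixture.atoms, 3, 90)
        accels = [build_accel(two_atom_ses, grid, a) for a in range(3)]
        s1, i1, _ = cast_grid_rays(two_atom_ses, grid, accels, seed=9)
        s2, i2, _ = cast_grid_rays(two_atom_ses, grid, accels, seed=9)
        assert np.array_equal(s1.centers, s2.centers)
        for a in range(3):
            assert np.array_equal(i1[a], i2[a])
            assert np.array_equal(s1.faces[a], s2.faces[a])


class TestEdgeRays:
    def test_hits_lie_on_sphere(self, sphere_fixture):
        surf = build_vdw(sphere_fixture.atoms,
                         SESParams(seed=1, perturbation=0))
        grid = make_grid(sphere_fixture.atoms, 4, 60)
        accels = [build_accel(surf, grid, a) for a in range(3)]
        vstat, ehits, rep = cast_edge_rays(surf, grid, accels, seed=1)
        assert len(ehits) > 0
        for key, hits in ehits.hits.items():
            for p, n in hits:
                assert abs(np.linalg.norm(p) - 1.0) < 1e-9

    def test_edge_parity_matches_vertex_statuses(self, two_atom_cast):
        """An edge whose endpoints share a status holds an even number of
        hits; differing statuses an odd number."""
        status = two_atom_cast["status"]
        ehits = two_atom_cast["edge_hits"]
        v = status.vertices
        mismatches = 0
        for (axis, i, j, k), hits in ehits.hits.items():
            step = [0, 0, 0]
            step[axis] = 1
            same = v[i, j, k] == v[i + step[0], j + step[1], k + step[2]]
            if same != (len(hits) % 2 == 0):
                mismatches += 1
        assert mismatches == 0


class TestClassifyPoints:
    def test_sphere_membership(self, sphere_fixture, rng):
        surf = build_vdw(sphere_fixture.atoms,
                         SESParams(seed=1, perturbation=0))
        pts = rng.uniform(-1.5, 1.5, size=(500, 3))
        r = np.linalg.norm(pts, axis=1)
        keep = np.abs(r - 1.0) > 1e-3
        inside = classify_points(surf, pts)
        assert (inside[keep] == (r[keep] < 1.0)).all()
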