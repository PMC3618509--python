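"""Marching cubes (analytic and bisecting), smoothing, area estimators."""

import math

import numpy as np
import pytest

from surfray.raycast import EdgeHits, build_accel, cast_edge_rays, \
    cast_grid_rays, make_grid
from surfray.surfaces import SESParams, build_vdw
from surfray.triangulate import (TABLES, incident_ray_area, laplacian_smooth,
                                 mc_analytic, mc_bisecting, mesh_area)


class TestMCTables:
    def test_empty_and_full_cases(self):
        assert TABLES[0] == []
        assert TABLES[255] == []

    def test_face_pairing_depends_only_on_face_state(self):
        """Crack-free requirement: the cut-edge pairing on any cube face is
        a function of that face's 4 corner states alone, so two cubes
        sharing the face always agree."""
        from surfray.triangulate import _FACES, _face_edges

        def boundary_segments(tris):
            seen = {}
            for t in tris:
                for e in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                    key = (min(e), max(e))
                    seen[key] = seen.get(key, 0) + 1
            return {e for e, n in seen.items() if n == 1}

        table = {}
        for case in range(256):
            segs = boundary_segments(TABLES[case])
            for face in _FACES:
                fe = set(_face_edges(face))
                state = tuple(bool(case & (1 << v)) for v in face)
                pairing = frozenset(s for s in segs
                                    if s[0] in fe and s[1] in fe)
                key = (tuple(sorted(fe)), state)
                assert table.setdefault(key, pairing) == pairing

    def test_single_corner_is_one_triangle(self):
        assert len(TABLES[1]) == 1

    def test_closed_on_random_binary_fields(self, rng):
        """Any parity-consistent vertex field triangulates to a closed
        manifold, however noisy (the crack-free table property)."""
        from surfray.raycast import Grid3D
        for _ in range(15):
            field = rng.uniform(size=(6, 6, 6)) < 0.4
            field[0] = field[-1] = False
            field[:, 0] = field[:, -1] = False
            field[:, :, 0] = field[:, :, -1] = False
            grid = Grid3D(np.zeros(3), 1.0, (6, 6, 6), 1.0, 90.0)
            mesh = mc_analytic(field, EdgeHits(), grid)
            assert mesh.is_closed()

    def test_area_matches_reference_mc_on_smooth_field(self, rng):
        """On a smooth (sphere) binary field, where ambiguous faces are
        rare, area agrees with scikit-image's marching cubes on the same
        vertex classification (vertices coincide at edge midpoints)."""
        from skimage import measure
        from surfray.raycast import Grid3D
        n = 17
        xs = np.arange(n) - (n - 1) / 2 + 0.1317
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        field = (np.sqrt(X**2 + Y**2 + Z**2) < 6.0)
        grid = Grid3D(np.zeros(3), 1.0, (n, n, n), 1.0, 90.0)
        mesh = mc_analytic(field, EdgeHits(), grid)
        assert mesh.is_closed()
        ref_v, ref_f, _, _ = measure.marching_cubes(field.astype(float), 0.5)
        ref_area = 0.5 * np.linalg.norm(
            np.cross(ref_v[ref_f[:, 1]] - ref_v[ref_f[:, 0]],
                     ref_v[ref_f[:, 2]] - ref_v[ref_f[:, 0]]), axis=1).sum()
        assert mesh.area() == pytest.approx(ref_area, rel=0.02)


@pytest.fixture(scope="module")
def sphere_cast():
    from surfray.fixtures import gen_sphere_atom
    atoms = gen_sphere_atom(1.0).atoms
    surf = build_vdw(atoms, SESParams(seed=1))
    grid = make_grid(atoms, 4, 60)
    accels = [build_accel(surf, grid, a) for a in range(3)]
    status, intervals, _, cos_hits = cast_grid_rays(surf, grid, accels,
                                                    seed=1, keep_hits=True)
    vstat, ehits, _ = cast_edge_rays(surf, grid, accels, seed=1)
    status.vertices = vstat
    return surf, grid, status, ehits, cos_hits


class TestMCAnalytic:
    def test_vertices_on_surface(self, sphere_cast):
        surf, grid, status, ehits, _ = sphere_cast
        mesh = mc_analytic(status.vertices, ehits, grid)
        resid = max(surf.implicit_residual(v) for v in mesh.vertices)
        assert resid < 1e-9
        assert mesh.midpoint_fallbacks == 0

    def test_closed_genus_zero(self, sphere_cast):
        surf, grid, status, ehits, _ = sphere_cast
        mesh = mc_analytic(status.vertices, ehits, grid)
        assert mesh.is_closed()
        assert mesh.euler_characteristic() == 2

    def test_outward_orientation(self, sphere_cast):
        surf, grid, status, ehits, _ = sphere_cast
        mesh = mc_analytic(status.vertices, ehits, grid)
        assert mesh.enclosed_volume() > 0
        normals = mesh.triangle_normals()
        centers = mesh.vertices[mesh.faces].mean(axis=1)
        outward = np.einsum("ij,ij->i", normals, centers)
        assert (outward > 0).all()

    def test_fully_inside_region_emits_nothing(self):
        from surfray.raycast import Grid3D
        grid = Grid3D(np.zeros(3), 1.0, (4, 4, 4), 1.0, 90.0)
        mesh = mc_analytic(np.ones((4, 4, 4), bool), EdgeHits(), grid)
        assert len(mesh.faces) == 0

    def test_grid_consistency(self, sphere_cast):
        """No triangle leaves its owning cube (up to tolerance)."""
        surf, grid, status, ehits, _ = sphere_cast
        mesh = mc_analytic(status.vertices, ehits, grid)
        h = grid.spacing
        for tri, cube in zip(mesh.faces, mesh.owners):
            lo = grid.origin + h * cube
            for v in mesh.vertices[tri]:
                assert (v >= lo - 1e-9).all() and (v <= lo + h + 1e-9).all()


class TestMCBisecting:
    def test_runs_without_edge_hits(self, sphere_cast):
        _, grid, status, _, _ = sphere_cast
        mesh = mc_bisecting(status, grid)
        assert len(mesh.faces) > 0
        assert mesh.is_closed()

    def test_same_topology_as_analytic(self, sphere_cast):
        _, grid, status, ehits, _ = sphere_cast
        ma = mc_analytic(status.vertices, ehits, grid)
        mb = mc_bisecting(status, grid)
        assert mb.euler_characteristic() == ma.euler_characteristic() == 2

    def test_area_coarser_but_close(self, sphere_cast):
        _, grid, status, _, _ = sphere_cast
        mb = mc_bisecting(status, grid)
        assert mb.area() == pytest.approx(4 * math.pi, rel=0.05)


class TestSmoothing:
    def test_zero_iterations_identity(self, sphere_cast):
        _, grid, status, ehits, _ = sphere_cast
        mesh = mc_analytic(status.vertices, ehits, grid)
        out = laplacian_smooth(mesh, 0, 0.5)
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_area_decreases_monotonically(self, sphere_cast):
        _, grid, status, ehits, _ = sphere_cast
        mesh = mc_analytic(status.vertices, ehits, grid)
        areas = [laplacian_smooth(mesh, k, 0.5).area() for k in range(4)]
        assert all(a1 > a2 for a1, a2 in zip(areas, areas[1:]))

    def test_topology_preserved(self, sphere_cast):
        _, grid, status, ehits, _ = sphere_cast
        mesh = mc_analytic(status.vertices, ehits, grid)
        out = laplacian_smooth(mesh, 2, 0.5)
        assert len(out.vertices) == len(mesh.vertices)
        assert np.array_equal(out.faces, mesh.faces)


class TestMeshArea:
    def test_unit_right_triangle(self):
        from surfray.triangulate import TriMesh
        mesh = TriMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]),
                       np.array([[0, 1, 2]]), np.array([[0, 0, 0]]))
        total, per_cube = mesh_area(mesh)
        assert total == pytest.approx(0.5)

    def test_per_cube_sums_to_total(self, sphere_cast):
        surf, grid, status, ehits, _ = sphere_cast
        mesh = mc_analytic(status.vertices, ehits, grid)
        total, per_cube = mesh_area(mesh)
        assert sum(per_cube.values()) == pytest.approx(total, rel=1e-12)

    def test_sphere_area(self, sphere_cast):
        surf, grid, status, ehits, _ = sphere_cast
        mesh = mc_analytic(status.vertices, ehits, grid)
        assert mesh.area() == pytest.approx(4 * math.pi, rel=0.02)


class TestIncidentRayArea:
    def test_axis_aligned_face_exact(self):
        """A square face hit square-on: cos = 1, the estimator returns the
        sampled plane area exactly."""
        from surfray.fixtures import gen_box_mesh
        mesh = gen_box_mesh(2.0, 2.0, 2.0).mesh_surface()
        grid = make_grid(mesh, 4, 50)
        accels = [build_accel(mesh, grid, a) for a in range(3)]
        _, _, _, cos_hits = cast_grid_rays(mesh, grid, accels, seed=1,
                                           keep_hits=True)
        per_axis, averaged = incident_ray_area(grid=grid, cos_hits=cos_hits)
        # every hit is square-on; 2 faces of 4 A^2 each per axis
        for a in range(3):
            assert per_axis[a] == pytest.approx(8.0, rel=1e-9)

    def test_sphere_single_axis_scale8(self):
        from surfray.fixtures import gen_sphere_atom
        atoms = gen_sphere_atom(1.0).atoms
        surf = build_vdw(atoms, SESParams(seed=1))
        grid = make_grid(atoms, 8, 60)
        accels = [build_accel(surf, grid, a) for a in range(3)]
        _, _, _, cos_hits = cast_grid_rays(surf, grid, accels, seed=1,
                                           keep_hits=True)
        per_axis, averaged = incident_ray_area(grid=grid, cos_hits=cos_hits,
                                               clamp=0.1)
        assert per_axis[0] == pytest.approx(4 * math.pi, rel=0.05)
        assert averaged == pytest.approx(4 * math.pi, rel=0.05)


class TestExport:
    def test_roundtrip_counts(self, sphere_cast, tmp_path):
        from surfray.triangulate import export_mesh
        from surfray.surfaces import load_mesh_surface
        surf, grid, status, ehits, _ = sphere_cast
        mesh = mc_analytic(status.vertices, ehits, grid)
        path = tmp_path / "s.off"
        export_mesh(mesh, path)
        back = load_mesh_surface(path)
        assert len(back.vertices) == len(mesh.vertices)
        assert len(back.faces) == len(mesh.faces)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-9)
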