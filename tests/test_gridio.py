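"""Grid coloring, boundary-point discovery, and surface projection."""

import math

import numpy as np
import pytest

from surfray.gridio import (Accel3D, BoundaryPoint, color_grid,
                            find_boundary_points, project_points)
from surfray.raycast import build_accel, cast_grid_rays, make_grid
from surfray.surfaces import AtomSet, SESParams, build_vdw
from surfray.geometry import SpherePatch, TorusPatch


@pytest.fixture(scope="module")
def sphere_colormap():
    atoms = AtomSet([[0, 0, 0]], [1.0])
    surf = build_vdw(atoms, SESParams(seed=1))
    grid = make_grid(atoms, 4, 60)
    accels = [build_accel(surf, grid, a) for a in range(3)]
    status, _, _ = cast_grid_rays(surf, grid, accels, seed=1)
    return surf, grid, status


class TestColorGrid:
    def test_keep_cavities_is_identity(self, sphere_colormap):
        surf, grid, status = sphere_colormap
        before = status.centers.copy()
        cmap = color_grid(status, "keep-cavities")
        assert np.array_equal(cmap.centers, before)

    def test_deep_face_centers_inside(self, sphere_colormap):
        surf, grid, status = sphere_colormap
        cmap = color_grid(status)
        h = grid.spacing
        fx = cmap.faces[0]
        for i in range(fx.shape[0]):
            for j in range(fx.shape[1]):
                for k in range(fx.shape[2]):
                    p = np.array([grid.vertex_coord(0, i),
                                  grid.center_coord(1, j),
                                  grid.center_coord(2, k)])
                    if np.linalg.norm(p) < 1.0 - h:
                        assert fx[i, j, k]

    def test_fill_all_on_hollow_shell(self):
        from surfray.fixtures import gen_hollow_shell
        fx = gen_hollow_shell(seed=0, n_mc=1000)
        surf = build_vdw(fx.atoms, SESParams(seed=1))
        grid = make_grid(fx.atoms, 2, 90)
        accels = [build_accel(surf, grid, a) for a in range(3)]
        status, _, _ = cast_grid_rays(surf, grid, accels, seed=1)
        cmap = color_grid(status, "fill-all")
        # no outside label strictly interior to the shell
        from scipy import ndimage
        outside = ~cmap.centers
        labels, n = ndimage.label(outside)
        border = set()
        for axis in range(3):
            for sl in (0, -1):
                idx = [slice(None)] * 3
                idx[axis] = sl
                border.update(np.unique(labels[tuple(idx)]))
        assert set(np.unique(labels)) - {0} <= border

    def test_unknown_policy(self, sphere_colormap):
        _, _, status = sphere_colormap
        with pytest.raises(ValueError):
            color_grid(status, "bogus")

    def test_dump_text(self, sphere_colormap, tmp_path):
        _, _, status = sphere_colormap
        cmap = color_grid(status)
        cmap.dump_text(tmp_path / "cm")
        head = (tmp_path / "cm.centers.txt").read_text().split("\n")[0]
        assert len(head.split()) == 7  # dims, origin, h


class TestFindBoundaryPoints:
    def test_all_inside_empty(self, sphere_colormap):
        _, grid, status = sphere_colormap
        import copy
        st = copy.deepcopy(status)
        st.centers[:] = True
        for a in range(3):
            st.faces[a][:] = True
        assert find_boundary_points(color_grid(st)) == []

    def test_count_matches_direct_scan(self, sphere_colormap):
        surf, grid, status = sphere_colormap
        cmap = color_grid(status)
        bps = find_boundary_points(cmap)
        count = 0
        nc = grid.n_cubes
        for i in range(nc[0]):
            for j in range(nc[1]):
                for k in range(nc[2]):
                    faces = cmap.cube_face_statuses(i, j, k)
                    if any(faces) and not all(faces):
                        count += 1
        assert len(bps) == count > 0

    def test_lexicographic_order(self, sphere_colormap):
        surf, grid, status = sphere_colormap
        bps = find_boundary_points(color_grid(status))
        cubes = [bp.cube for bp in bps]
        assert cubes == sorted(cubes)


class TestProjection:
    def test_sphere_closed_form(self):
        patch = SpherePatch(np.zeros(3), 1.0)
        from surfray.surfaces.base import PatchSet
        ps = PatchSet([patch])
        pts = [np.array([0.0, 0, 1.7]), np.array([0.3, -0.2, 0.1])]
        out = project_points(pts, ps)
        for bp, x in zip(out, pts):
            assert np.linalg.norm(bp.projection) == pytest.approx(1.0, abs=1e-9)
            assert bp.distance == pytest.approx(abs(np.linalg.norm(x) - 1.0),
                                                abs=1e-9)

    def test_triangle_perpendicular_foot(self):
        from surfray.fixtures import gen_box_mesh
        mesh = gen_box_mesh(2.0, 2.0, 2.0).mesh_surface()
        out = project_points([np.array([0.2, 0.3, 1.9])], mesh)
        assert out[0].projection == pytest.approx([0.2, 0.3, 1.0], abs=1e-9)

    def test_boundary_points_land_on_surface(self, sphere_colormap):
        surf, grid, status = sphere_colormap
        bps = find_boundary_points(color_grid(status))
        out = project_points(bps[:30], surf)
        half_diag = grid.spacing * math.sqrt(3) / 2
        for bp in out:
            assert surf.implicit_residual(bp.projection) < 1e-6
            assert bp.distance <= half_diag + 1e-9

    def test_torus_vs_parameter_sweep(self, two_atom_ses, rng):
        tor = next(p for p in two_atom_ses.patches
                   if isinstance(p, TorusPatch))
        a = tor.axis
        e1 = np.cross(a, [1, 0, 0.0]) if abs(a[0]) < 0.9 else \
            np.cross(a, [0, 1, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        from surfray.gridio import _project_patch
        for _ in range(6):
            x = rng.uniform(-1.0, 3.0, 3)
            p = _project_patch(x, tor)
            if p is None:
                continue
            best = math.inf
            for u in np.linspace(0, 2 * math.pi, 120, endpoint=False):
                radial = math.cos(u) * e1 + math.sin(u) * e2
                q = tor.center + tor.major_radius * radial
                for v in np.linspace(0, 2 * math.pi, 84, endpoint=False):
                    pt = q + tor.minor_radius * (math.cos(v) * radial
                                                 + math.sin(v) * a)
                    if tor.contains_point(pt):
                        best = min(best, float(np.linalg.norm(pt - x)))
            # the projection is never worse than the dense sweep
            assert float(np.linalg.norm(p - x)) <= best + 1e-4


class TestAccel3D:
    def test_projection_matches_brute_force(self, two_atom_ses, rng):
        """Shell-accelerated projection finds the same nearest point as an
        exhaustive scan over every patch."""
        from surfray.gridio import _project_patch
        lo, hi = two_atom_ses.bbox()
        pts = [rng.uniform(lo - 0.5, hi + 0.5) for _ in range(15)]
        out = project_points(pts, two_atom_ses, accel_cell=0.5)
        for bp, x in zip(out, pts):
            best = math.inf
            for patch in two_atom_ses.patches:
                p = _project_patch(x, patch)
                if p is not None:
                    best = min(best, float(np.linalg.norm(p - x)))
            assert bp.distance == pytest.approx(best, abs=1e-9)
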