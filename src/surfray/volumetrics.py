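"""Volume estimation, floodfill cavity detection, and conditional filling.

The volume integral of the indicator function (1 inside, 0 outside) is
discretized per casting axis as V = h^2 * sum over rays of the inside
interval lengths.  Cavities are connected outside-status components of the
cube-center lattice (6-connectivity) not touching the grid boundary; those
below a volume threshold are toggled to inside, and the face/vertex/edge
records around filled voxels are re-derived so the triangulation sees a
consistent field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raycast import EdgeHits, Grid3D, StatusGrid

__all__ = [
    "Cavity", "VolumeEstimate", "volume_from_intervals", "detect_cavities",
    "fill_cavities", "WATER_VOLUME",
]

#: default fill threshold: the volume of a 1.4 Angstrom water-probe sphere
WATER_VOLUME = 4.0 * math.pi / 3.0 * 1.4**3  # ~11.49 A^3


@dataclass
class Cavity:
    id: int
    voxels: np.ndarray  # (n, 3) cube-center lattice indices
    volume: float  # A^3

    @property
    def seed_voxel(self):
        return tuple(int(v) for v in self.voxels[0])


@dataclass
class VolumeEstimate:
    """Per-axis ray-casting volume estimates and their mean."""

    per_axis: dict

    @property
    def averaged(self):
        vals = list(self.per_axis.values())
        return float(np.mean(vals))

    def __getitem__(self, axis):
        return self.per_axis[axis]


def volume_from_intervals(intervals, grid: Grid3D, axis=None) -> VolumeEstimate:
    """V = h^2 * sum_rays sum_intervals (t_exit - t_entry), per axis."""
    h2 = grid.spacing**2
    if axis is not None:
        return VolumeEstimate({axis: h2 * float(np.sum(intervals[axis]))})
    return VolumeEstimate({a: h2 * float(np.sum(v)) for a, v in intervals.items()})


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # face adjacency


def detect_cavities(status: StatusGrid):
    """Label outside components: the boundary-touching one is the exterior,
    every other is a cavity with volume = voxel count * h^3."""
    outside = ~status.centers
    labels, n = ndimage.label(outside, structure=_STRUCT6)
    boundary_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            idx = [slice(None)] * 3
            idx[axis] = sl
            boundary_labels.update(np.unique(labels[tuple(idx)]))
    boundary_labels.discard(0)
    if not boundary_labels:
        raise ValueError("no outside voxels on the grid boundary: the grid "
                         "does not enclose the system")
    h3 = status.grid.spacing**3
    exterior = np.isin(labels, sorted(boundary_labels))
    cavities = []
    cid = 0
    for lab in range(1, n + 1):
        if lab in boundary_labels:
            continue
        vox = np.argwhere(labels == lab)
        cavities.append(Cavity(cid, vox, len(vox) * h3))
        cid += 1
    status.cavity_labels = labels
    return exterior & outside, cavities


def fill_cavities(status: StatusGrid, cavities, min_volume=WATER_VOLUME,
                  fill_all=False, edge_hits: EdgeHits = None):
    """Toggle below-threshold cavities to inside and repair the local field.

    Face centers, cube vertices, and stored edge hits within one cell of a
    filled voxel are re-derived so Marching Cubes sees a consistent field:
    edges whose two vertices became inside drop their hits; mixed edges keep
    the hit nearest the surviving outside vertex.  Returns a repair log.
    """
    log = {"filled": [], "faces_toggled": 0, "vertices_toggled": 0,
           "edges_cleared": 0}
    filled_mask = np.zeros_like(status.centers)
    for cav in cavities:
        if fill_all or cav.volume < min_volume:
            filled_mask[tuple(cav.voxels.T)] = True
            log["filled"].append(cav.id)
    if not filled_mask.any():
        return status, log
    status.centers = status.centers | filled_mask

    # halo of affected lattice sites: filled voxels dilated by one cube
    halo = ndimage.binary_dilation(filled_mask, structure=np.ones((3, 3, 3)))

    # faces: a face center between two inside cubes is inside
    if status.faces is not None:
        for axis in range(3):
            f = status.faces[axis]
            inner = [slice(None)] * 3
            lo_sl = [slice(None)] * 3
            hi_sl = [slice(None)] * 3
            inner[axis] = slice(1, -1)
            lo_sl[axis] = slice(None, -1)
            hi_sl[axis] = slice(1, None)
            both_in = status.centers[tuple(lo_sl)] & status.centers[tuple(hi_sl)]
            touched = halo[tuple(lo_sl)] | halo[tuple(hi_sl)]
            target = f[tuple(inner)]
            n_new = int((both_in & touched & ~target).sum())
            log["faces_toggled"] += n_new
            f[tuple(inner)] = target | (both_in & touched)

    # vertices: a vertex surrounded by 8 inside cubes is inside
    if status.vertices is not None:
        c = status.centers
        pad = np.zeros(tuple(s + 2 for s in c.shape), bool)
        pad[1:-1, 1:-1, 1:-1] = c
        all_in = np.ones(status.vertices.shape, bool)
        hpad = np.zeros_like(pad)
        hpad[1:-1, 1:-1, 1:-1] = halo
        touched = np.zeros(status.vertices.shape, bool)
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    blk = pad[dx:dx + c.shape[0] + 1,
                              dy:dy + c.shape[1] + 1,
                              dz:dz + c.shape[2] + 1]
                    all_in &= blk
                    touched |= hpad[dx:dx + c.shape[0] + 1,
                                    dy:dy + c.shape[1] + 1,
                                    dz:dz + c.shape[2] + 1]
        newly = all_in & touched & ~status.vertices
        log["vertices_toggled"] = int(newly.sum())
        status.vertices = status.vertices | newly

        # edges: drop hits whose two endpoint vertices are now both inside
        if edge_hits is not None:
            v = status.vertices
            stale = []
            for (axis, i, j, k) in list(edge_hits.hits.keys()):
                step = [0, 0, 0]
                step[axis] = 1
                if v[i, j, k] and v[i + step[0], j + step[1], k + step[2]]:
                    stale.append((axis, (i, j, k)))
            for axis, key in stale:
                edge_hits.remove_edge(axis, key)
            log["edges_cleared"] = len(stale)
    return status, log


def cavity_report_tsv(cavities, path):
    """TSV export: id, voxel_count, volume_A3, seed voxel (i, j, k)."""
    with open(path, "w") as fh:
        fh.write("id\tvoxel_count\tvolume_A3\ti\tj\tk\n")
        for c in cavities:
            i, j, k = c.seed_voxel
            fh.write(f"{c.id}\t{len(c.voxels)}\t{c.volume:.4f}\t{i}\t{j}\t{k}\n")
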