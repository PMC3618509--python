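"""End-to-end pipeline: build -> ray-cast -> cavities -> triangulate.

The four stages mirror the framework flowchart: (1) the surface is computed
or loaded, (2) it is ray-cast on the cubic grid, (3) cavities are detected
and conditionally filled, (4) the surface is triangulated grid-consistently
and measured.  ``run`` drives everything from a RunConfig and returns the
stats dictionary the CLI serializes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import raycast, triangulate, volumetrics, gridio
from .surfaces import (GaussianParams, SESParams, SkinParams, build_gaussian,
                       build_sas, build_ses, build_skin, build_vdw,
                       load_mesh_surface, read_atoms)

log = logging.getLogger("surfray")

SURFACE_KINDS = ("ses", "vdw", "sas", "skin", "gaussian", "mesh")
CAVITY_POLICIES = ("keep", "fill_below", "fill_all")
MC_VARIANTS = ("analytic", "bisecting")


@dataclass
class RunConfig:
    """Run parameters; defaults follow the framework's standard settings
    (scale 2 grids/A, perfil 90, probe 1.4 A, shrink 0.45, blobbyness -2.5,
    cavity policy keep, analytic marching cubes)."""

    surface: str = "ses"
    input_path: str = None
    input_format: str = None  # xyzr | pqr | pdb | off | ply | msms
    scale: float = 2.0
    perfil: float = 90.0
    probe_radius: float = 1.4
    shrink: float = 0.45
    blobbyness: float = -2.5
    cavity_policy: str = "keep"
    cavity_min_volume: float = volumetrics.WATER_VOLUME
    mc_variant: str = "analytic"
    smooth_iterations: int = 0
    smooth_factor: float = 0.5
    grid_margin: float = 0.0
    seed: int = 0
    retries: int = 5
    out_mesh: str = None
    out_stats: str = None
    out_colormap: str = None
    out_cavities: str = None

    def validate(self):
        if self.surface not in SURFACE_KINDS:
            raise ValueError(f"surface must be one of {SURFACE_KINDS}")
        if self.cavity_policy not in CAVITY_POLICIES:
            raise ValueError(f"cavity policy must be one of {CAVITY_POLICIES}")
        if self.mc_variant not in MC_VARIANTS:
            raise ValueError(f"mc variant must be one of {MC_VARIANTS}")
        if not (0 < self.perfil < 100):
            raise ValueError("perfil must be in (0, 100)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")

    # flat key=value config-file dialect --------------------------------
    @classmethod
    def from_file(cls, path):
        kwargs = {}
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        types = {f.name: type(f.default) for f in cls.__dataclass_fields__.values()
                 if f.default is not None}
        for ln, line in enumerate(open(path), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key=value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{ln}: unknown key {key!r}")
            caster = types.get(key, str)
            kwargs[key] = caster(val) if caster in (int, float) else val
        return cls(**kwargs)

    def to_file(self, path):
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                if v is not None:
                    fh.write(f"{k} = {v}\n")


def build_surface(config: RunConfig, atoms=None, grid=None):
    """Stage 1: construct or import the surface named by the config."""
    kind = config.surface
    if kind == "mesh":
        return load_mesh_surface(config.input_path, config.input_format), None
    if atoms is None:
        atoms = read_atoms(config.input_path, config.input_format)
    if kind == "ses":
        return build_ses(atoms, SESParams(config.probe_radius,
                                          seed=config.seed)), atoms
    if kind == "vdw":
        return build_vdw(atoms, SESParams(seed=config.seed)), atoms
    if kind == "sas":
        return build_sas(atoms, config.probe_radius,
                         SESParams(seed=config.seed)), atoms
    if kind == "skin":
        return build_skin(atoms, SkinParams(config.shrink,
                                            seed=config.seed)), atoms
    if kind == "gaussian":
        if grid is None:
            raise ValueError("gaussian surface needs the grid first")
        return build_gaussian(atoms, GaussianParams(config.blobbyness),
                              grid), atoms
    raise ValueError(kind)


def run(config: RunConfig, atoms=None) -> dict:
    """Execute the four pipeline stages and return the stats dictionary."""
    config.validate()
    t0 = time.time()
    stats = {"config": {k: v for k, v in asdict(config).items()
                        if v is not None}}

    # stage 1: surface ---------------------------------------------------
    if config.surface == "gaussian":
        if atoms is None:
            atoms = read_atoms(config.input_path, config.input_format)
        margin = config.grid_margin or 1.0
        grid = raycast.make_grid(atoms, config.scale, config.perfil, margin)
        surface, _ = build_surface(config, atoms, grid)
    else:
        surface, atoms = build_surface(config, atoms)
        if config.surface == "mesh":
            grid = raycast.make_grid(surface, config.scale, config.perfil,
                                     config.grid_margin)
        else:
            grid = raycast.make_grid(atoms, config.scale, config.perfil,
                                     config.grid_margin)
    log.info("stage 1: %s surface built (%.2fs)", config.surface,
             time.time() - t0)

    # stage 2: ray casting ------------------------------------------------
    t1 = time.time()
    accels = [raycast.build_accel(surface, grid, a) for a in range(3)]
    status, intervals, report = raycast.cast_grid_rays(
        surface, grid, accels, retries=config.retries, seed=config.seed)
    vertex_status, edge_hits, ereport = raycast.cast_edge_rays(
        surface, grid, accels, retries=config.retries, seed=config.seed)
    status.vertices = vertex_status
    report.merge(ereport)
    log.info("stage 2: %d rays cast, %d retried, %d fallbacks (%.2fs)",
             report.rays_cast, report.rays_retried, report.fallbacks,
             time.time() - t1)

    # stage 3: cavities ---------------------------------------------------
    t2 = time.time()
    _, cavities = volumetrics.detect_cavities(status)
    stats["cavities"] = {
        "count": len(cavities),
        "volumes_A3": [round(c.volume, 4) for c in cavities],
        "total_volume_A3": sum(c.volume for c in cavities),
    }
    if config.cavity_policy != "keep":
        _, fill_log = volumetrics.fill_cavities(
            status, cavities,
            min_volume=config.cavity_min_volume,
            fill_all=config.cavity_policy == "fill_all",
            edge_hits=edge_hits)
        stats["cavities"]["filled"] = fill_log["filled"]
        _, cavities_after = volumetrics.detect_cavities(status)
        stats["cavities"]["remaining"] = len(cavities_after)
    log.info("stage 3: %d cavities (%.2fs)", len(cavities), time.time() - t2)

    # stage 4: triangulation + measures -----------------------------------
    t3 = time.time()
    if config.mc_variant == "analytic":
        mesh = triangulate.mc_analytic(status.vertices, edge_hits, grid)
    else:
        mesh = triangulate.mc_bisecting(status, grid)
    if config.smooth_iterations:
        mesh = triangulate.laplacian_smooth(mesh, config.smooth_iterations,
                                            config.smooth_factor)
    area, _ = triangulate.mesh_area(mesh)
    vol = volumetrics.volume_from_intervals(intervals, grid)
    stats.update({
        "grid": {"dims": list(grid.dims), "spacing": grid.spacing,
                 "origin": [round(float(v), 6) for v in grid.origin]},
        "area_A2": area,
        "volume_A3": {"x": vol[0], "y": vol[1], "z": vol[2],
                      "averaged": vol.averaged},
        "mesh": {"vertices": len(mesh.vertices),
                 "triangles": len(mesh.faces),
                 "closed": mesh.is_closed(),
                 "euler_characteristic": mesh.euler_characteristic(),
                 "midpoint_fallbacks": mesh.midpoint_fallbacks},
        "parity": {"rays_cast": report.rays_cast,
                   "rays_retried": report.rays_retried,
                   "retries": report.parity_retries,
                   "fallbacks": report.fallbacks,
                   "odd_after_protocol": report.odd_after_protocol,
                   "axis_disagreements": report.axis_disagreements},
        "elapsed_s": round(time.time() - t0, 3),
    })
    log.info("stage 4: %d triangles, area %.3f (%.2fs)", len(mesh.faces),
             area, time.time() - t3)

    # artifacts -----------------------------------------------------------
    if config.out_mesh:
        triangulate.export_mesh(mesh, config.out_mesh)
    if config.out_cavities:
        volumetrics.cavity_report_tsv(cavities, config.out_cavities)
    if config.out_colormap:
        cmap = gridio.color_grid(status, "keep-cavities")
        cmap.dump_text(config.out_colormap)
    if config.out_stats:
        Path(config.out_stats).write_text(json.dumps(stats, indent=2,
                                                     sort_keys=True))
    return stats, mesh, status
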