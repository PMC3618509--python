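"""Gaussian (blobby) molecular surface: iso-1 level set of a sum of
atom-centered Gaussians.

    field(x) = sum_i exp( B * ( ||x - c_i||^2 / R_i^2  -  1 ) ),  B < 0

With this kernel the isolated-atom isosurface at iso-value 1 is exactly the
VdW sphere, which anchors the tests.  Contributions beyond ``cutoff`` are
dropped (atom-centered accumulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atoms import AtomSet
from .base import ScalarFieldSurface

__all__ = ["GaussianParams", "build_gaussian", "gaussian_field_at"]


@dataclass
class GaussianParams:
    """Blobbyness B < 0 (roughness), iso-value, and accumulation cutoff."""

    blobbyness: float = -2.5
    iso: float = 1.0
    cutoff: float = 6.0

    def __post_init__(self):
        if self.blobbyness >= 0:
            raise ValueError("blobbyness must be negative")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def gaussian_field_at(points, atoms: AtomSet, params: GaussianParams,
                      apply_cutoff=False):
    """Exact field values at arbitrary points (the implicit-function oracle)."""
    pts = np.atleast_2d(np.asarray(points, float))
    B = params.blobbyness
    out = np.zeros(len(pts))
    for c, r in zip(atoms.centers, atoms.radii):
        d2 = ((pts - c) ** 2).sum(axis=1)
        term = np.exp(B * (d2 / (r * r) - 1.0))
        if apply_cutoff:
            term[d2 > params.cutoff**2] = 0.0
        out += term
    return out


def build_gaussian(atoms: AtomSet, params: GaussianParams | None, grid
                   ) -> ScalarFieldSurface:
    """Sample the field at the grid vertices; surface = {field = iso}.

    The grid must enclose every atom plus the cutoff; atoms are accumulated
    one at a time over the sub-block of vertices within their cutoff.
    """
    params = params or GaussianParams()
    if params.cutoff <= atoms.radii.max():
        raise ValueError("cutoff must exceed the largest atomic radius")
    lo, hi = atoms.bbox()
    g_lo = grid.origin
    g_hi = grid.origin + grid.spacing * (np.asarray(grid.dims) - 1)
    if (lo < g_lo).any() or (hi > g_hi).any():
        raise ValueError("grid does not enclose the atom set")

    nx, ny, nz = grid.dims
    xs = g_lo[0] + grid.spacing * np.arange(nx)
    ys = g_lo[1] + grid.spacing * np.arange(ny)
    zs = g_lo[2] + grid.spacing * np.arange(nz)
    field = np.zeros((nx, ny, nz))
    B, cut = params.blobbyness, params.cutoff
    h = grid.spacing
    for c, r in zip(atoms.centers, atoms.radii):
        i0 = np.maximum(((c - cut - g_lo) / h).astype(int), 0)
        i1 = np.minimum(((c + cut - g_lo) / h).astype(int) + 2, grid.dims)
        sx = xs[i0[0]:i1[0]][:, None, None] - c[0]
        sy = ys[i0[1]:i1[1]][None, :, None] - c[1]
        sz = zs[i0[2]:i1[2]][None, None, :] - c[2]
        d2 = sx * sx + sy * sy + sz * sz
        blob = np.exp(B * (d2 / (r * r) - 1.0))
        blob[d2 > cut * cut] = 0.0
        field[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] += blob
    return ScalarFieldSurface(grid, field, iso=params.iso)
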