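"""Atom containers and file readers (XYZR, PQR, PDB + radius table)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Atom", "AtomSet", "read_atoms", "perturb_atoms", "DEFAULT_ELEMENT_RADII"]

#: fallback van der Waals radii by element symbol (Angstrom), Bondi-style
DEFAULT_ELEMENT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 1.40, "ZN": 1.39, "MG": 1.73, "CA": 1.74, "NA": 2.27, "K": 2.75,
}


@dataclass(frozen=True)
class Atom:
    center: tuple
    radius: float


class AtomSet:
    """Centers + radii of the molecular system; sole input to the builders."""

    def __init__(self, centers, radii, provenance=None):
        self.centers = np.asarray(centers, float).reshape(-1, 3)
        self.radii = np.asarray(radii, float).reshape(-1)
        if len(self.centers) != len(self.radii):
            raise ValueError("centers and radii length mismatch")
        if len(self.centers) < 1:
            raise ValueError("an AtomSet needs at least one atom")
        if not np.isfinite(self.centers).all() or not np.isfinite(self.radii).all():
            raise ValueError("non-finite atom data")
        if (self.radii <= 0).any():
            bad = int(np.nonzero(self.radii <= 0)[0][0])
            raise ValueError(f"non-positive radius at atom index {bad}")
        self.provenance = dict(provenance or {})

    def __len__(self):
        return len(self.radii)

    def __iter__(self):
        for c, r in zip(self.centers, self.radii):
            yield Atom(tuple(c), float(r))

    def bbox(self, inflate=0.0):
        r = (self.radii + inflate)[:, None]
        return (self.centers - r).min(axis=0), (self.centers + r).max(axis=0)

    def inflated(self, delta):
        return AtomSet(self.centers.copy(), self.radii + delta,
                       {**self.provenance, "inflated_by": delta})

    def to_xyzr(self, path):
        with open(path, "w") as fh:
            for c, r in zip(self.centers, self.radii):
                fh.write(f"{c[0]:.6f} {c[1]:.6f} {c[2]:.6f} {r:.6f}\n")


class AtomParseError(ValueError):
    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _read_xyzr(path):
    centers, radii = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 4:
                raise AtomParseError(path, ln, f"expected 'x y z r', got {s!r}")
            try:
                x, y, z, r = (float(v) for v in parts[:4])
            except ValueError:
                raise AtomParseError(path, ln, f"malformed number in {s!r}") from None
            if r <= 0:
                raise AtomParseError(path, ln, f"non-positive radius {r}")
            centers.append((x, y, z))
            radii.append(r)
    if not centers:
        raise AtomParseError(path, 0, "no atoms found")
    return centers, radii


def _read_pqr(path):
    """PQR: whitespace PDB dialect; charge is parsed and ignored, radius kept."""
    centers, radii = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            parts = line.split()
            if len(parts) < 10:
                raise AtomParseError(path, ln, "too few fields for a PQR record")
            try:
                x, y, z = (float(v) for v in parts[-5:-2])
                r = float(parts[-1])
            except ValueError:
                raise AtomParseError(path, ln, "malformed coordinate/radius") from None
            if r <= 0:
                raise AtomParseError(path, ln, f"non-positive radius {r}")
            centers.append((x, y, z))
            radii.append(r)
    if not centers:
        raise AtomParseError(path, 0, "no ATOM/HETATM records found")
    return centers, radii


def _read_pdb(path, radius_table):
    """wwPDB v3.3 fixed columns via Biopython; radii from a name/element table."""
    from Bio.PDB import PDBParser

    table = {k.upper(): v for k, v in (radius_table or DEFAULT_ELEMENT_RADII).items()}
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("mol", str(path))
    centers, radii, unmatched = [], [], []
    for atom in structure.get_atoms():
        name = atom.get_name().strip().upper()
        element = (atom.element or "").strip().upper()
        r = table.get(name, table.get(element))
        if r is None:
            unmatched.append(name)
            continue
        centers.append(tuple(atom.get_coord()))
        radii.append(float(r))
    if unmatched:
        raise ValueError(
            "no radius rule for atom name(s): " + ", ".join(sorted(set(unmatched)))
        )
    if not centers:
        raise AtomParseError(path, 0, "no atoms found")
    return centers, radii


def read_atoms(path, fmt=None, radius_table=None) -> AtomSet:
    """Read an AtomSet from XYZR, PQR, or PDB (+ radius table) files."""
    path = Path(path)
    if fmt is None:
        fmt = {".xyzr": "xyzr", ".pqr": "pqr", ".pdb": "pdb", ".ent": "pdb"}.get(
            path.suffix.lower(), "xyzr")
    if fmt == "xyzr":
        centers, radii = _read_xyzr(path)
    elif fmt == "pqr":
        centers, radii = _read_pqr(path)
    elif fmt == "pdb":
        centers, radii = _read_pdb(path, radius_table)
    else:
        raise ValueError(f"unknown atom file format {fmt!r}")
    return AtomSet(centers, radii, {"file": str(path), "format": fmt})


def perturb_atoms(atoms: AtomSet, magnitude: float, seed: int) -> AtomSet:
    """Independent uniform jitter in [-magnitude, magnitude] per coordinate.

    Deterministic for a fixed seed; used to break co-spherical/co-planar
    degeneracies before the lifted convex-hull triangulation.
    """
    if magnitude < 0:
        raise ValueError("perturbation magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    shift = rng.uniform(-magnitude, magnitude, size=atoms.centers.shape)
    return AtomSet(atoms.centers + shift, atoms.radii.copy(),
                   {**atoms.provenance, "perturbation": magnitude, "seed": seed})
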