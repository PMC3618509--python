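"""Shared fixtures: expensive builds are session-scoped."""

import numpy as np
import pytest

from surfray.fixtures import gen_sphere_atom, gen_two_atoms
from surfray.surfaces import SESParams, build_ses
from surfray.raycast import build_accel, cast_edge_rays, cast_grid_rays, make_grid


@pytest.fixture(scope="session")
def sphere_fixture():
    return gen_sphere_atom(1.0)


@pytest.fixture(scope="session")
def two_atom_fixture():
    return gen_two_atoms(1.0, 1.0, 2.5, 1.4)


@pytest.fixture(scope="session")
def two_atom_ses(two_atom_fixture):
    return build_ses(two_atom_fixture.atoms, SESParams(seed=1))


@pytest.fixture(scope="session")
def two_atom_cast(two_atom_fixture, two_atom_ses):
    """Grid + both ray families for the overlapping two-atom SES."""
    grid = make_grid(two_atom_fixture.atoms, 4, 90)
    accels = [build_accel(two_atom_ses, grid, a) for a in range(3)]
    status, intervals, report = cast_grid_rays(two_atom_ses, grid, accels, seed=1)
    vstat, ehits, ereport = cast_edge_rays(two_atom_ses, grid, accels, seed=1)
    status.vertices = vstat
    return {
        "grid": grid, "accels": accels, "status": status,
        "intervals": intervals, "report": report, "edge_hits": ehits,
        "edge_report": ereport,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
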