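"""Shared fixtures: small head models are expensive, so they are built
once per session and reused read-only across test modules."""

import numpy as np
import pytest

from tdcsfem.electrodes import SurfaceProjector, conventional_montage
from tdcsfem.fem import DirectSolver, assemble_system
from tdcsfem.head_model import build_layered_sphere_head


@pytest.fixture(scope="session")
def head8():
    """Default five-shell head at 8 mm edge length (fast, ~50k tets)."""
    return build_layered_sphere_head(mesh_size=8.0, seed=1)


@pytest.fixture(scope="session")
def projector8(head8):
    return SurfaceProjector(head8.mesh)


@pytest.fixture(scope="session")
def system8(head8):
    return assemble_system(head8)


@pytest.fixture(scope="session")
def solver8(system8):
    return DirectSolver(system8)


@pytest.fixture(scope="session")
def conventional8(head8, projector8):
    return conventional_montage(head8, projector=projector8)


@pytest.fixture(scope="session")
def head10():
    """Very coarse head for topology/IO tests."""
    return build_layered_sphere_head(mesh_size=10.0, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
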