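"""Shared fixtures: phantoms and pipeline inputs are expensive, so they are
built once per session and treated as read-only by tests."""

import numpy as np
import pytest

import pelvifem as pf


@pytest.fixture(scope="session")
def default_params():
    return pf.PhantomParams()


@pytest.fixture(scope="session")
def phantom(default_params):
    """Intact default phantom (mesh, hu). Do not mutate."""
    return pf.build_phantom(default_params)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return pf.build_phantom(pf.PhantomParams(hu_noise_sd=0.0))


@pytest.fixture(scope="session")
def inputs():
    """Full pipeline inputs (phantom + fracture + ligaments). Do not mutate."""
    return pf.prepare_inputs()


@pytest.fixture(scope="session")
def comparison(inputs):
    """The default USI/BSI/TSI x stance comparison (shared: ~30 s)."""
    return pf.compare_constructs(inputs)


@pytest.fixture()
def small_block():
    """A small elastic block for solver unit tests (~hundreds of dofs)."""
    mesh = pf.box_mesh((4.0, 2.0, 2.0), h=1.0)
    nodes = mesh.nodes
    mesh.surface_patches["left"] = np.flatnonzero(nodes[:, 0] < 1e-9)
    mesh.surface_patches["right"] = np.flatnonzero(nodes[:, 0] > 4.0 - 1e-9)
    mesh.surface_patches["boundary"] = np.flatnonzero(
        (nodes[:, 0] < 1e-9) | (nodes[:, 0] > 4.0 - 1e-9)
        | (nodes[:, 1] < 1e-9) | (nodes[:, 1] > 2.0 - 1e-9)
        | (nodes[:, 2] < 1e-9) | (nodes[:, 2] > 2.0 - 1e-9))
    return mesh


class UniformMaterial:
    """Minimal material carrier for solver tests."""

    def __init__(self, mesh, E=1000.0, nu=0.3):
        self.E = np.full(mesh.n_elements, float(E))
        self.nu = np.full(mesh.n_elements, float(nu))


@pytest.fixture()
def uniform_material():
    return UniformMaterial
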