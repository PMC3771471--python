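import numpy as np
import pytest

import fmeit as fm


@pytest.fixture(scope="session")
def full_arc():
    return fm.BoundaryArc.full_circle()


@pytest.fixture(scope="session")
def basis8(full_arc):
    return fm.make_boundary_basis(full_arc, 8)


@pytest.fixture(scope="session")
def basis16(full_arc):
    return fm.make_boundary_basis(full_arc, 16)


@pytest.fixture(scope="session")
def mesh_coarse():
    return fm.disk_mesh(0.06)


@pytest.fixture(scope="session")
def mesh_mid():
    return fm.disk_mesh(0.03)


@pytest.fixture(scope="session")
def bg():
    return fm.homogeneous_field(1.0)


@pytest.fixture(scope="session")
def fem_bg_coarse(mesh_coarse, bg, basis8):
    return fm.FemSystem(mesh_coarse, bg, basis8)


@pytest.fixture(scope="session")
def disk_phantom():
    """Reference phantom: disk of radius 0.3 at (0.3, 0), contrast +1."""
    return fm.make_phantom(
        1.0, [fm.ShapeSpec(kind="disk", contrast=1.0, center=(0.3, 0.0), radius=0.3)])


def unit_currents(basis):
    K = basis.order
    return [fm.BoundaryFunction(np.eye(K)[:, k], basis) for k in range(K)]
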