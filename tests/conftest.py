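"""Shared fixtures: analytic domes and their fitted stress fields.

Solving the inverse problem dominates test runtime, so fitted results are
session-scoped and shared between unit and acceptance tests.
"""

import numpy as np
import pytest

from cmsm import (CurvedMonolayerStress, ShapeSpec, axisymmetric_oracle,
                  make_cap_mesh, spheroid_meridian)

DP = 100.0  # Pa, reference luminal pressure for fixture domes


@pytest.fixture(scope="session")
def sphere_spec():
    return ShapeSpec.spherical(100.0, 0.5)


@pytest.fixture(scope="session")
def sphere_mesh(sphere_spec):
    return make_cap_mesh(sphere_spec)


@pytest.fixture(scope="session")
def sphere_result(sphere_mesh):
    return CurvedMonolayerStress(sphere_mesh, DP).fit()


@pytest.fixture(scope="session")
def spheroid23_spec():
    return ShapeSpec.spheroid(50.0, 2.0 / 3.0, 0.5, edge_length=50.0 / 24.0)


@pytest.fixture(scope="session")
def spheroid23_mesh(spheroid23_spec):
    return make_cap_mesh(spheroid23_spec)


@pytest.fixture(scope="session")
def spheroid23_result(spheroid23_mesh):
    return CurvedMonolayerStress(spheroid23_mesh, DP).fit()


@pytest.fixture(scope="session")
def spheroid23_oracle(spheroid23_spec, spheroid23_mesh):
    z, r = spheroid_meridian(spheroid23_spec)
    return axisymmetric_oracle(z, r, DP)


@pytest.fixture(scope="session")
def tube14_spec():
    return ShapeSpec.rect_tube(50.0, 4.0, 0.9)


@pytest.fixture(scope="session")
def tube14_mesh(tube14_spec):
    return make_cap_mesh(tube14_spec)


@pytest.fixture(scope="session")
def tube14_result(tube14_mesh):
    return CurvedMonolayerStress(tube14_mesh, DP).fit()


@pytest.fixture(scope="session")
def ellipse13_spec():
    return ShapeSpec.ellipsoidal(90.0, 30.0, 0.8)


@pytest.fixture(scope="session")
def ellipse13_mesh(ellipse13_spec):
    return make_cap_mesh(ellipse13_spec)


@pytest.fixture(scope="session")
def ellipse13_result(ellipse13_mesh):
    return CurvedMonolayerStress(ellipse13_mesh, DP).fit()


def oracle_principal(oracle, mesh):
    """Oracle (sigma_I, sigma_II) in Pa*um at mesh vertices."""
    ev = oracle.evaluate(mesh)
    return (np.maximum(ev["N_phi"], ev["N_theta"]),
            np.minimum(ev["N_phi"], ev["N_theta"]))
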