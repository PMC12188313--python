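"""Shared fixtures.

Heavy objects (meshes, the phosphatase-rate scan, scenario runs) are
session-scoped and computed at coarse but converged resolutions for the
unit tests; the acceptance tests build their own full-resolution pipeline.
"""

import numpy as np
import pytest

from cortexflow import air1, paramfit, scenarios
from cortexflow.geometry import EmbryoGeometry, assemble_fem, build_mesh


@pytest.fixture(scope="session")
def geometry():
    return EmbryoGeometry()


@pytest.fixture(scope="session")
def coarse_mesh(geometry):
    """1 µm mesh refined at the reference polarization source."""
    cue = air1.polarization_cue(geometry=geometry)
    return build_mesh(geometry, target_edge_length=1.0,
                      refine_near=[(cue.centers[0], 3 * cue.sigma_c)])


@pytest.fixture(scope="session")
def coarse_fem(coarse_mesh):
    return assemble_fem(coarse_mesh)


@pytest.fixture(scope="session")
def params():
    """Canonical fitted polarization parameter set (k=2, seed 0)."""
    return paramfit.fitted_params(k=2, polarization=True, seed=0)


@pytest.fixture(scope="session")
def pol_air1_256():
    """Calibrated polarization AIR-1 profile, coarse mesh, 256-cell grid."""
    return scenarios.polarization_air1(1.9, target_edge_length=1.0,
                                       n_grid=256)


@pytest.fixture(scope="session")
def control_run_256(params, pol_air1_256):
    """Coarse control polarization run reused by several tests."""
    return scenarios.run_polarization(1.9, params=params, n=256,
                                      target_edge_length=1.0,
                                      duration_min=15)
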