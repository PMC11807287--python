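"""Shared fixtures: small grids and geometries for fast unit tests.

The "tiny" profile keeps the full anatomy inside a 283 mm field of view
at coarse voxels so each projection costs milliseconds.
"""

from __future__ import annotations

import numpy as np
import pytest

from mewpdq import (
    DetectorEnergyModel,
    GridSpec,
    ScannerGeometry,
    default_windows,
    make_pelvic_phantom,
    standard_uptake,
)
from mewpdq.system import build_regional_system_matrix, calibrate_sensitivity


@pytest.fixture(scope="session")
def windows():
    return default_windows()


@pytest.fixture(scope="session")
def detector():
    return DetectorEnergyModel()


@pytest.fixture(scope="session")
def tiny_grid():
    # 283 x 283 x 141 mm field of view at very coarse voxels.
    return GridSpec((24, 24, 12), 11.78)


@pytest.fixture(scope="session")
def tiny_geometry():
    return ScannerGeometry(n_angles=8, n_blur_groups=4)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_grid):
    phantom = make_pelvic_phantom(grid=tiny_grid)
    uptake = standard_uptake(phantom)
    for k in range(1, uptake.n_regions + 1):
        mask = phantom.region_mask(k)
        phantom.activity_th[mask] = uptake.lambda_th[k - 1]
        phantom.activity_ra[mask] = uptake.lambda_ra[k - 1]
    return phantom, uptake


@pytest.fixture(scope="session")
def tiny_system(tiny_phantom, tiny_geometry, windows, detector):
    """Calibrated geometry plus the regional system matrix set."""
    phantom, uptake = tiny_phantom
    geometry = calibrate_sensitivity(
        phantom, tiny_geometry, windows, detector
    )
    sysmat = build_regional_system_matrix(phantom, geometry, windows, detector)
    return phantom, uptake, geometry, sysmat


def assert_allclose(actual, desired, rtol=1e-7, atol=0.0):
    np.testing.assert_allclose(actual, desired, rtol=rtol, atol=atol)
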