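"""Projector oracles: point source, adjointness, linearity, attenuation."""

import numpy as np
import pytest

from mewpdq.nuclides import (
    DetectorEnergyModel,
    EmissionLine,
    LineSpectrum,
    default_windows,
    effective_window_response,
    load_builtin_spectrum,
)
from mewpdq.phantoms import GridSpec
from mewpdq.projector import Projector, ScannerGeometry


@pytest.fixture(scope="module")
def sharp_geometry():
    """No blur, no scatter: the projector reduces to rotate-and-sum."""
    return ScannerGeometry(
        n_angles=6,
        intrinsic_fwhm_mm=0.0,
        collimator_slope_fwhm_mm_per_cm=0.0,
        scatter_fraction=None,
    )


@pytest.fixture(scope="module")
def odd_grid():
    # odd transaxial size: the center voxel is exactly on the rotation axis
    return GridSpec((15, 15, 7), 10.0)


def _air_cache(proj, grid, spectrum):
    mu = np.zeros(grid.shape)
    classes = np.zeros(grid.shape, dtype=np.int16)
    return proj.attenuation_cache(mu, classes, spectrum)


def test_point_source_total_counts_analytic(odd_grid, sharp_geometry, windows, detector):
    """Total expected counts of a point source in air equal
    (window mass) x sensitivity x time, per view, to 1e-6."""
    spectrum = load_builtin_spectrum("Th227")
    proj = Projector(odd_grid, sharp_geometry, windows, detector)
    cache = _air_cache(proj, odd_grid, spectrum)

    act = np.zeros(odd_grid.shape)
    act[7, 7, 3] = 1.0 / odd_grid.voxel_volume_ml  # 1 Bq total
    out = proj.project(act, cache)

    weights, _ = effective_window_response(spectrum, windows, detector)
    scale = sharp_geometry.sensitivity_scale * sharp_geometry.acquisition_time_s
    for w in range(len(windows)):
        for a in range(sharp_geometry.n_angles):
            assert out[w, a].sum() == pytest.approx(weights[w] * scale, rel=1e-6)


def test_point_source_on_axis_stays_in_center_bin(odd_grid, sharp_geometry, windows, detector):
    spectrum = load_builtin_spectrum("Th227")
    proj = Projector(odd_grid, sharp_geometry, windows, detector)
    cache = _air_cache(proj, odd_grid, spectrum)
    act = np.zeros(odd_grid.shape)
    act[7, 7, 3] = 1.0
    out = proj.project(act, cache)
    for a in range(sharp_geometry.n_angles):
        plane = out[0, a]
        peak = np.unravel_index(np.argmax(plane), plane.shape)
        assert peak == (7, 3)
        # all mass in the center bin (source on the rotation axis)
        assert plane[7, 3] == pytest.approx(plane.sum(), rel=1e-9)


def test_adjoint_dot_product_identity(tiny_grid, windows, detector):
    geometry = ScannerGeometry(n_angles=8, n_blur_groups=4)
    spectrum = load_builtin_spectrum("Ra223chain")
    proj = Projector(tiny_grid, geometry, windows, detector)
    mu = np.full(tiny_grid.shape, 0.15)
    classes = np.ones(tiny_grid.shape, dtype=np.int16)
    cache = proj.attenuation_cache(mu, classes, spectrum)
    rng = np.random.default_rng(11)
    x = rng.random(tiny_grid.shape)
    y = rng.random(proj.bins_shape)
    lhs = float((proj.project(x, cache) * y).sum())
    rhs = float((x * proj.backproject(y, cache)).sum())
    assert lhs == pytest.approx(rhs, rel=1e-12)


def test_adjoint_holds_on_angle_subsets(tiny_grid, windows, detector):
    geometry = ScannerGeometry(n_angles=8, n_blur_groups=4)
    spectrum = load_builtin_spectrum("Th227")
    proj = Projector(tiny_grid, geometry, windows, detector)
    cache = _air_cache(proj, tiny_grid, spectrum)
    rng = np.random.default_rng(5)
    x = rng.random(tiny_grid.shape)
    y = rng.random(proj.bins_shape)
    angles = [1, 4, 6]
    lhs = float((proj.project(x, cache, angles=angles) * y).sum())
    rhs = float((x * proj.backproject(y, cache, angles=angles)).sum())
    assert lhs == pytest.approx(rhs, rel=1e-12)


def test_linearity_superposition(tiny_grid, tiny_geometry, windows, detector):
    spectrum = load_builtin_spectrum("Th227")
    proj = Projector(tiny_grid, tiny_geometry, windows, detector)
    cache = _air_cache(proj, tiny_grid, spectrum)
    rng = np.random.default_rng(3)
    a = rng.random(tiny_grid.shape)
    b = rng.random(tiny_grid.shape)
    combined = proj.project(a + 2.0 * b, cache)
    separate = proj.project(a, cache) + 2.0 * proj.project(b, cache)
    np.testing.assert_allclose(combined, separate, rtol=1e-10, atol=1e-12)


def test_doubling_time_doubles_counts(tiny_grid, windows, detector):
    from dataclasses import replace

    spectrum = load_builtin_spectrum("Th227")
    g1 = ScannerGeometry(n_angles=4, n_blur_groups=4)
    g2 = replace(g1, acquisition_time_s=2 * g1.acquisition_time_s)
    rng = np.random.default_rng(9)
    act = rng.random(tiny_grid.shape)
    outs = []
    for g in (g1, g2):
        proj = Projector(tiny_grid, g, windows, detector)
        cache = _air_cache(proj, tiny_grid, spectrum)
        outs.append(proj.project(act, cache))
    np.testing.assert_allclose(outs[1], 2.0 * outs[0], rtol=1e-12)


def test_attenuation_monotonicity(tiny_grid, tiny_geometry, windows, detector):
    """Increasing mu anywhere never increases any expected count."""
    spectrum = load_builtin_spectrum("Th227")
    proj = Projector(tiny_grid, tiny_geometry, windows, detector)
    classes = np.ones(tiny_grid.shape, dtype=np.int16)
    mu_low = np.full(tiny_grid.shape, 0.05)
    mu_high = mu_low.copy()
    mu_high[8:16, 8:16, :] = 0.30  # denser interior block
    act = np.zeros(tiny_grid.shape)
    act[12, 12, 6] = 5.0
    lo = proj.project(act, proj.attenuation_cache(mu_low, classes, spectrum))
    hi = proj.project(act, proj.attenuation_cache(mu_high, classes, spectrum))
    assert np.all(hi <= lo + 1e-12)
    assert hi.sum() < lo.sum()


def test_scatter_surrogate_preserves_adjointness_and_adds_counts(
    tiny_grid, windows, detector
):
    geo_scatter = ScannerGeometry(n_angles=4, n_blur_groups=4)
    geo_clean = ScannerGeometry(n_angles=4, n_blur_groups=4, scatter_fraction=None)
    spectrum = load_builtin_spectrum("Th227")
    act = np.zeros(tiny_grid.shape)
    act[12, 12, 6] = 1.0
    outs = {}
    for name, geo in (("scatter", geo_scatter), ("clean", geo_clean)):
        proj = Projector(tiny_grid, geo, windows, detector)
        cache = _air_cache(proj, tiny_grid, spectrum)
        outs[name] = proj.project(act, cache)
    assert outs["scatter"].sum() > outs["clean"].sum()


def test_nonfinite_activity_rejected(tiny_grid, tiny_geometry, windows, detector):
    proj = Projector(tiny_grid, tiny_geometry, windows, detector)
    spectrum = load_builtin_spectrum("Th227")
    cache = _air_cache(proj, tiny_grid, spectrum)
    act = np.zeros(tiny_grid.shape)
    act[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        proj.project(act, cache)


def test_invalid_geometry_rejected():
    with pytest.raises(ValueError):
        ScannerGeometry(n_angles=0)
    with pytest.raises(ValueError):
        ScannerGeometry(sensitivity_scale=0.0)
    with pytest.raises(ValueError):
        ScannerGeometry(intrinsic_fwhm_mm=-1.0)
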