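"""Regional system matrices, stray noise, simulation, and HDF5 I/O."""

import numpy as np
import pytest

from mewpdq.phantoms import LESION, RegionalUptake
from mewpdq.system import (
    DEFAULT_STRAY_REFERENCE,
    STRAY_REFERENCE_TIME_S,
    build_regional_system_matrix,
    calibrate_sensitivity,
    load_system_matrix,
    save_system_matrix,
    simulate_projections,
    simulate_projections_from_phantom,
    stray_noise_means,
)


# ---------------------------------------------------------------------------
# Stray noise
# ---------------------------------------------------------------------------


def test_stray_means_scale_with_time_and_window_width(windows):
    psi = stray_noise_means(0.1, windows, 1800.0, bins_per_window=2)
    widths = np.array([w.width_kev for w in windows])
    w3 = widths[2]
    expected_per_window = 0.1 * (1800.0 / STRAY_REFERENCE_TIME_S) * widths / w3
    np.testing.assert_allclose(psi, np.repeat(expected_per_window, 2), rtol=1e-12)
    # window 3 block carries exactly the time-scaled reference
    assert psi[4] == pytest.approx(0.1 * 3.0)


def test_stray_means_zero_reference(windows):
    psi = stray_noise_means(0.0, windows, 1800.0, bins_per_window=5)
    assert np.all(psi == 0)


def test_stray_negative_reference_rejected(windows):
    with pytest.raises(ValueError):
        stray_noise_means(-0.1, windows, 600.0, bins_per_window=1)


# ---------------------------------------------------------------------------
# System matrix construction
# ---------------------------------------------------------------------------


def test_columns_positive_and_shapes(tiny_system, windows):
    phantom, _, _, sysmat = tiny_system
    n_bins = int(np.prod(sysmat.bins_shape))
    assert sysmat.h_th.shape == (n_bins, phantom.n_regions)
    assert sysmat.h_ra.shape == sysmat.h_th.shape
    # every VOI is visible in every isotope: nonzero column sums
    assert np.all(sysmat.h_th.sum(axis=0) > 0)
    assert np.all(sysmat.h_ra.sum(axis=0) > 0)
    assert np.all(sysmat.h_th >= 0) and np.all(sysmat.h_ra >= 0)


def test_matched_model_identity(tiny_system, detector):
    """H columns are projections of unit VOI indicators, so H @ lambda
    must equal the projection of the piecewise-constant activity map."""
    phantom, uptake, geometry, sysmat = tiny_system
    from mewpdq.nuclides import load_builtin_spectrum
    from mewpdq.projector import Projector

    proj = Projector(phantom.grid, geometry, sysmat.windows, detector)
    voxel_mean = np.zeros(proj.bins_shape)
    for iso, lam in (("Th227", uptake.lambda_th), ("Ra223chain", uptake.lambda_ra)):
        act = np.zeros(phantom.grid.shape)
        for k in range(1, phantom.n_regions + 1):
            act[phantom.region_mask(k)] = lam[k - 1]
        cache = proj.attenuation_cache(
            phantom.mu_ref, phantom.tissue_classes, load_builtin_spectrum(iso)
        )
        voxel_mean += proj.project(act, cache)
    regional_mean = sysmat.expected_counts(uptake) - sysmat.psi
    np.testing.assert_allclose(
        regional_mean, voxel_mean.ravel(), rtol=1e-10, atol=1e-12
    )


def test_expected_counts_include_psi(tiny_system):
    _, uptake, _, sysmat = tiny_system
    zero = RegionalUptake(
        np.zeros(sysmat.n_regions), np.zeros(sysmat.n_regions)
    )
    np.testing.assert_allclose(sysmat.expected_counts(zero), sysmat.psi)


def test_window_rows_partition(tiny_system, windows):
    *_, sysmat = tiny_system
    per_window = int(np.prod(sysmat.bins_shape[1:]))
    all_rows = np.zeros(sysmat.n_bins, dtype=int)
    for idx in (1, 2, 3, 4):
        mask = sysmat.window_rows([idx])
        assert mask.sum() == per_window
        all_rows += mask.astype(int)
    np.testing.assert_array_equal(all_rows, 1)


def test_empty_voi_raises(tiny_phantom, tiny_geometry, windows, detector):
    phantom, _ = tiny_phantom
    import copy

    broken = copy.deepcopy(phantom)
    # empty out a middle region (gut) so the label range still spans
    # 1..4 but one VOI has no voxels
    broken.voi_labels[broken.voi_labels == 3] = 1
    with pytest.raises(ValueError, match="empty"):
        build_regional_system_matrix(broken, tiny_geometry, windows, detector)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def test_simulation_is_deterministic(tiny_system):
    _, uptake, _, sysmat = tiny_system
    a = simulate_projections(sysmat, uptake, seed=99)
    b = simulate_projections(sysmat, uptake, seed=99)
    np.testing.assert_array_equal(a.counts, b.counts)
    c = simulate_projections(sysmat, uptake, seed=100)
    assert not np.array_equal(a.counts, c.counts)


def test_zero_uptake_zero_stray_gives_zero_counts(tiny_system):
    phantom, _, geometry, _ = tiny_system
    from mewpdq import DetectorEnergyModel, default_windows

    sysmat0 = build_regional_system_matrix(
        phantom, geometry, default_windows(), DetectorEnergyModel(),
        stray_reference=0.0,
    )
    zero = RegionalUptake(np.zeros(4), np.zeros(4))
    data = simulate_projections(sysmat0, zero, seed=1)
    assert data.counts.sum() == 0


def test_counts_are_nonnegative_integers(tiny_system):
    _, uptake, _, sysmat = tiny_system
    data = simulate_projections(sysmat, uptake, seed=4)
    assert np.issubdtype(data.counts.dtype, np.integer)
    assert data.counts.min() >= 0


def test_voxel_mode_simulator_total_matches_regional_mean(tiny_system, windows, detector):
    """With piecewise-constant activity the voxel-mode simulator draws
    from the same Poisson mean as the regional model (up to float
    summation order), so many-realization totals agree closely."""
    phantom, uptake, geometry, sysmat = tiny_system
    mean_total = float(sysmat.expected_counts(uptake).sum())
    totals = [
        simulate_projections_from_phantom(
            phantom, geometry, windows, detector, seed=s
        ).counts.sum()
        for s in range(30)
    ]
    # Poisson total: sd = sqrt(mean_total); 30 draws give SE ~ sqrt(mean/30)
    se = np.sqrt(mean_total / len(totals))
    assert abs(np.mean(totals) - mean_total) < 5 * se


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def test_calibration_hits_target(tiny_phantom, tiny_geometry, windows, detector):
    phantom, uptake = tiny_phantom
    geo = calibrate_sensitivity(
        phantom, tiny_geometry, windows, detector, target_total_counts=5e4
    )
    sysmat = build_regional_system_matrix(phantom, geo, windows, detector)
    signal = sysmat.expected_counts(uptake) - sysmat.psi
    assert signal.sum() == pytest.approx(5e4, rel=1e-9)


def test_calibration_empty_phantom_raises(tiny_grid, tiny_geometry, windows, detector):
    from mewpdq import make_pelvic_phantom

    phantom = make_pelvic_phantom(grid=tiny_grid)  # activity maps all zero
    with pytest.raises(ValueError, match="no counts"):
        calibrate_sensitivity(phantom, tiny_geometry, windows, detector)


# ---------------------------------------------------------------------------
# HDF5 round trip
# ---------------------------------------------------------------------------


def test_hdf5_round_trip(tiny_system, tmp_path):
    *_, sysmat = tiny_system
    path = tmp_path / "sysmat.h5"
    save_system_matrix(sysmat, path)
    back = load_system_matrix(path)
    np.testing.assert_array_equal(back.h_th, sysmat.h_th)
    np.testing.assert_array_equal(back.h_ra, sysmat.h_ra)
    np.testing.assert_array_equal(back.psi, sysmat.psi)
    assert back.bins_shape == sysmat.bins_shape
    assert [w.index for w in back.windows] == [w.index for w in sysmat.windows]
    assert back.geometry.acquisition_time_s == sysmat.geometry.acquisition_time_s
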