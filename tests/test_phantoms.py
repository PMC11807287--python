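"""Phantom anatomy, uptake scaling, heterogeneity, VIT, misregistration."""

import numpy as np
import pytest

from mewpdq.phantoms import (
    BACKGROUND,
    BONE,
    GUT,
    LESION,
    GridSpec,
    LumpyParams,
    RegionalUptake,
    STANDARD_TOTAL_TH_BQ,
    TABLE_RATIOS,
    VITConfig,
    apply_lumpy_heterogeneity,
    apply_rigid_misregistration,
    load_phantom,
    make_pelvic_phantom,
    mix_heterogeneity,
    sample_vit_population,
    save_phantom,
    standard_uptake,
    uptake_from_ratios,
)


# ---------------------------------------------------------------------------
# Anatomy
# ---------------------------------------------------------------------------


def test_all_four_vois_present_and_nested_correctly():
    ph = make_pelvic_phantom()
    labels = ph.voi_labels
    for k in (BACKGROUND, BONE, GUT, LESION):
        assert (labels == k).any(), f"VOI {k} empty"
    # lesion voxels carry bone tissue class
    from mewpdq.attenuation import TISSUE_BONE

    assert np.all(ph.tissue_classes[labels == LESION] == TISSUE_BONE)
    # nothing outside the body is labeled
    assert np.all(ph.tissue_classes[labels == 0] == 0)


def test_lesion_volume_matches_sphere_on_fine_grid():
    grid = GridSpec((128, 128, 64), 2.21)
    ph = make_pelvic_phantom(33.75, grid=grid)
    vol = ph.region_volumes_ml()[LESION - 1] * 1000.0  # mm^3
    expected = np.pi / 6.0 * 33.75**3
    assert vol == pytest.approx(expected, rel=0.02)


def test_lesion_overflow_raises():
    with pytest.raises(ValueError, match="outside the bone"):
        make_pelvic_phantom(120.0)


def test_nonpositive_diameter_rejected():
    with pytest.raises(ValueError):
        make_pelvic_phantom(0.0)


def test_body_scale_scales_volumes():
    small = make_pelvic_phantom(body_scale=0.9)
    large = make_pelvic_phantom(body_scale=1.05)
    assert (
        large.region_volumes_ml()[BACKGROUND - 1]
        > small.region_volumes_ml()[BACKGROUND - 1]
    )


# ---------------------------------------------------------------------------
# Uptake scaling
# ---------------------------------------------------------------------------


def test_standard_uptake_hits_total_activities():
    ph = make_pelvic_phantom()
    up = standard_uptake(ph)
    vols = ph.region_volumes_ml()
    total_th = float(up.lambda_th @ vols)
    total_ra = float(up.lambda_ra @ vols)
    assert total_th == pytest.approx(STANDARD_TOTAL_TH_BQ, rel=1e-12)
    assert total_ra == pytest.approx(STANDARD_TOTAL_TH_BQ / 5.0, rel=1e-12)


def test_uptake_preserves_concentration_ratios():
    ph = make_pelvic_phantom()
    up = standard_uptake(ph)
    ratios = up.lambda_th / up.lambda_th[0]
    expected = TABLE_RATIOS["Th227"] / TABLE_RATIOS["Th227"][0]
    np.testing.assert_allclose(ratios, expected, rtol=1e-12)


def test_lesion_to_bone_ratio_override():
    ph = make_pelvic_phantom()
    up = standard_uptake(ph, lesion_to_bone_ratio=4.0)
    assert up.lambda_th[LESION - 1] / up.lambda_th[BONE - 1] == pytest.approx(4.0)
    assert up.lambda_ra[LESION - 1] / up.lambda_ra[BONE - 1] == pytest.approx(4.0)


def test_negative_uptake_rejected():
    with pytest.raises(ValueError, match="nonnegative"):
        RegionalUptake(np.array([1.0, -1.0]), np.array([1.0, 1.0]))


def test_uptake_from_ratios_totals():
    ph = make_pelvic_phantom()
    up = uptake_from_ratios(
        ph, np.array([1.0, 2, 3, 4]), np.array([1.0, 1, 1, 1]), 5e6, 1e6
    )
    vols = ph.region_volumes_ml()
    assert float(up.lambda_th @ vols) == pytest.approx(5e6)
    assert float(up.lambda_ra @ vols) == pytest.approx(1e6)


# ---------------------------------------------------------------------------
# Lumpy heterogeneity and mixture
# ---------------------------------------------------------------------------


def test_lumpy_preserves_region_mean_exactly(tiny_phantom):
    phantom, _ = tiny_phantom
    params = LumpyParams(mean_num_lumps=50.0, lump_width_mm=20.0, region=1, seed=7)
    textured = apply_lumpy_heterogeneity(phantom, params)
    mask = phantom.region_mask(1)
    for name in ("activity_th", "activity_ra"):
        before = getattr(phantom, name)[mask].mean()
        after = getattr(textured, name)[mask].mean()
        assert after == pytest.approx(before, rel=1e-10)
    # other regions untouched
    other = ~mask
    np.testing.assert_array_equal(
        textured.activity_th[other], phantom.activity_th[other]
    )


def test_lumpy_zero_mean_count_is_homogeneous(tiny_phantom):
    phantom, _ = tiny_phantom
    params = LumpyParams(mean_num_lumps=0.0, lump_width_mm=10.0, region=1, seed=3)
    textured = apply_lumpy_heterogeneity(phantom, params)
    np.testing.assert_array_equal(textured.activity_th, phantom.activity_th)


def test_lumpy_actually_textures(tiny_phantom):
    phantom, _ = tiny_phantom
    params = LumpyParams(mean_num_lumps=30.0, lump_width_mm=15.0, region=1, seed=1)
    textured = apply_lumpy_heterogeneity(phantom, params)
    mask = phantom.region_mask(1)
    assert textured.activity_th[mask].std() > 0


def test_mixture_endpoints_and_midpoint(tiny_phantom):
    phantom, _ = tiny_phantom
    params = LumpyParams(mean_num_lumps=30.0, lump_width_mm=15.0, region=1, seed=2)
    het = apply_lumpy_heterogeneity(phantom, params)
    at0 = mix_heterogeneity(het, phantom, 0.0)
    at1 = mix_heterogeneity(het, phantom, 1.0)
    mid = mix_heterogeneity(het, phantom, 0.4)
    np.testing.assert_allclose(at0.activity_th, phantom.activity_th)
    np.testing.assert_allclose(at1.activity_th, het.activity_th)
    np.testing.assert_allclose(
        mid.activity_th,
        0.4 * het.activity_th + 0.6 * phantom.activity_th,
        rtol=1e-12,
    )


def test_mixture_weight_out_of_range(tiny_phantom):
    phantom, _ = tiny_phantom
    with pytest.raises(ValueError):
        mix_heterogeneity(phantom, phantom, 1.5)


# ---------------------------------------------------------------------------
# Virtual imaging trial population
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_population(tiny_grid):
    cfg = VITConfig(grid=tiny_grid)
    return sample_vit_population(6, seed=123, config=cfg), cfg


def test_vit_is_deterministic(tiny_grid):
    cfg = VITConfig(grid=tiny_grid)
    a = sample_vit_population(3, seed=42, config=cfg)
    b = sample_vit_population(3, seed=42, config=cfg)
    for (pa, ua), (pb, ub) in zip(a, b):
        np.testing.assert_array_equal(pa.activity_th, pb.activity_th)
        np.testing.assert_array_equal(ua.composite(), ub.composite())


def test_vit_seeds_differ(tiny_grid):
    cfg = VITConfig(grid=tiny_grid)
    a = sample_vit_population(1, seed=1, config=cfg)[0][0]
    b = sample_vit_population(1, seed=2, config=cfg)[0][0]
    assert a.meta["lesion_diameter_mm"] != b.meta["lesion_diameter_mm"]


def test_vit_respects_truncation_and_containment(small_population):
    population, cfg = small_population
    for phantom, uptake in population:
        assert phantom.meta["lesion_diameter_mm"] >= cfg.lesion_diameter_min_mm
        assert np.all(uptake.composite() >= 0)
        # lesion fully inside what used to be bone: no lesion voxel touches
        # soft tissue or air
        lesion = phantom.region_mask(LESION)
        assert lesion.any()


def test_vit_population_varies(small_population):
    population, _ = small_population
    diams = [p.meta["lesion_diameter_mm"] for p, _ in population]
    assert len(set(diams)) > 1


# ---------------------------------------------------------------------------
# Rigid misregistration
# ---------------------------------------------------------------------------


def test_misregistration_identity_is_copy(tiny_phantom):
    phantom, _ = tiny_phantom
    out = apply_rigid_misregistration(phantom)
    np.testing.assert_array_equal(out.activity_th, phantom.activity_th)


@pytest.fixture(scope="module")
def roomy_phantom():
    """Body clear of every grid boundary so rigid moves fit.

    The 12-slice tiny grid has the body touching the axial edge planes,
    which the clip check rejects for any transform; use a grid with
    axial headroom instead.
    """
    grid = GridSpec((28, 28, 16), 10.1)
    phantom = make_pelvic_phantom(grid=grid, body_scale=0.8)
    up = standard_uptake(phantom)
    for k in range(1, up.n_regions + 1):
        mask = phantom.region_mask(k)
        phantom.activity_th[mask] = up.lambda_th[k - 1]
        phantom.activity_ra[mask] = up.lambda_ra[k - 1]
    return phantom


def test_misregistration_keeps_labels_stale(roomy_phantom):
    out = apply_rigid_misregistration(roomy_phantom, shift_voxels=(1.5, 0.0))
    np.testing.assert_array_equal(out.voi_labels, roomy_phantom.voi_labels)
    assert not np.array_equal(out.activity_th, roomy_phantom.activity_th)


def test_misregistration_conserves_activity(roomy_phantom):
    out = apply_rigid_misregistration(roomy_phantom, rotation_deg_about_y=2.0)
    total0 = roomy_phantom.total_activity_bq("Th227")
    total1 = out.total_activity_bq("Th227")
    assert total1 == pytest.approx(total0, rel=5e-3)


def test_misregistration_clipping_raises(tiny_phantom):
    phantom, _ = tiny_phantom
    with pytest.raises(ValueError, match="clips"):
        apply_rigid_misregistration(phantom, shift_voxels=(8.0, 0.0))


# ---------------------------------------------------------------------------
# I/O round trip
# ---------------------------------------------------------------------------


def test_save_load_round_trip(tiny_phantom, tmp_path):
    phantom, _ = tiny_phantom
    save_phantom(phantom, tmp_path / "ph")
    back = load_phantom(tmp_path / "ph")
    assert back.grid == phantom.grid
    np.testing.assert_array_equal(back.voi_labels, phantom.voi_labels)
    np.testing.assert_allclose(back.activity_th, phantom.activity_th)
    np.testing.assert_allclose(back.mu_ref, phantom.mu_ref)
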