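"""Regional system matrices, stray-radiation noise, and Poisson data.

The regional (VOI-basis) system matrix of one isotope has one column
per VOI: the expected detector counts per unit activity concentration
(1 Bq/mL) filling that VOI, computed noise-free with the simplified
projector.  Stray-radiation background is Poisson with a mean that is
constant within each energy-window block and proportional to the window
width, scaled from a reference mean measured in window 3 over 10
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .nuclides import (
    DetectorEnergyModel,
    EnergyWindow,
    LineSpectrum,
    load_builtin_spectrum,
)
from .phantoms import GridSpec, Phantom, RegionalUptake
from .projector import Projector, ScannerGeometry

__all__ = [
    "SystemMatrixSet",
    "ProjectionData",
    "build_regional_system_matrix",
    "stray_noise_means",
    "simulate_projections",
    "simulate_projections_from_phantom",
    "calibrate_sensitivity",
    "save_system_matrix",
    "load_system_matrix",
]

#: Acquisition time of the blank scan from which the stray-noise
#: reference mean is specified.
STRAY_REFERENCE_TIME_S = 600.0

#: Default reference stray-noise mean: counts per projection bin in
#: energy window 3 over a 10-minute blank scan.
DEFAULT_STRAY_REFERENCE = 0.1


@dataclass
class SystemMatrixSet:
    """Per-isotope regional system matrices plus stray-noise means."""

    h_th: np.ndarray  # (M, K) expected counts per Bq/mL in VOI k
    h_ra: np.ndarray
    psi: np.ndarray  # (M,) stray-noise means
    windows: tuple[EnergyWindow, ...]
    geometry: ScannerGeometry
    grid: GridSpec
    bins_shape: tuple[int, int, int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.h_th.shape != self.h_ra.shape:
            raise ValueError("isotope system matrices must share shape")
        if self.psi.shape != (self.h_th.shape[0],):
            raise ValueError("psi length must match the number of bins")
        if np.any(self.h_th < 0) or np.any(self.h_ra < 0) or np.any(self.psi < 0):
            raise ValueError("system matrix and psi entries must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.h_th.shape[0]

    @property
    def n_regions(self) -> int:
        return self.h_th.shape[1]

    @property
    def h_composite(self) -> np.ndarray:
        """(M, 2K) composite matrix: Th columns then Ra columns (cached)."""
        cached = getattr(self, "_h_composite", None)
        if cached is None:
            cached = np.hstack([self.h_th, self.h_ra])
            object.__setattr__(self, "_h_composite", cached)
        return cached

    def expected_counts(self, uptake: RegionalUptake | np.ndarray) -> np.ndarray:
        lam = (
            uptake.composite()
            if isinstance(uptake, RegionalUptake)
            else np.asarray(uptake, dtype=float)
        )
        return self.h_composite @ lam + self.psi

    def window_rows(self, window_indices: Sequence[int]) -> np.ndarray:
        """Boolean row mask selecting the given 1-based window blocks."""
        per_window = int(np.prod(self.bins_shape[1:]))
        block = np.repeat(
            [w.index for w in self.windows], per_window
        )
        return np.isin(block, np.asarray(window_indices))


@dataclass
class ProjectionData:
    """One realization of measured counts (flattened, window-major)."""

    counts: np.ndarray  # (M,) nonnegative integers
    bins_shape: tuple[int, int, int, int]
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


def stray_noise_means(
    reference_mean_window3_per_10min: float,
    windows: Sequence[EnergyWindow],
    acquisition_time_s: float,
    bins_per_window: int,
) -> np.ndarray:
    """Window-block-constant stray-noise means for all M bins.

    The window-3 mean equals the 10-minute reference scaled by the
    acquisition time; other windows are scaled by their width relative
    to window 3.
    """
    if reference_mean_window3_per_10min < 0:
        raise ValueError("reference stray mean must be >= 0")
    widths = np.array([w.width_kev for w in windows])
    if np.any(widths <= 0):
        raise ValueError("window widths must be positive")
    ref_window = next((w for w in windows if w.index == 3), windows[-1])
    per_window = (
        reference_mean_window3_per_10min
        * (acquisition_time_s / STRAY_REFERENCE_TIME_S)
        * widths
        / ref_window.width_kev
    )
    return np.repeat(per_window, bins_per_window)


def build_regional_system_matrix(
    phantom: Phantom,
    geometry: ScannerGeometry,
    windows: Sequence[EnergyWindow],
    detector: DetectorEnergyModel,
    stray_reference: float = DEFAULT_STRAY_REFERENCE,
    spectra: dict[str, LineSpectrum] | None = None,
) -> SystemMatrixSet:
    """Build the per-isotope VOI-basis system matrices for a phantom.

    Column k of each matrix is the noise-free projection of a unit
    concentration (1 Bq/mL) filling VOI k, so ``H @ lambda`` gives the
    expected counts for regional uptake ``lambda`` in Bq/mL.
    """
    spectra = spectra or {
        iso: load_builtin_spectrum(iso) for iso in ("Th227", "Ra223chain")
    }
    proj = Projector(phantom.grid, geometry, windows, detector)
    n_regions = phantom.n_regions
    columns = {iso: [] for iso in ("Th227", "Ra223chain")}
    for iso in columns:
        cache = proj.attenuation_cache(
            phantom.mu_ref, phantom.tissue_classes, spectra[iso]
        )
        for k in range(1, n_regions + 1):
            mask = phantom.region_mask(k)
            if not mask.any():
                raise ValueError(f"VOI {k} is empty")
            columns[iso].append(
                proj.project(mask.astype(float), cache).ravel()
            )
    h_th = np.column_stack(columns["Th227"])
    h_ra = np.column_stack(columns["Ra223chain"])
    bins_per_window = int(np.prod(proj.bins_shape[1:]))
    psi = stray_noise_means(
        stray_reference, windows, geometry.acquisition_time_s, bins_per_window
    )
    return SystemMatrixSet(
        h_th=h_th,
        h_ra=h_ra,
        psi=psi,
        windows=tuple(windows),
        geometry=geometry,
        grid=phantom.grid,
        bins_shape=proj.bins_shape,
        meta={"stray_reference_per_10min": stray_reference},
    )


def simulate_projections(
    sysmat: SystemMatrixSet,
    uptake: RegionalUptake,
    seed: int | np.random.SeedSequence,
) -> ProjectionData:
    """Draw one Poisson realization from the VOI-basis forward model."""
    mean = sysmat.expected_counts(uptake)
    assert np.all(mean >= 0)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean)
    return ProjectionData(
        counts=counts,
        bins_shape=sysmat.bins_shape,
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_projections_from_phantom(
    phantom: Phantom,
    geometry: ScannerGeometry,
    windows: Sequence[EnergyWindow],
    detector: DetectorEnergyModel,
    seed: int | np.random.SeedSequence,
    stray_reference: float = DEFAULT_STRAY_REFERENCE,
    spectra: dict[str, LineSpectrum] | None = None,
) -> ProjectionData:
    """Poisson realization with voxel-mode means (for heterogeneity and
    misregistration studies where the truth is not in the VOI basis)."""
    spectra = spectra or {
        iso: load_builtin_spectrum(iso) for iso in ("Th227", "Ra223chain")
    }
    proj = Projector(phantom.grid, geometry, windows, detector)
    mean = np.zeros(proj.bins_shape)
    for iso in ("Th227", "Ra223chain"):
        mean += proj.project_emission_map(
            phantom.activity(iso), phantom.mu_ref, phantom.tissue_classes,
            spectra[iso],
        )
    bins_per_window = int(np.prod(proj.bins_shape[1:]))
    psi = stray_noise_means(
        stray_reference, windows, geometry.acquisition_time_s, bins_per_window
    )
    mean = mean.ravel() + psi
    rng = np.random.default_rng(seed)
    return ProjectionData(
        counts=rng.poisson(mean),
        bins_shape=proj.bins_shape,
        seed=seed if isinstance(seed, int) else None,
    )


def calibrate_sensitivity(
    phantom: Phantom,
    geometry: ScannerGeometry,
    windows: Sequence[EnergyWindow],
    detector: DetectorEnergyModel,
    target_total_counts: float = 2e5,
    spectra: dict[str, LineSpectrum] | None = None,
) -> ScannerGeometry:
    """Set the sensitivity scale to hit a target detected-count total.

    The returned geometry yields ``target_total_counts`` expected counts
    (both isotopes, all windows, stray noise excluded) for the given
    phantom — the low-count regime dial of the study conditions.
    """
    spectra = spectra or {
        iso: load_builtin_spectrum(iso) for iso in ("Th227", "Ra223chain")
    }
    proj = Projector(phantom.grid, geometry, windows, detector)
    total = 0.0
    for iso in ("Th227", "Ra223chain"):
        total += proj.project_emission_map(
            phantom.activity(iso), phantom.mu_ref, phantom.tissue_classes,
            spectra[iso],
        ).sum()
    if total <= 0:
        raise ValueError("phantom produces no counts; cannot calibrate")
    return geometry.with_sensitivity(
        geometry.sensitivity_scale * target_total_counts / total
    )


# ---------------------------------------------------------------------------
# HDF5 container I/O (layout: /H/Th, /H/Ra, /psi, /meta/...)
# ---------------------------------------------------------------------------


def save_system_matrix(sysmat: SystemMatrixSet, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("H/Th", data=sysmat.h_th)
        f.create_dataset("H/Ra", data=sysmat.h_ra)
        f.create_dataset("psi", data=sysmat.psi)
        meta = f.create_group("meta")
        meta.attrs["bins_shape"] = sysmat.bins_shape
        meta.attrs["grid_shape"] = sysmat.grid.shape
        meta.attrs["voxel_mm"] = sysmat.grid.voxel_mm
        meta.attrs["n_angles"] = sysmat.geometry.n_angles
        meta.attrs["acquisition_time_s"] = sysmat.geometry.acquisition_time_s
        meta.attrs["sensitivity_scale"] = sysmat.geometry.sensitivity_scale
        meta.attrs["window_bounds"] = [
            (w.low_kev, w.high_kev) for w in sysmat.windows
        ]
        meta.attrs["window_indices"] = [w.index for w in sysmat.windows]


def load_system_matrix(path: str | Path) -> SystemMatrixSet:
    import h5py

    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        windows = tuple(
            EnergyWindow(lo, hi, int(idx))
            for (lo, hi), idx in zip(
                meta["window_bounds"], meta["window_indices"]
            )
        )
        geometry = ScannerGeometry(
            n_angles=int(meta["n_angles"]),
            acquisition_time_s=float(meta["acquisition_time_s"]),
            sensitivity_scale=float(meta["sensitivity_scale"]),
        )
        return SystemMatrixSet(
            h_th=f["H/Th"][()],
            h_ra=f["H/Ra"][()],
            psi=f["psi"][()],
            windows=windows,
            geometry=geometry,
            grid=GridSpec(tuple(meta["grid_shape"]), float(meta["voxel_mm"])),
            bins_shape=tuple(meta["bins_shape"]),
        )
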