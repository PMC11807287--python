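"""Emission spectra, energy windows, and the detector energy response.

Th-227 decays by alpha emission to Ra-223, which redistributes in the
patient and decays through a chain of short-lived daughters.  Both parent
and daughter chain emit X- and gamma-ray photons over an overlapping set
of energies, so a gamma camera records a mixture of the two isotopes in
every energy window.  This module holds the bundled line tables and the
Gaussian energy-response model that turns an emission line into a
per-window detection weight.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "EmissionLine",
    "LineSpectrum",
    "EnergyWindow",
    "DetectorEnergyModel",
    "ISOTOPES",
    "load_builtin_spectrum",
    "window_detection_weight",
    "spectrum_window_weights",
    "default_windows",
]

#: Identifiers of the bundled spectra.  ``Ra223chain`` includes the photons
#: emitted by the short-lived daughters of Ra-223 in secular equilibrium.
ISOTOPES = ("Th227", "Ra223chain")

_DATA_FILES = {
    "Th227": "th227_lines.tsv",
    "Ra223chain": "ra223_chain_lines.tsv",
}

_PROVENANCE = (
    "Compiled from published evaluated nuclear decay data "
    "(ICRP Publication 107 / NNDC ENSDF); photons per decay."
)


@dataclass(frozen=True)
class EmissionLine:
    """A single photon emission line."""

    energy_kev: float
    intensity: float  # photons per decay

    def __post_init__(self) -> None:
        if not self.energy_kev > 0:
            raise ValueError(f"line energy must be positive, got {self.energy_kev}")
        if not 0.0 <= self.intensity <= 10.0:
            raise ValueError(f"line intensity out of range: {self.intensity}")


@dataclass(frozen=True)
class LineSpectrum:
    """Ordered photon line table of one isotope (or decay chain)."""

    isotope: str
    lines: tuple[EmissionLine, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        energies = [ln.energy_kev for ln in self.lines]
        if any(b <= a for a, b in zip(energies, energies[1:])):
            raise ValueError("spectrum lines must be strictly increasing in energy")

    @property
    def energies(self) -> np.ndarray:
        return np.array([ln.energy_kev for ln in self.lines])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([ln.intensity for ln in self.lines])

    def __len__(self) -> int:
        return len(self.lines)


@dataclass(frozen=True)
class EnergyWindow:
    """Half-open acquisition energy window [low, high) in keV."""

    low_kev: float
    high_kev: float
    index: int  # 1-based acquisition window number

    def __post_init__(self) -> None:
        if not self.low_kev < self.high_kev:
            raise ValueError(f"window {self.index}: low must be < high")

    @property
    def width_kev(self) -> float:
        return self.high_kev - self.low_kev


@dataclass(frozen=True)
class DetectorEnergyModel:
    """Gaussian energy response of a NaI(Tl) scintillation detector.

    The relative FWHM follows the standard inverse-square-root law for
    scintillators, anchored at ``fwhm_fraction_at_ref`` (default 9.8% at
    140 keV):  FWHM(E) = f_ref * E_ref * sqrt(E / E_ref).  Setting
    ``fwhm_fraction_at_ref`` to 0 disables energy blur (sharp windows).
    """

    fwhm_fraction_at_ref: float = 0.098
    ref_energy_kev: float = 140.0

    def __post_init__(self) -> None:
        if self.fwhm_fraction_at_ref < 0:
            raise ValueError("FWHM fraction must be >= 0")

    def fwhm_kev(self, energy_kev: float | np.ndarray) -> float | np.ndarray:
        e = np.asarray(energy_kev, dtype=float)
        out = self.fwhm_fraction_at_ref * self.ref_energy_kev * np.sqrt(
            e / self.ref_energy_kev
        )
        return out if out.ndim else float(out)

    def sigma_kev(self, energy_kev: float | np.ndarray) -> float | np.ndarray:
        return self.fwhm_kev(energy_kev) / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def default_windows() -> tuple[EnergyWindow, ...]:
    """The four default acquisition windows (keV).

    Chosen to bracket the dominant X-ray region shared by both isotopes
    (window 1), the Ra-223 gammas near 144/154 keV (window 2), the Th-227
    236 keV photopeak (window 3), and the Ra-223/Rn-219 270 keV photopeaks
    together with the upper Th-227 lines (window 4).
    """
    return (
        EnergyWindow(74.0, 94.0, 1),
        EnergyWindow(140.0, 168.0, 2),
        EnergyWindow(216.0, 256.0, 3),
        EnergyWindow(256.0, 288.0, 4),
    )


def validate_windows(windows: Sequence[EnergyWindow]) -> None:
    """Check that windows are sorted and non-overlapping."""
    for a, b in zip(windows, windows[1:]):
        if b.low_kev < a.high_kev:
            raise ValueError(
                f"windows {a.index} and {b.index} overlap or are unsorted"
            )


def load_builtin_spectrum(
    isotope: str, intensity_floor: float = 1e-4
) -> LineSpectrum:
    """Load the bundled line table for ``Th227`` or ``Ra223chain``.

    Lines with intensity below ``intensity_floor`` (photons/decay) are
    dropped to bound the spectrum length.
    """
    if isotope not in _DATA_FILES:
        raise ValueError(
            f"unknown isotope {isotope!r}; expected one of {ISOTOPES}"
        )
    path = importlib.resources.files("mewpdq.data") / _DATA_FILES[isotope]
    lines: list[EmissionLine] = []
    for raw in path.read_text().splitlines():
        raw = raw.strip()
        if not raw or raw.startswith("#"):
            continue
        energy, intensity = (float(tok) for tok in raw.split())
        if intensity >= intensity_floor:
            lines.append(EmissionLine(energy, intensity))
    lines.sort(key=lambda ln: ln.energy_kev)
    return LineSpectrum(isotope=isotope, lines=tuple(lines), provenance=_PROVENANCE)


def window_detection_weight(
    line: EmissionLine, window: EnergyWindow, model: DetectorEnergyModel
) -> float:
    """Expected detected fraction of a line inside one energy window.

    The detector records the line as a Gaussian of FWHM given by the
    energy-response model; the weight is the line intensity times the
    Gaussian mass falling inside the half-open window.
    """
    if model.fwhm_fraction_at_ref == 0.0:
        inside = window.low_kev <= line.energy_kev < window.high_kev
        return line.intensity if inside else 0.0
    sigma = model.sigma_kev(line.energy_kev)
    mass = ndtr((window.high_kev - line.energy_kev) / sigma) - ndtr(
        (window.low_kev - line.energy_kev) / sigma
    )
    return float(line.intensity * mass)


def spectrum_window_weights(
    spectrum: LineSpectrum,
    windows: Sequence[EnergyWindow],
    model: DetectorEnergyModel,
) -> np.ndarray:
    """Per-line, per-window detection weights, shape (n_lines, n_windows)."""
    out = np.empty((len(spectrum), len(windows)))
    for i, line in enumerate(spectrum.lines):
        for j, win in enumerate(windows):
            out[i, j] = window_detection_weight(line, win, model)
    return out


def effective_window_response(
    spectrum: LineSpectrum,
    windows: Sequence[EnergyWindow],
    model: DetectorEnergyModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a line spectrum to one (weight, effective energy) per window.

    The weight is the summed per-line detection weight; the effective
    energy is the weight-averaged line energy, used to evaluate the
    attenuation coefficient once per window instead of once per line.
    Windows with zero weight get the window center as a placeholder energy.
    """
    w = spectrum_window_weights(spectrum, windows, model)
    weights = w.sum(axis=0)
    energies = np.empty(len(windows))
    for j, win in enumerate(windows):
        if weights[j] > 0:
            energies[j] = float(w[:, j] @ spectrum.energies) / weights[j]
        else:
            energies[j] = 0.5 * (win.low_kev + win.high_kev)
    return weights, energies
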