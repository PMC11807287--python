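"""Photon attenuation model for body tissues.

Voxels are assigned one of three tissue classes (air, soft tissue, bone).
Linear attenuation coefficients at any photon energy are obtained from a
bundled mass-attenuation table (water and ICRU-44 cortical bone),
interpolated log-log in energy and scaled by the nominal tissue density.
Phantoms carry their attenuation map at a reference energy of 140 keV;
the projector rescales it per tissue class to the effective energy of
each (isotope, window) pair.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache

import numpy as np

__all__ = [
    "TISSUE_AIR",
    "TISSUE_SOFT",
    "TISSUE_BONE",
    "REFERENCE_ENERGY_KEV",
    "mu_linear",
    "mu_scale_factors",
]

TISSUE_AIR = 0
TISSUE_SOFT = 1
TISSUE_BONE = 2

#: Phantom attenuation maps are stored at this reference energy.
REFERENCE_ENERGY_KEV = 140.0

# Nominal densities, g/cm^3.  Soft tissue is water-equivalent.  The bone
# class covers whole pelvic bone (cortical shell plus trabecular bone and
# marrow), whose volume-averaged density is far below pure cortical bone
# (1.92); 1.40 is a representative spongiosa-dominated average.  The
# mass-attenuation spectrum of cortical bone is retained as the energy
# dependence for the class.
_DENSITY = {TISSUE_SOFT: 1.0, TISSUE_BONE: 1.40}


@lru_cache(maxsize=1)
def _table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = importlib.resources.files("mewpdq.data") / "mass_attenuation.tsv"
    rows = [
        [float(tok) for tok in raw.split()]
        for raw in path.read_text().splitlines()
        if raw.strip() and not raw.startswith("#")
    ]
    arr = np.asarray(rows)
    return arr[:, 0], arr[:, 1], arr[:, 2]


def _interp_mu_over_rho(energy_kev: float, column: np.ndarray) -> float:
    energies, _, _ = _table()
    return float(
        np.exp(np.interp(np.log(energy_kev), np.log(energies), np.log(column)))
    )


def mu_linear(energy_kev: float, tissue_class: int) -> float:
    """Linear attenuation coefficient (1/cm) of one tissue class."""
    if tissue_class == TISSUE_AIR:
        return 0.0
    energies, water, bone = _table()
    if not energies[0] <= energy_kev <= energies[-1]:
        raise ValueError(
            f"energy {energy_kev} keV outside bundled table range "
            f"[{energies[0]}, {energies[-1]}]"
        )
    col = water if tissue_class == TISSUE_SOFT else bone
    return _DENSITY[tissue_class] * _interp_mu_over_rho(energy_kev, col)


def mu_scale_factors(energy_kev: float) -> np.ndarray:
    """Per-class ratio mu(E)/mu(reference), indexed by tissue class.

    Multiplying a reference-energy attenuation map by
    ``mu_scale_factors(E)[tissue_classes]`` yields the map at energy E.
    The air entry is zero by convention (air voxels carry zero mu).
    """
    out = np.zeros(3)
    for cls in (TISSUE_SOFT, TISSUE_BONE):
        out[cls] = mu_linear(energy_kev, cls) / mu_linear(
            REFERENCE_ENERGY_KEV, cls
        )
    return out


def reference_mu_map(tissue_classes: np.ndarray) -> np.ndarray:
    """Attenuation map (1/cm) at the reference energy from a class map."""
    lut = np.array(
        [0.0, mu_linear(REFERENCE_ENERGY_KEV, TISSUE_SOFT),
         mu_linear(REFERENCE_ENERGY_KEV, TISSUE_BONE)]
    )
    return lut[tissue_classes]
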