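"""Figures of merit for regional uptake estimates.

For repeated noise realizations of a single patient with true uptake
``lambda`` and estimates ``lambda_hat_i``:

* NB   = (mean(lambda_hat) - lambda) / lambda          (accuracy)
* NSD  = std_pop(lambda_hat) / lambda                  (precision)
* NRMSE = rms(lambda_hat - lambda) / lambda            (overall error)

The population (1/n) standard deviation is used so the Pythagorean
identity NRMSE^2 = NB^2 + NSD^2 holds exactly.

For a patient population with one realization per patient, the ensemble
variants aggregate the per-patient normalized errors e_p:

* ensemble NB    = | mean_p e_p |   (signed errors average out; a
  nonzero value indicates systematic bias across the population)
* ensemble NRMSE = sqrt( mean_p e_p^2 )
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantoms import VOI_NAMES, RegionalUptake

__all__ = ["MeritReport", "merit_report", "ensemble_merit_report"]

_ISO_BLOCKS = ("Th227", "Ra223chain")


@dataclass
class MeritReport:
    """Per-region, per-isotope merit figures as a tidy table."""

    table: pd.DataFrame  # columns: isotope, region, nb, nsd, nrmse
    n_realizations: int

    def value(self, isotope: str, region: int, figure: str) -> float:
        row = self.table[
            (self.table.isotope == isotope) & (self.table.region == region)
        ]
        return float(row[figure].iloc[0])

    def max_abs(self, figure: str) -> float:
        return float(self.table[figure].abs().max())


def _estimate_vector(est) -> np.ndarray:
    """Composite (2K,) vector from an estimate of any supported shape."""
    if hasattr(est, "lambda_hat"):
        return np.asarray(est.lambda_hat)
    if hasattr(est, "composite"):
        return np.asarray(est.composite())
    return np.asarray(est)


def _stack_estimates(estimates) -> np.ndarray:
    return np.stack([_estimate_vector(e) for e in estimates])  # (n, 2K)


def _truth_vector(truth: RegionalUptake) -> np.ndarray:
    vec = truth.composite()
    if np.any(vec == 0):
        raise ValueError("zero true uptake: normalized figures undefined")
    return vec


def _tidy(values: dict[str, np.ndarray], n_regions: int) -> pd.DataFrame:
    rows = []
    for b, iso in enumerate(_ISO_BLOCKS):
        for k in range(n_regions):
            row = {
                "isotope": iso,
                "region": k + 1,
                "region_name": VOI_NAMES.get(k + 1, str(k + 1)),
            }
            row.update({fig: arr[b * n_regions + k] for fig, arr in values.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def merit_report(estimates, truth: RegionalUptake) -> MeritReport:
    """NB/NSD/NRMSE over noise realizations of a single patient."""
    lam = _truth_vector(truth)
    samples = _stack_estimates(estimates)
    if samples.shape[1] != lam.shape[0]:
        raise ValueError("estimate and truth dimensions disagree")
    n = samples.shape[0]
    if n < 1:
        raise ValueError("need at least one realization")
    nb = (samples.mean(axis=0) - lam) / lam
    nsd = samples.std(axis=0, ddof=0) / lam if n >= 2 else np.zeros_like(lam)
    nrmse = np.sqrt(np.mean((samples - lam) ** 2, axis=0)) / lam
    table = _tidy(
        {"nb": nb, "nsd": nsd, "nrmse": nrmse}, truth.n_regions
    )
    return MeritReport(table=table, n_realizations=n)


def ensemble_merit_report(
    estimates, truths: list[RegionalUptake]
) -> MeritReport:
    """Ensemble NB / ensemble NRMSE over a patient population.

    One estimate per patient; normalized errors are computed against
    each patient's own truth and aggregated across patients.
    """
    if len(estimates) != len(truths):
        raise ValueError("one estimate per patient required")
    if len(truths) < 1:
        raise ValueError("need at least one patient")
    errors = []
    for est, truth in zip(estimates, truths):
        lam = _truth_vector(truth)
        vec = _estimate_vector(est)
        errors.append((vec - lam) / lam)
    err = np.stack(errors)  # (n_patients, 2K)
    ens_nb = np.abs(err.mean(axis=0))
    ens_nrmse = np.sqrt(np.mean(err**2, axis=0))
    table = _tidy(
        {"ensemble_nb": ens_nb, "ensemble_nrmse": ens_nrmse},
        truths[0].n_regions,
    )
    return MeritReport(table=table, n_realizations=len(truths))
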