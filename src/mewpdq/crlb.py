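"""Fisher information and Cramér–Rao bounds for the Poisson model.

For independent Poisson bins with mean ``(H lambda)_m + psi_m`` the
Fisher information for the composite regional-uptake vector is

    F_ab = sum_m H_ma H_mb / ((H lambda)_m + psi_m),

optionally restricted to the rows of a subset of energy windows.  The
CRLB-derived normalized standard deviation (NSD) of parameter ``a`` is
``sqrt((F^{-1})_aa) / lambda_a`` — the precision floor of any unbiased
estimator, used both as a benchmark for the estimator's empirical NSD
and to quantify the information gained by acquiring more energy
windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .system import SystemMatrixSet

__all__ = [
    "FisherInfo",
    "fisher_information",
    "crlb_nsd",
    "window_subset_study",
]


@dataclass
class FisherInfo:
    """Fisher information matrix at a given uptake point."""

    matrix: np.ndarray  # (2K, 2K)
    lambda_point: np.ndarray
    window_subset: tuple[int, ...]

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("Fisher information must be symmetric")


def _as_composite(lam) -> np.ndarray:
    if hasattr(lam, "composite"):
        lam = lam.composite()
    return np.asarray(lam, dtype=float)


def fisher_information(
    sysmat: SystemMatrixSet,
    lam: np.ndarray,
    window_subset: Sequence[int] | None = None,
) -> FisherInfo:
    """Poisson Fisher information restricted to the given 1-based windows.

    ``lam`` may be a composite ``(2K,)`` vector or a ``RegionalUptake``.
    """
    lam = _as_composite(lam)
    h = sysmat.h_composite
    mean = h @ lam + sysmat.psi
    if window_subset is None:
        window_subset = tuple(w.index for w in sysmat.windows)
    rows = sysmat.window_rows(window_subset)
    h_sub, mean_sub = h[rows], mean[rows]
    if np.any(mean_sub <= 0):
        raise ValueError("a retained bin has zero mean; Fisher info undefined")
    weighted = h_sub / mean_sub[:, None]
    f = h_sub.T @ weighted
    f = 0.5 * (f + f.T)  # enforce exact symmetry
    return FisherInfo(matrix=f, lambda_point=lam, window_subset=tuple(window_subset))


def crlb_nsd(
    fisher: FisherInfo,
    lambda_true: np.ndarray,
    allow_pseudo_inverse: bool = False,
) -> np.ndarray:
    """CRLB-derived NSD: sqrt(diag(F^-1)) / lambda, per parameter."""
    lam = _as_composite(lambda_true)
    if np.any(lam <= 0):
        raise ValueError("normalization requires positive true uptake")
    f = fisher.matrix
    cond = np.linalg.cond(f)
    if cond > 1e12:
        if not allow_pseudo_inverse:
            raise np.linalg.LinAlgError(
                f"Fisher information is singular (cond={cond:.2e}); "
                "enable the pseudo-inverse fallback to proceed"
            )
        warnings.warn(
            "Fisher information nearly singular; using an "
            "eigenvalue-floored pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        vals, vecs = np.linalg.eigh(f)
        floor = max(vals.max(), 1.0) * 1e-12
        inv = (vecs / np.maximum(vals, floor)) @ vecs.T
    else:
        inv = np.linalg.inv(f)
    return np.sqrt(np.clip(np.diag(inv), 0.0, None)) / lam


def window_subset_study(
    sysmat: SystemMatrixSet,
    lam: np.ndarray,
    subsets: Sequence[Sequence[int]] = ((1,), (1, 2), (1, 2, 3), (1, 2, 3, 4)),
    allow_pseudo_inverse: bool = True,
) -> dict[tuple[int, ...], np.ndarray]:
    """CRLB-derived NSD per parameter for nested window subsets.

    Adding windows can only add Fisher information, so for nested
    subsets the per-parameter NSD is non-increasing along the sequence.
    Non-nested subsets trigger a warning (monotonicity not guaranteed).
    """
    nested = all(
        set(a).issubset(set(b)) for a, b in zip(subsets, subsets[1:])
    )
    if not nested:
        warnings.warn(
            "window subsets are not nested; CRLB monotonicity is not implied",
            RuntimeWarning,
            stacklevel=2,
        )
    out: dict[tuple[int, ...], np.ndarray] = {}
    for subset in subsets:
        fisher = fisher_information(sysmat, lam, subset)
        out[tuple(subset)] = crlb_nsd(
            fisher, lam, allow_pseudo_inverse=allow_pseudo_inverse
        )
    return out
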