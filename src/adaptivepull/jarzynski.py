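"""Nonequilibrium work averaging: pointwise free-energy estimation over a
work ensemble, the trajectory selector used for stage contraction, and a
jackknife error utility."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import KB
from .curves import PMFCurve
from .errors import ConfigurationError, NumericalError

__all__ = ["WorkEnsemble", "jarzynski_pmf", "je_select", "jackknife_delta_f"]


@dataclass(frozen=True)
class WorkEnsemble:
    """Per-trajectory accumulated external work on a shared lambda grid.

    ``works[i, g]`` is trajectory i's work at grid point g [kcal/mol];
    every trajectory starts at zero work.
    """

    lambda_grid: np.ndarray
    works: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda_grid, dtype=float)
        W = np.asarray(self.works, dtype=float)
        object.__setattr__(self, "lambda_grid", grid)
        object.__setattr__(self, "works", W)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ConfigurationError("WorkEnsemble: lambda grid must be strictly increasing")
        if W.ndim != 2 or W.shape[1] != grid.size:
            raise ConfigurationError("WorkEnsemble: work matrix must be (n_traj, n_grid)")
        if W.shape[0] < 1:
            raise ConfigurationError("WorkEnsemble: at least one trajectory required")
        if not np.all(np.isfinite(W)):
            raise ConfigurationError("WorkEnsemble: non-finite work values")
        if np.any(W[:, 0] != 0.0):
            raise ConfigurationError("WorkEnsemble: W[i, 0] must be exactly 0 for every i")
        if self.temperature <= 0:
            raise ConfigurationError("WorkEnsemble: temperature must be > 0")

    @property
    def n_traj(self) -> int:
        return self.works.shape[0]

    @property
    def end_works(self) -> np.ndarray:
        return self.works[:, -1]


def _log_mean_exp(neg_beta_w: np.ndarray, axis: int = 0) -> np.ndarray:
    n = neg_beta_w.shape[axis]
    return logsumexp(neg_beta_w, axis=axis) - np.log(n)


def jarzynski_pmf(ensemble: WorkEnsemble) -> PMFCurve:
    """Pointwise exponential-average free energy over the work ensemble.

    F(lam_g) = -kT ln (1/N) sum_i exp(-W[i,g]/kT), evaluated in log-space
    so it is stable for works far exceeding kT; F is zero at the first
    grid point because all works start at zero.
    """
    kT = KB * ensemble.temperature
    F = -kT * _log_mean_exp(-ensemble.works / kT, axis=0)
    if not np.all(np.isfinite(F)):
        raise NumericalError("jarzynski_pmf produced non-finite free energies")
    return PMFCurve(ensemble.lambda_grid, F, float(ensemble.lambda_grid[0]))


def je_select(end_works: np.ndarray, F_end: float) -> int:
    """Index of the trajectory whose final work is closest to F_end.

    Ties break to the lowest index (np.argmin semantics).
    """
    w = np.asarray(end_works, dtype=float)
    if w.size == 0:
        raise ConfigurationError("je_select requires a non-empty work list")
    if not (np.all(np.isfinite(w)) and np.isfinite(F_end)):
        raise ConfigurationError("je_select requires finite works and F_end")
    return int(np.argmin(np.abs(w - F_end)))


def jackknife_delta_f(ensemble: WorkEnsemble) -> tuple[float, float]:
    """Leave-one-out jackknife estimate and standard error of the endpoint
    free-energy difference."""
    kT = KB * ensemble.temperature
    z = -ensemble.end_works / kT
    n = z.size
    full = -kT * _log_mean_exp(z)
    if n < 2:
        return float(full), float("inf")
    loo = np.empty(n)
    for i in range(n):
        loo[i] = -kT * (logsumexp(np.delete(z, i)) - np.log(n - 1))
    se = np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2))
    return float(full), float(se)
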