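"""Free-energy profile container shared by the oracle, estimator and runners."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["PMFCurve"]


@dataclass(frozen=True)
class PMFCurve:
    """A free-energy profile F(lambda) on a strictly increasing grid.

    ``F`` is zero at ``reference_lambda``, which must be a grid point.
    Units: lambdas in A, F in kcal/mol.
    """

    lambdas: np.ndarray
    F: np.ndarray
    reference_lambda: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "F", F)
        if lam.ndim != 1 or F.shape != lam.shape:
            raise ConfigurationError("PMFCurve: lambdas and F must be 1-D with equal length")
        if lam.size < 1:
            raise ConfigurationError("PMFCurve: empty grid")
        if lam.size > 1 and not np.all(np.diff(lam) > 0):
            raise ConfigurationError("PMFCurve: lambda grid must be strictly increasing")
        ref = self.reference_lambda
        if ref is None:
            ref = float(lam[0])
            object.__setattr__(self, "reference_lambda", ref)
        idx = self._ref_index(lam, ref)
        if abs(F[idx]) > 1e-9:
            raise ConfigurationError(
                f"PMFCurve: F(reference_lambda={ref}) = {F[idx]!r}, expected 0"
            )

    @staticmethod
    def _ref_index(lam: np.ndarray, ref: float) -> int:
        idx = int(np.argmin(np.abs(lam - ref)))
        if abs(lam[idx] - ref) > 1e-9:
            raise ConfigurationError("PMFCurve: reference_lambda is not a grid point")
        return idx

    @property
    def delta_F(self) -> float:
        """F at the last grid point minus F at the first."""
        return float(self.F[-1] - self.F[0])

    def rereferenced(self, reference_lambda: float) -> "PMFCurve":
        """Shift F so it vanishes at ``reference_lambda``."""
        idx = self._ref_index(self.lambdas, reference_lambda)
        return PMFCurve(self.lambdas, self.F - self.F[idx], reference_lambda)

    def value_at(self, lam: float) -> float:
        """Linear interpolation of F at ``lam`` (must lie inside the grid)."""
        lo, hi = self.lambdas[0], self.lambdas[-1]
        if not (lo - 1e-9 <= lam <= hi + 1e-9):
            raise ConfigurationError(f"lambda={lam} outside PMF grid [{lo}, {hi}]")
        return float(np.interp(lam, self.lambdas, self.F))
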