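"""Analytic toy potentials with exact gradients and a quadrature PMF oracle.

Every model evaluates energies/gradients for a single configuration of
shape ``(dim,)`` or a batch ``(B, dim)``.  The quadrature oracle
:func:`reference_pmf` provides an estimator-independent free-energy
profile for one-dimensional systems, used to validate the nonequilibrium
estimators elsewhere in the package.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import logsumexp

from .constants import KB
from .curves import PMFCurve
from .errors import ConfigurationError, NumericalError

__all__ = [
    "PotentialSpec",
    "PotentialModel",
    "FreePotential",
    "HarmonicPotential",
    "DoubleWellPotential",
    "TiltedDoubleWellPotential",
    "BeadSpringHelixPotential",
    "make_potential",
    "reference_pmf",
]

_KINDS = ("free", "harmonic", "double_well", "tilted_double_well", "bead_spring_helix")


@dataclass(frozen=True)
class PotentialSpec:
    """Declarative description of a toy potential.

    params (by kind):
      harmonic:            a   [kcal/mol/A^2] stiffness
      double_well:         h   [kcal/mol] barrier height, w [A] half well separation
      tilted_double_well:  h, w as above, c [kcal/mol/A] linear tilt
      bead_spring_helix:   n_beads, bond_k, bond_r0, contact_eps,
                           contact_r0, contact_sigma
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)
    dimension: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"unknown potential kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.dimension < 1:
            raise ConfigurationError("dimension must be >= 1")
        for name in ("a", "h", "bond_k", "contact_eps"):
            if name in self.params and self.params[name] < 0:
                raise ConfigurationError(f"parameter {name!r} must be >= 0")
        if self.kind == "bead_spring_helix":
            n = int(self._require("n_beads"))
            if self.dimension != 3 * n:
                raise ConfigurationError(
                    f"bead_spring_helix requires dimension = 3*n_beads = {3 * n}, "
                    f"got {self.dimension}"
                )

    def _require(self, name: str) -> float:
        if name not in self.params:
            raise ConfigurationError(
                f"potential kind {self.kind!r} is missing required parameter {name!r}"
            )
        return float(self.params[name])


def _batched(x: np.ndarray, dim: int) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        if x.shape[0] != dim:
            raise ConfigurationError(f"expected {dim} coordinates, got {x.shape[0]}")
        return x[None, :], True
    if x.ndim == 2 and x.shape[1] == dim:
        return x, False
    raise ConfigurationError(f"coordinate array of shape {x.shape} incompatible with dim={dim}")


class PotentialModel(ABC):
    """Evaluatable energy U(x) and gradient dU/dx over system coordinates."""

    dimension: int
    #: curvature scale of the stiffest quadratic term [kcal/mol/A^2]; used
    #: to size quadrature windows.  0 for a flat potential.
    stiffness_scale: float = 0.0
    #: characteristic spatial extent of structure in U (well positions etc.) [A]
    extent: float = 0.0

    @abstractmethod
    def _energy(self, x: np.ndarray) -> np.ndarray:  # (B, dim) -> (B,)
        ...

    @abstractmethod
    def _gradient(self, x: np.ndarray) -> np.ndarray:  # (B, dim) -> (B, dim)
        ...

    def energy(self, x: np.ndarray):
        xb, single = _batched(x, self.dimension)
        e = self._energy(xb)
        return float(e[0]) if single else e

    def gradient(self, x: np.ndarray) -> np.ndarray:
        xb, single = _batched(x, self.dimension)
        g = self._gradient(xb)
        return g[0] if single else g


class FreePotential(PotentialModel):
    """U identically zero."""

    def __init__(self, dimension: int = 1):
        self.dimension = dimension

    def _energy(self, x):
        return np.zeros(x.shape[0])

    def _gradient(self, x):
        return np.zeros_like(x)


class HarmonicPotential(PotentialModel):
    """Isotropic harmonic well U = a |x|^2 / 2."""

    def __init__(self, a: float, dimension: int = 1):
        self.a = float(a)
        self.dimension = dimension
        self.stiffness_scale = self.a

    def _energy(self, x):
        return 0.5 * self.a * np.sum(x * x, axis=1)

    def _gradient(self, x):
        return self.a * x


class DoubleWellPotential(PotentialModel):
    """Symmetric quartic double well U = h ((x/w)^2 - 1)^2 (1-D).

    Minima at x = +-w with U = 0; barrier of height h at x = 0.
    """

    def __init__(self, h: float, w: float):
        if w <= 0:
            raise ConfigurationError("double_well parameter w must be > 0")
        self.h = float(h)
        self.w = float(w)
        self.dimension = 1
        self.stiffness_scale = 8.0 * self.h / self.w**2  # curvature at the minima
        self.extent = self.w

    def _energy(self, x):
        s = (x[:, 0] / self.w) ** 2 - 1.0
        return self.h * s * s

    def _gradient(self, x):
        u = x[:, 0]
        g = 4.0 * self.h * u * ((u / self.w) ** 2 - 1.0) / self.w**2
        return g[:, None]


class TiltedDoubleWellPotential(DoubleWellPotential):
    """Double well with a linear tilt: U = h ((x/w)^2 - 1)^2 + c x."""

    def __init__(self, h: float, w: float, c: float):
        super().__init__(h, w)
        self.c = float(c)

    def _energy(self, x):
        return super()._energy(x) + self.c * x[:, 0]

    def _gradient(self, x):
        return super()._gradient(x) + np.array([[self.c]])


class BeadSpringHelixPotential(PotentialModel):
    """Coarse bead chain: bonded springs plus attractive i,i+4 Gaussian contacts.

    U = sum_i bond_k/2 (|r_{i+1}-r_i| - bond_r0)^2
        - sum_i contact_eps * exp(-(|r_{i+4}-r_i| - contact_r0)^2 / (2 contact_sigma^2))
    """

    def __init__(
        self,
        n_beads: int,
        bond_k: float,
        bond_r0: float,
        contact_eps: float = 0.0,
        contact_r0: float = 5.0,
        contact_sigma: float = 1.0,
    ):
        if n_beads < 2:
            raise ConfigurationError("bead_spring_helix requires n_beads >= 2")
        self.n_beads = int(n_beads)
        self.bond_k = float(bond_k)
        self.bond_r0 = float(bond_r0)
        self.contact_eps = float(contact_eps)
        self.contact_r0 = float(contact_r0)
        self.contact_sigma = float(contact_sigma)
        self.dimension = 3 * self.n_beads
        self.stiffness_scale = self.bond_k
        self.extent = self.bond_r0 * self.n_beads

    def _pairs(self):
        n = self.n_beads
        bonds = [(i, i + 1) for i in range(n - 1)]
        contacts = [(i, i + 4) for i in range(n - 4)] if self.contact_eps else []
        return bonds, contacts

    def _energy(self, x):
        r = x.reshape(x.shape[0], self.n_beads, 3)
        bonds, contacts = self._pairs()
        e = np.zeros(x.shape[0])
        for i, j in bonds:
            d = np.linalg.norm(r[:, j] - r[:, i], axis=1)
            e += 0.5 * self.bond_k * (d - self.bond_r0) ** 2
        for i, j in contacts:
            d = np.linalg.norm(r[:, j] - r[:, i], axis=1)
            e -= self.contact_eps * np.exp(
                -((d - self.contact_r0) ** 2) / (2.0 * self.contact_sigma**2)
            )
        return e

    def _gradient(self, x):
        r = x.reshape(x.shape[0], self.n_beads, 3)
        g = np.zeros_like(r)
        bonds, contacts = self._pairs()
        for i, j in bonds:
            dv = r[:, j] - r[:, i]
            d = np.linalg.norm(dv, axis=1, keepdims=True)
            u = dv / np.where(d > 0, d, 1.0)
            f = self.bond_k * (d - self.bond_r0) * u
            g[:, j] += f
            g[:, i] -= f
        for i, j in contacts:
            dv = r[:, j] - r[:, i]
            d = np.linalg.norm(dv, axis=1, keepdims=True)
            u = dv / np.where(d > 0, d, 1.0)
            gauss = np.exp(-((d - self.contact_r0) ** 2) / (2.0 * self.contact_sigma**2))
            f = self.contact_eps * (d - self.contact_r0) / self.contact_sigma**2 * gauss * u
            g[:, j] += f
            g[:, i] -= f
        return g.reshape(x.shape)


def make_potential(spec: PotentialSpec) -> PotentialModel:
    """Instantiate a :class:`PotentialModel` from a validated spec."""
    k, p = spec.kind, spec
    if k == "free":
        return FreePotential(spec.dimension)
    if k == "harmonic":
        return HarmonicPotential(p._require("a"), spec.dimension)
    if k == "double_well":
        return DoubleWellPotential(p._require("h"), p._require("w"))
    if k == "tilted_double_well":
        return TiltedDoubleWellPotential(p._require("h"), p._require("w"), p._require("c"))
    if k == "bead_spring_helix":
        return BeadSpringHelixPotential(
            int(p._require("n_beads")),
            p._require("bond_k"),
            p._require("bond_r0"),
            float(spec.params.get("contact_eps", 0.0)),
            float(spec.params.get("contact_r0", 5.0)),
            float(spec.params.get("contact_sigma", 1.0)),
        )
    raise ConfigurationError(f"unknown potential kind {k!r}")  # pragma: no cover


def reference_pmf(
    potential: PotentialModel,
    k: float,
    lambda_grid: np.ndarray,
    temperature: float,
    n_points: int = 2**13 + 1,
    pad_sigmas: float = 10.0,
) -> PMFCurve:
    """Exact (quadrature) free-energy profile of a 1-D guided system.

    F(lam) = -kT ln Integral exp(-[U(x) + k/2 (x - lam)^2]/kT) dx,
    re-referenced to zero at the first grid point.  The integration window
    covers the grid plus the potential's structural extent, padded by
    ``pad_sigmas`` thermal widths of the stiffest quadratic term.  A
    grid-refinement self-check (half resolution vs full) guards against
    under-resolution.
    """
    if potential.dimension != 1:
        raise ConfigurationError("reference_pmf supports 1-D potentials only")
    if temperature <= 0:
        raise ConfigurationError("reference_pmf requires temperature > 0")
    lam = np.asarray(lambda_grid, dtype=float)
    kT = KB * temperature
    stiff = max(potential.stiffness_scale, k, 1e-12)
    sigma = np.sqrt(kT / stiff)
    pad = pad_sigmas * sigma + potential.extent
    lo = min(lam.min(), -potential.extent) - pad
    hi = max(lam.max(), potential.extent) + pad

    def profile(n: int) -> np.ndarray:
        x = np.linspace(lo, hi, n)
        dx = x[1] - x[0]
        U = potential.energy(x[:, None])
        out = np.empty(lam.size)
        for g, l in enumerate(lam):
            E = U + 0.5 * k * (x - l) ** 2
            out[g] = -kT * (logsumexp(-E / kT) + np.log(dx))
        return out

    F = profile(n_points)
    F_coarse = profile(n_points // 2 + 1)
    err = np.max(np.abs((F - F[0]) - (F_coarse - F_coarse[0])))
    if not np.isfinite(err) or err > 1e-8:
        raise NumericalError(
            f"reference_pmf quadrature not converged: refinement residual {err:.3e} "
            f"(window [{lo:.2f}, {hi:.2f}], {n_points} points)"
        )
    return PMFCurve(lam, F - F[0], float(lam[0]))
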