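"""Langevin dynamics under a moving harmonic guide, with work accounting.

The integrator is a BAOAB splitting; the guide contributes a potential
k/2 (xi(x) - lambda(t))^2 whose minimum moves at constant velocity in
pull mode and is stationary in hold mode.  External work is accumulated
in the thermodynamic-integration form dW = k (lambda - xi) dlambda/dt dt
by the trapezoidal rule, so a stationary guide performs exactly zero work.

All ensemble propagation in the package funnels through
:func:`integrate_batch`, which advances B trajectories in lock-step with
per-trajectory noise streams; a single trajectory is a batch of one, so
scalar and ensemble code paths are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .constants import A_PER_NS_TO_A_PER_PS, KB
from .errors import ConfigurationError, GeometryError, IntegrationError

__all__ = [
    "LangevinParams",
    "SteeringProtocol",
    "SystemState",
    "WorkTrace",
    "IdentityCoordinate",
    "DistanceCoordinate",
    "langevin_step",
    "steered_segment",
    "relax_segment",
    "integrate_batch",
]

_NOISE_CHUNK = 4096  # steps of pre-generated noise held in memory at once


class IdentityCoordinate:
    """Reaction coordinate equal to one Cartesian coordinate (1-D toys)."""

    def __init__(self, index: int = 0):
        self.index = int(index)

    def value(self, x: np.ndarray) -> np.ndarray:  # (B, dim) -> (B,)
        return x[:, self.index]

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        g[:, self.index] = 1.0
        return g

    def dof_indices(self, dim: int) -> np.ndarray:
        return np.array([self.index])


class DistanceCoordinate:
    """Distance between two tagged atoms of a 3-D bead system."""

    def __init__(self, atom_i: int, atom_j: int):
        if atom_i == atom_j:
            raise ConfigurationError("DistanceCoordinate requires two distinct atoms")
        self.atom_i = int(atom_i)
        self.atom_j = int(atom_j)

    def _diff(self, x: np.ndarray) -> np.ndarray:
        r = x.reshape(x.shape[0], -1, 3)
        return r[:, self.atom_j] - r[:, self.atom_i]

    def value(self, x: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(self._diff(x), axis=1)
        if np.any(d < 1e-10):
            raise GeometryError("tagged atoms coincide; reaction coordinate undefined")
        return d

    def gradient(self, x: np.ndarray) -> np.ndarray:
        dv = self._diff(x)
        d = np.linalg.norm(dv, axis=1, keepdims=True)
        if np.any(d < 1e-10):
            raise GeometryError("tagged atoms coincide; reaction coordinate undefined")
        u = dv / d
        g = np.zeros((x.shape[0], x.shape[1] // 3, 3))
        g[:, self.atom_j] = u
        g[:, self.atom_i] = -u
        return g.reshape(x.shape)

    def dof_indices(self, dim: int) -> np.ndarray:
        idx = []
        for a in (self.atom_i, self.atom_j):
            idx.extend(range(3 * a, 3 * a + 3))
        return np.array(idx)


@dataclass(frozen=True)
class LangevinParams:
    """Thermostat and integration parameters.

    temperature [K], friction [1/ps], timestep [ps]; masses either a
    scalar or a per-degree-of-freedom array in kcal/mol ps^2/A^2.
    """

    temperature: float
    friction: float
    timestep: float
    masses: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ConfigurationError("temperature must be >= 0")
        if self.friction < 0:
            raise ConfigurationError("friction must be >= 0")
        if self.timestep <= 0:
            raise ConfigurationError("timestep must be > 0")
        if np.any(np.asarray(self.masses) <= 0):
            raise ConfigurationError("masses must be > 0")


@dataclass(frozen=True)
class SteeringProtocol:
    """Moving-guide definition.

    ``velocity`` is quoted in A/ns (the user-facing convention) and
    converted internally; ``lam_start``/``lam_end`` in A.  In hold mode
    the guide minimum stays at ``lam_start``.
    """

    xi: IdentityCoordinate | DistanceCoordinate
    k: float
    lam_start: float
    lam_end: float
    velocity: float
    mode: str = "pull"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigurationError("spring constant k must be > 0")
        if self.mode not in ("pull", "hold"):
            raise ConfigurationError(f"unknown steering mode {self.mode!r}")
        if self.mode == "pull" and self.velocity <= 0:
            raise ConfigurationError("pulling velocity must be > 0 in pull mode")

    @property
    def v_ps(self) -> float:
        """Signed guide velocity in A/ps (0 in hold mode)."""
        if self.mode == "hold":
            return 0.0
        return np.sign(self.lam_end - self.lam_start) * self.velocity * A_PER_NS_TO_A_PER_PS

    @property
    def duration(self) -> float:
        """Pull duration in ps (0 in hold mode)."""
        if self.mode == "hold":
            return 0.0
        return abs(self.lam_end - self.lam_start) / abs(self.v_ps)

    def with_segment(self, lam_start: float, lam_end: float) -> "SteeringProtocol":
        return replace(self, lam_start=lam_start, lam_end=lam_end)


@dataclass
class SystemState:
    """Positions/velocities snapshot of one trajectory."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    stream_key: tuple = ()

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ConfigurationError("positions and velocities must have matching shapes")

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(), self.time, self.stream_key)


@dataclass(frozen=True)
class WorkTrace:
    """External work and coordinates sampled on the guide's lambda grid."""

    times: np.ndarray
    lambdas: np.ndarray
    xis: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("lambdas", "xis", "W"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError(f"WorkTrace field {name} length mismatch")
        if n and self.W[0] != 0.0:
            raise ConfigurationError("WorkTrace must start at W = 0")


def _substeps(delta_lam: float, v_ps: float, dt: float) -> tuple[int, float]:
    """Integer substep count landing exactly on the next grid point."""
    span = abs(delta_lam / v_ps)
    n = max(1, round(span / dt))
    return n, span / n


def integrate_batch(
    x: np.ndarray,
    v: np.ndarray,
    potential,
    steering: Optional[SteeringProtocol],
    params: LangevinParams,
    rngs: Sequence[np.random.Generator],
    record_grid: Optional[np.ndarray] = None,
    duration: Optional[float] = None,
    frozen_dofs: Optional[np.ndarray] = None,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Advance B trajectories in lock-step.

    Pull mode: ``record_grid`` (monotone along the pull, both endpoints
    included) defines where work and coordinates are sampled; the step
    size is adjusted per grid interval so samples land exactly on grid
    points.  Hold/relax mode: ``duration`` sets the integration time and
    no work is accumulated (W stays exactly 0).

    Returns ``(traj, xis, W, x_final, v_final)`` with traj of shape
    (B, G, dim), xis and W of shape (B, G).
    """
    x = np.array(x, dtype=float)
    v = np.array(v, dtype=float)
    B, dim = x.shape
    if len(rngs) != B:
        raise ConfigurationError("one RNG stream per trajectory is required")

    m = np.broadcast_to(np.asarray(params.masses, dtype=float), (dim,))
    dt_nom = params.timestep
    kT = KB * params.temperature
    pulling = steering is not None and steering.mode == "pull"

    if pulling:
        grid = np.asarray(record_grid, dtype=float)
        sgn = np.sign(steering.lam_end - steering.lam_start)
        if grid.size < 2 or not np.all(np.diff(grid) * sgn > 0):
            raise ConfigurationError("record_grid must be monotone along the pull")
        if grid[0] != steering.lam_start or grid[-1] != steering.lam_end:
            raise ConfigurationError("record_grid must include both pull endpoints")
        v_ps = steering.v_ps
        intervals = [_substeps(grid[g + 1] - grid[g], v_ps, dt_nom) for g in range(grid.size - 1)]
    else:
        if duration is None:
            raise ConfigurationError("duration required when not pulling")
        n_hold = max(1, round(duration / dt_nom)) if duration > 0 else 0
        dt_hold = duration / n_hold if n_hold else dt_nom
        grid_t = np.array([t0, t0 + duration]) if duration > 0 else np.array([t0])
        lam_hold = steering.lam_start if steering is not None else np.nan
        grid = np.full(grid_t.shape, lam_hold)
        intervals = [(n_hold, dt_hold)] if n_hold else []
        v_ps = 0.0

    G = grid.size
    traj = np.empty((B, G, dim))
    xis = np.full((B, G), np.nan)
    W = np.zeros((B, G))

    k = steering.k if steering is not None else 0.0
    xi = steering.xi if steering is not None else None

    def total_force(xb: np.ndarray, lam: float) -> np.ndarray:
        F = -potential.gradient(xb)
        if steering is not None:
            F = F - k * (xi.value(xb) - lam)[:, None] * xi.gradient(xb)
        if frozen_dofs is not None:
            F[:, frozen_dofs] = 0.0
        return F

    if frozen_dofs is not None:
        v[:, frozen_dofs] = 0.0

    t = t0
    lam = grid[0] if steering is not None else np.nan
    traj[:, 0] = x
    if xi is not None:
        xis[:, 0] = xi.value(x)
    F = total_force(x, lam)
    Wacc = np.zeros(B)

    for g, (n_sub, dt) in enumerate(intervals):
        c1 = np.exp(-params.friction * dt)
        sig = np.sqrt(kT * (1.0 - c1 * c1) / m)  # (dim,)
        half = 0.5 * dt
        done = 0
        while done < n_sub:
            chunk = min(_NOISE_CHUNK, n_sub - done)
            noise = np.stack([r.standard_normal((chunk, dim)) for r in rngs], axis=0)
            if frozen_dofs is not None:
                noise[:, :, frozen_dofs] = 0.0
            for s in range(chunk):
                lam0 = lam
                lam1 = lam + v_ps * dt
                if pulling:
                    f0 = k * (lam0 - xi.value(x)) * v_ps
                v = v + half * F / m
                x = x + half * v
                v = c1 * v + sig * noise[:, s]
                x = x + half * v
                F = total_force(x, lam1)
                v = v + half * F / m
                if pulling:
                    f1 = k * (lam1 - xi.value(x)) * v_ps
                    Wacc = Wacc + 0.5 * (f0 + f1) * dt
                lam = lam1
                t += dt
            done += chunk
        if not np.all(np.isfinite(x)):
            bad = np.argwhere(~np.isfinite(x))[0]
            raise IntegrationError(
                f"non-finite position at t={t:.6g} ps (trajectory {bad[0]}, dof {bad[1]})"
            )
        if pulling:
            lam = grid[g + 1]  # clamp accumulated rounding
        traj[:, g + 1] = x
        if xi is not None:
            xis[:, g + 1] = xi.value(x)
        W[:, g + 1] = Wacc

    return traj, xis, W, x, v


def langevin_step(
    state: SystemState,
    potential,
    guide: Optional[SteeringProtocol],
    params: LangevinParams,
    rng: np.random.Generator,
) -> SystemState:
    """One BAOAB step; the guide (if any) is treated at its current lambda.

    Convenience wrapper over :func:`integrate_batch` with a batch of one
    and a stationary guide for the duration of the step.
    """
    hold = None
    if guide is not None:
        lam_now = guide.lam_start + guide.v_ps * (state.time - 0.0)
        hold = replace(guide, mode="hold", lam_start=lam_now, lam_end=lam_now, velocity=guide.velocity)
    _, _, _, xf, vf = integrate_batch(
        state.positions[None, :],
        state.velocities[None, :],
        potential,
        hold,
        params,
        [rng],
        duration=params.timestep,
        t0=state.time,
    )
    return SystemState(xf[0], vf[0], state.time + params.timestep, state.stream_key)


def steered_segment(
    state: SystemState,
    potential,
    steering: SteeringProtocol,
    params: LangevinParams,
    rng: np.random.Generator,
    record_grid: np.ndarray,
) -> tuple[np.ndarray, WorkTrace, SystemState]:
    """Pull a single trajectory across one lambda segment.

    Returns (coordinates at the record grid, WorkTrace, final state).
    In hold mode the work trace is exactly zero throughout.
    """
    if steering.mode == "hold":
        raise ConfigurationError("use relax_segment for hold-mode propagation")
    traj, xis, W, xf, vf = integrate_batch(
        state.positions[None, :],
        state.velocities[None, :],
        potential,
        steering,
        params,
        [rng],
        record_grid=record_grid,
        t0=state.time,
    )
    grid = np.asarray(record_grid, dtype=float)
    times = state.time + np.abs(grid - grid[0]) / abs(steering.v_ps)
    trace = WorkTrace(times, grid, xis[0], W[0])
    final = SystemState(xf[0], vf[0], times[-1], state.stream_key)
    return traj[0], trace, final


def relax_segment(
    state: SystemState,
    potential,
    params: LangevinParams,
    rng: np.random.Generator,
    duration: float,
    frozen_dofs: Optional[np.ndarray] = None,
    hold_guide: Optional[SteeringProtocol] = None,
) -> tuple[SystemState, WorkTrace]:
    """Constrained relaxation: free dynamics with either the tagged
    degrees of freedom frozen (default) or a stationary guide held.

    Performs exactly zero external work by construction; the returned
    WorkTrace asserts it.
    """
    guide = None
    if hold_guide is not None:
        guide = replace(hold_guide, mode="hold", lam_end=hold_guide.lam_start)
    _, _, W, xf, vf = integrate_batch(
        state.positions[None, :],
        state.velocities[None, :],
        potential,
        guide,
        params,
        [rng],
        duration=duration,
        frozen_dofs=frozen_dofs,
        t0=state.time,
    )
    assert np.all(W == 0.0), "relaxation must perform zero work"
    times = np.array([state.time, state.time + duration]) if duration > 0 else np.array([state.time])
    lam = np.full_like(times, hold_guide.lam_start if hold_guide else np.nan)
    trace = WorkTrace(times, lam, np.full_like(times, np.nan), np.zeros_like(times))
    return SystemState(xf[0], vf[0], state.time + duration, state.stream_key), trace
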