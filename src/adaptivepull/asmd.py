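"""Stage orchestration: plain SMD, naive adaptive staging with
JE-criterion ensemble contraction, and full-relaxation staging with
zero-work constrained relaxation between pulls.

RNG scheme: a master seed is split into independent per-(stage,
trajectory, phase) streams through ``numpy`` SeedSequence spawn keys
(phase 0 = pulling, phase 1 = relaxation), so full runs reproduce
bit-identically from the master seed while every trajectory sees its own
noise sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .constants import KB
from .curves import PMFCurve
from .dynamics import (
    LangevinParams,
    SteeringProtocol,
    SystemState,
    integrate_batch,
)
from .errors import ConfigurationError
from .jarzynski import WorkEnsemble, jarzynski_pmf, je_select
from .potentials import PotentialModel

__all__ = [
    "System",
    "StagePlan",
    "StageResult",
    "stream",
    "run_smd",
    "run_naive_asmd",
    "run_fr_asmd",
    "assemble_pmf",
]

log = logging.getLogger(__name__)

DEFAULT_RECORD_SPACING = 0.1  # A


def stream(master_seed: int, stage: int, traj: int, phase: int = 0) -> np.random.Generator:
    """Independent, reproducible RNG stream for one (stage, trajectory, phase)."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(stage, traj, phase))
    )


@dataclass
class System:
    """A potential plus the common initial state of all trajectories.

    ``frozen_dofs`` are the degrees of freedom held fixed during
    constrained relaxation (defaults to those of the steering
    coordinate's tagged atoms).
    """

    potential: PotentialModel
    initial_state: SystemState
    frozen_dofs: Optional[np.ndarray] = None

    def relax_dofs(self, steering: SteeringProtocol) -> np.ndarray:
        if self.frozen_dofs is not None:
            return self.frozen_dofs
        return steering.xi.dof_indices(self.potential.dimension)


@dataclass(frozen=True)
class StagePlan:
    """Ordered pulling segments plus per-stage sampling settings.

    Defaults follow the benchmark protocol: ten contiguous 2 A segments
    spanning 13 -> 33 A with 100 ps of inter-stage relaxation.
    """

    segments: tuple = ()
    tps: int = 100
    t_relax: float = 100.0
    record_spacing: float = DEFAULT_RECORD_SPACING

    def __post_init__(self) -> None:
        if not self.segments:
            object.__setattr__(self, "segments", tuple(self.default_segments()))
        segs = tuple((float(a), float(b)) for a, b in self.segments)
        object.__setattr__(self, "segments", segs)
        for i, (a, b) in enumerate(segs):
            if b <= a:
                raise ConfigurationError("StagePlan: segments must increase in lambda")
            if i and a != segs[i - 1][1]:
                raise ConfigurationError(
                    f"StagePlan: segment {i} starts at {a}, expected {segs[i - 1][1]} (contiguity)"
                )
        if self.tps < 1:
            raise ConfigurationError("StagePlan: tps must be >= 1")
        if self.t_relax < 0:
            raise ConfigurationError("StagePlan: t_relax must be >= 0")
        if self.record_spacing <= 0:
            raise ConfigurationError("StagePlan: record_spacing must be > 0")

    @staticmethod
    def default_segments(lam_start: float = 13.0, lam_end: float = 33.0, n: int = 10) -> list:
        edges = np.linspace(lam_start, lam_end, n + 1)
        return [(float(edges[i]), float(edges[i + 1])) for i in range(n)]

    @property
    def lam_start(self) -> float:
        return self.segments[0][0]

    @property
    def lam_end(self) -> float:
        return self.segments[-1][1]

    def as_single_segment(self) -> "StagePlan":
        return StagePlan(
            segments=((self.lam_start, self.lam_end),),
            tps=self.tps,
            t_relax=self.t_relax,
            record_spacing=self.record_spacing,
        )

    def stage_grid(self, stage: int) -> np.ndarray:
        """Recording grid of one stage; endpoints exact, spacing ~record_spacing."""
        a, b = self.segments[stage]
        n = max(1, round((b - a) / self.record_spacing))
        grid = a + (b - a) * np.arange(n + 1) / n
        grid[0], grid[-1] = a, b
        return grid


@dataclass
class StageResult:
    """Everything produced by one pulling stage.

    ``ensemble`` holds stage-relative works (zero at the stage start);
    ``pmf`` is the stage free-energy curve, zero at the stage start.
    """

    stage: int
    ensemble: WorkEnsemble
    pmf: PMFCurve
    final_states: list
    selected: Optional[int] = None
    record: dict = field(default_factory=dict)


def _stage_f_end(end_works: np.ndarray, T: float) -> float:
    kT = KB * T
    return float(-kT * (logsumexp(-end_works / kT) - np.log(end_works.size)))


def run_smd(
    system: System,
    steering: SteeringProtocol,
    plan: StagePlan,
    params: LangevinParams,
    master_seed: int = 0,
) -> StageResult:
    """Single-stage steered run: N independent pulls over the full path
    from a common initial state, averaged with the exponential estimator.

    A degenerate case of naive staging, and implemented as such so the
    two are bit-identical under matched seeds.
    """
    results, _ = run_naive_asmd(system, steering, plan.as_single_segment(), params, master_seed)
    return results[0]


def run_naive_asmd(
    system: System,
    steering: SteeringProtocol,
    plan: StagePlan,
    params: LangevinParams,
    master_seed: int = 0,
) -> tuple[list, PMFCurve]:
    """Adaptive staging with JE-criterion contraction.

    Each stage pulls ``tps`` trajectories from a shared start under fresh
    noise streams; the trajectory whose final work lands closest to the
    stage free energy donates its coordinates and velocities to the next
    stage's common start.
    """
    B = plan.tps
    state = system.initial_state
    xs = np.repeat(state.positions[None, :], B, axis=0)
    vs = np.repeat(state.velocities[None, :], B, axis=0)
    t = state.time
    results: list[StageResult] = []
    for s, (a, b) in enumerate(plan.segments):
        st = steering.with_segment(a, b)
        grid = plan.stage_grid(s)
        rngs = [stream(master_seed, s, i, 0) for i in range(B)]
        _, _, W, xf, vf = integrate_batch(
            xs, vs, system.potential, st, params, rngs, record_grid=grid, t0=t
        )
        t += st.duration
        ens = WorkEnsemble(grid, W, params.temperature)
        pmf = jarzynski_pmf(ens)
        F_end = _stage_f_end(W[:, -1], params.temperature)
        sel = je_select(W[:, -1], F_end)
        results.append(
            StageResult(
                stage=s,
                ensemble=ens,
                pmf=pmf,
                final_states=[SystemState(xf[i], vf[i], t, (s, i)) for i in range(B)],
                selected=sel,
                record={
                    "n_traj": B,
                    "mean_W": float(W[:, -1].mean()),
                    "F_end": F_end,
                    "selected": sel,
                },
            )
        )
        log.info("stage %d: N=%d <W>=%.4f F_end=%.4f selected=%d",
                 s, B, results[-1].record["mean_W"], F_end, sel)
        xs = np.repeat(xf[sel][None, :], B, axis=0)
        vs = np.repeat(vf[sel][None, :], B, axis=0)
    return results, assemble_pmf(results)


def run_fr_asmd(
    system: System,
    steering: SteeringProtocol,
    plan: StagePlan,
    params: LangevinParams,
    master_seed: int = 0,
    relax_mode: str = "freeze",
    continuous_streams: bool = False,
) -> tuple[list, PMFCurve]:
    """Full-relaxation staging: every trajectory continues itself through
    all stages, with a zero-work constrained relaxation between pulls.

    ``relax_mode='freeze'`` pins the tagged degrees of freedom (default);
    ``'hold_spring'`` keeps the guide active at the stage-end position.
    Both perform exactly zero external work.  Because trajectories are
    continuous, each stage's free-energy curve is computed from the
    trajectories' cumulative works (re-zeroed at the stage start), which
    makes the assembled profile identical to a single exponential average
    over the cumulative works.  With ``continuous_streams=True`` each
    trajectory keeps one noise stream across stages (stage-0 keys), so a
    zero-relaxation run is bit-identical to plain SMD on the full path.
    """
    if relax_mode not in ("freeze", "hold_spring"):
        raise ConfigurationError(f"unknown relax_mode {relax_mode!r}")
    B = plan.tps
    state = system.initial_state
    xs = np.repeat(state.positions[None, :], B, axis=0)
    vs = np.repeat(state.velocities[None, :], B, axis=0)
    t = state.time
    Wcum = np.zeros(B)
    F_origin = 0.0  # exponential-average free energy at the current stage start
    results: list[StageResult] = []
    frozen = system.relax_dofs(steering)
    kT = KB * params.temperature
    if continuous_streams:
        pull_rngs = [stream(master_seed, 0, i, 0) for i in range(B)]
    for s, (a, b) in enumerate(plan.segments):
        st = steering.with_segment(a, b)
        grid = plan.stage_grid(s)
        rngs = pull_rngs if continuous_streams else [stream(master_seed, s, i, 0) for i in range(B)]
        _, _, W, xf, vf = integrate_batch(
            xs, vs, system.potential, st, params, rngs, record_grid=grid, t0=t
        )
        t += st.duration
        Wtot = W + Wcum[:, None]  # cumulative work at every grid point of this stage
        F_cum = -kT * (logsumexp(-Wtot / kT, axis=0) - np.log(B))
        pmf = PMFCurve(grid, F_cum - F_origin, float(grid[0]))
        results.append(
            StageResult(
                stage=s,
                ensemble=WorkEnsemble(grid, W, params.temperature),
                pmf=pmf,
                final_states=[SystemState(xf[i], vf[i], t, (s, i)) for i in range(B)],
                selected=None,
                record={
                    "n_traj": B,
                    "mean_W": float(W[:, -1].mean()),
                    "F_end": float(pmf.F[-1]),
                    "relax_mode": relax_mode,
                },
            )
        )
        log.info("stage %d: N=%d <W>=%.4f F_end=%.4f (FR)",
                 s, B, results[-1].record["mean_W"], results[-1].record["F_end"])
        Wcum = Wtot[:, -1]
        F_origin = float(F_cum[-1])
        xs, vs = xf, vf
        if plan.t_relax > 0 and s < len(plan.segments) - 1:
            relax_rngs = (
                pull_rngs if continuous_streams
                else [stream(master_seed, s, i, 1) for i in range(B)]
            )
            guide = replace(st, mode="hold", lam_start=b) if relax_mode == "hold_spring" else None
            _, _, Wr, xs, vs = integrate_batch(
                xs, vs, system.potential, guide, params, relax_rngs,
                duration=plan.t_relax,
                frozen_dofs=frozen if relax_mode == "freeze" else None,
                t0=t,
            )
            assert np.all(Wr == 0.0), "constrained relaxation must perform zero work"
            results[-1].record["relax_work"] = float(np.max(np.abs(Wr)))
            t += plan.t_relax
    return results, assemble_pmf(results)


def assemble_pmf(stage_results: list) -> PMFCurve:
    """Stitch stage profiles into one continuous global profile.

    Each stage curve is offset by the cumulative end free energy of the
    preceding stages; continuity at the joins is exact by construction
    and F is zero at the global start.
    """
    if not stage_results:
        raise ConfigurationError("assemble_pmf requires at least one stage")
    lams = [stage_results[0].pmf.lambdas]
    Fs = [stage_results[0].pmf.F - stage_results[0].pmf.F[0]]
    for prev, cur in zip(stage_results, stage_results[1:]):
        if prev.pmf.lambdas[-1] != cur.pmf.lambdas[0]:
            raise ConfigurationError(
                f"stages {prev.stage} and {cur.stage} are not contiguous "
                f"({prev.pmf.lambdas[-1]} vs {cur.pmf.lambdas[0]})"
            )
        offset = Fs[-1][-1]
        seg_F = cur.pmf.F - cur.pmf.F[0] + offset
        lams.append(cur.pmf.lambdas[1:])
        Fs.append(seg_F[1:])
    lam = np.concatenate(lams)
    F = np.concatenate(Fs)
    return PMFCurve(lam, F, float(lam[0]))
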