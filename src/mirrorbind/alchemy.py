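"""Thermodynamic-integration engine.

Each single-site (or multi-site) mutation is driven through the three-stage
coupled potential (decharge, vdW softcore, recharge) at a fixed set of
lambda windows per stage; each window is an independent simulation
(minimise, equilibrate, sample) that estimates the ensemble average of
dU/dlambda.  Stage free energies come from the quadrature

    dG = sum_i w_i <dU/dlambda>_i,     err = sqrt(sum_i w_i^2 stderr_i^2),

with 9-point Gauss-Legendre abscissas/weights on (0, 1) by default (a
uniform trapezoid schedule is available).  The binding free-energy change is
the difference of the mutation free energy in the two environments,

    ddG_bind = dG_mut(complex) - dG_mut(free),

negative meaning the mutation improves binding.  A stability gate rejects
mutations whose apo trajectory strays more than a backbone-RMSD threshold
(default 4.0 A, strict) from the trajectory-average structure, since such
conformational changes invalidate the sampling assumptions of TI.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import conformers
from .ffmodel import (
    AlchemicalState,
    AlchemicalTopology,
    SoftcoreParams,
    STAGES,
    coupled_potential,
)
from .sampler import BOLTZMANN_KCAL, SamplerConfig, Trajectory, minimize, sample, SamplerError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "LambdaSchedule",
    "TILeg",
    "WindowStats",
    "TIResult",
    "StabilityGate",
    "GateVerdict",
    "WindowProtocol",
    "AlchemicalSystem",
    "AlchemyError",
    "gauss_legendre_schedule",
    "trapezoid_schedule",
    "default_schedules",
    "plan",
    "derive_seed",
    "stability_gate",
    "run_window",
    "integrate",
    "run_stage",
    "ddG_binding",
    "kd_fold_change",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal/(mol*K)


class AlchemyError(RuntimeError):
    pass


@dataclass(frozen=True)
class LambdaSchedule:
    stage: str
    abscissas: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.abscissas) != len(self.weights):
            raise AlchemyError("abscissas and weights differ in length")
        lam = np.array(self.abscissas)
        if np.any(lam <= 0) or np.any(lam >= 1) or np.any(np.diff(lam) <= 0):
            raise AlchemyError("lambdas must be strictly increasing inside (0, 1)")

    @property
    def n_windows(self) -> int:
        return len(self.abscissas)


def gauss_legendre_schedule(stage: str, n: int = 9) -> LambdaSchedule:
    """Gauss-Legendre nodes/weights mapped to (0, 1); weights sum to 1."""
    x, w = np.polynomial.legendre.leggauss(n)
    return LambdaSchedule(
        stage=stage,
        abscissas=tuple((x + 1.0) / 2.0),
        weights=tuple(w / 2.0),
    )


def trapezoid_schedule(stage: str, n: int = 9) -> LambdaSchedule:
    """Uniform interior nodes with composite-trapezoid weights on (0, 1)."""
    lam = np.linspace(0.0, 1.0, n + 2)[1:-1]
    w = np.full(n, 1.0 / (n + 1))
    w[0] += 0.5 / (n + 1)
    w[-1] += 0.5 / (n + 1)
    return LambdaSchedule(stage=stage, abscissas=tuple(lam), weights=tuple(w))


def default_schedules(n: int = 9, kind: str = "gauss") -> dict[str, LambdaSchedule]:
    maker = gauss_legendre_schedule if kind == "gauss" else trapezoid_schedule
    return {stage: maker(stage, n) for stage in STAGES}


@dataclass(frozen=True)
class TILeg:
    environment: str   # complex | free
    stage: str
    lam: float
    weight: float
    window_index: int
    seed: int


@dataclass
class WindowStats:
    mean_dudl: float
    stderr: float
    n_samples: int

    def __post_init__(self):
        if self.stderr < 0:
            raise AlchemyError("stderr must be >= 0")


@dataclass
class TIResult:
    mutation: str
    dG_stage: dict[tuple[str, str], tuple[float, float]]  # (env, stage) -> (dG, err)
    dG_mut_complex: float
    dG_mut_free: float
    err_complex: float
    err_free: float
    rejected: bool = False
    gate_rmsd: float | None = None

    @property
    def ddG_bind(self) -> float:
        return self.dG_mut_complex - self.dG_mut_free

    @property
    def ddG_err(self) -> float:
        return float(np.hypot(self.err_complex, self.err_free))


@dataclass(frozen=True)
class StabilityGate:
    rmsd_threshold: float = 4.0

    def __post_init__(self):
        if self.rmsd_threshold <= 0:
            raise AlchemyError("gate threshold must be > 0")


@dataclass
class GateVerdict:
    passed: bool
    max_rmsd: float
    threshold: float


@dataclass
class WindowProtocol:
    """Per-window simulation budget for TI legs."""

    minimize_iters: int = 50
    equil_steps: int = 500
    prod_steps: int = 4000
    stride: int = 5
    move_scale: float = 0.25
    temperature: float = 300.0
    frozen: bool = False
    movable: np.ndarray | None = None


@dataclass
class AlchemicalSystem:
    """A mutation ready for TI in one environment: a dual topology plus the
    starting coordinates (and optionally which atoms may move)."""

    topo: AlchemicalTopology
    coords: np.ndarray
    movable: np.ndarray | None = None
    softcore: SoftcoreParams = field(default_factory=SoftcoreParams)

    def u_and_dudl(self, coords: np.ndarray, stage: str, lam: float):
        return coupled_potential(coords, self.topo, AlchemicalState(stage, lam),
                                 self.softcore)


# ---------------------------------------------------------------------------
# planning and seeding
# ---------------------------------------------------------------------------

def derive_seed(master_seed: int, *parts) -> int:
    """Stable, platform-independent per-leg seed below 2**31."""
    text = f"{master_seed}|" + "|".join(str(p) for p in parts)
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def plan(
    mutation: str,
    schedules: dict[str, LambdaSchedule],
    environments=("complex", "free"),
    master_seed: int = 0,
) -> list[TILeg]:
    """One leg per (environment, stage, window); 9 windows x 3 stages x 2
    environments gives the standard 54 simulations per full calculation."""
    missing = set(STAGES) - set(schedules)
    if missing:
        raise AlchemyError(f"missing stage schedule(s): {sorted(missing)}")
    legs = []
    for env in environments:
        for stage in STAGES:
            sched = schedules[stage]
            for i, (lam, w) in enumerate(zip(sched.abscissas, sched.weights)):
                legs.append(
                    TILeg(
                        environment=env, stage=stage, lam=lam, weight=w,
                        window_index=i,
                        seed=derive_seed(master_seed, mutation, env, stage, i),
                    )
                )
    return legs


# ---------------------------------------------------------------------------
# stability gate
# ---------------------------------------------------------------------------

def _traj_max_rmsd_to_average(traj: Trajectory, mask=None) -> float:
    frames = [np.asarray(f, float) for f in traj.frames]
    if not frames:
        raise AlchemyError("empty trajectory")
    ref = frames[0]
    aligned = []
    for f in frames:
        try:
            sup = conformers.superpose(ref, f, mask=mask)
            aligned.append(sup.apply(f))
        except conformers.ConformerError:
            aligned.append(f)  # too few atoms to superpose: compare in place
    avg = np.mean(aligned, axis=0)
    return max(conformers.rmsd(avg, f, mask=mask, superposed=False) for f in aligned)


def stability_gate(
    apo_wt_traj: Trajectory,
    apo_mut_traj: Trajectory,
    gate: StabilityGate = StabilityGate(),
    mask=None,
) -> GateVerdict:
    """Backbone RMSD of every frame to the trajectory-average structure;
    fails if any frame exceeds the threshold (strict >)."""
    worst = max(
        _traj_max_rmsd_to_average(apo_wt_traj, mask=mask),
        _traj_max_rmsd_to_average(apo_mut_traj, mask=mask),
    )
    return GateVerdict(
        passed=not (worst > gate.rmsd_threshold),
        max_rmsd=worst,
        threshold=gate.rmsd_threshold,
    )


# ---------------------------------------------------------------------------
# windows and integration
# ---------------------------------------------------------------------------

def run_window(
    system: AlchemicalSystem,
    state: AlchemicalState,
    protocol: WindowProtocol = WindowProtocol(),
    seed: int = 0,
) -> WindowStats:
    """Minimise, equilibrate and sample one lambda window; accumulate
    dU/dlambda at every snapshot; stderr by block averaging (10 blocks)."""

    def u(c):
        return system.u_and_dudl(c, state.stage, state.lam)[0]

    def dudl(c):
        return system.u_and_dudl(c, state.stage, state.lam)[1]

    coords = np.array(system.coords, float)
    movable = system.movable if protocol.movable is None else protocol.movable
    try:
        if not protocol.frozen and protocol.minimize_iters > 0:
            coords = minimize(coords, u, max_iter=protocol.minimize_iters,
                              movable=movable).coords
        cfg = SamplerConfig(
            temperature=protocol.temperature,
            n_steps=protocol.equil_steps,
            snapshot_stride=max(1, protocol.equil_steps),
            seed=derive_seed(seed, "equil"),
            move_scale=protocol.move_scale,
            movable=movable,
            frozen=protocol.frozen,
        )
        if protocol.equil_steps > 0 and not protocol.frozen:
            traj = sample(coords, u, cfg)
            if traj.frames:
                coords = traj.frames[-1]
        prod_cfg = replace(
            cfg,
            n_steps=protocol.prod_steps,
            snapshot_stride=protocol.stride,
            seed=derive_seed(seed, "prod"),
        )
        traj = sample(coords, u, prod_cfg, observable=dudl)
    except SamplerError as exc:
        raise AlchemyError(
            f"sampler failure in window (stage={state.stage}, lambda={state.lam:.4f}): {exc}"
        ) from exc
    obs = np.array(traj.observables, float)
    if obs.size == 0:
        raise AlchemyError("window produced no snapshots")
    mean = float(np.mean(obs))
    nb = min(10, obs.size)
    blocks = np.array_split(obs, nb)
    bm = np.array([b.mean() for b in blocks])
    stderr = float(np.std(bm, ddof=1) / np.sqrt(nb)) if nb > 1 else 0.0
    return WindowStats(mean_dudl=mean, stderr=stderr, n_samples=int(obs.size))


def integrate(stats: list[WindowStats], schedule: LambdaSchedule) -> tuple[float, float]:
    """Quadrature of the per-window <dU/dlambda> values with error propagation."""
    if len(stats) != schedule.n_windows:
        raise AlchemyError(
            f"{len(stats)} window stats for a {schedule.n_windows}-window schedule"
        )
    w = np.array(schedule.weights)
    mu = np.array([s.mean_dudl for s in stats])
    se = np.array([s.stderr for s in stats])
    return float(np.sum(w * mu)), float(np.sqrt(np.sum(w**2 * se**2)))


def run_stage(
    system: AlchemicalSystem,
    schedule: LambdaSchedule,
    protocol: WindowProtocol = WindowProtocol(),
    master_seed: int = 0,
    seed_tag: str = "",
) -> tuple[float, float, list[WindowStats]]:
    stats = [
        run_window(
            system,
            AlchemicalState(schedule.stage, lam),
            protocol,
            seed=derive_seed(master_seed, seed_tag, schedule.stage, i),
        )
        for i, lam in enumerate(schedule.abscissas)
    ]
    dg, err = integrate(stats, schedule)
    return dg, err, stats


def ddG_binding(
    mutation: str,
    complex_system: AlchemicalSystem,
    free_system: AlchemicalSystem,
    schedules: dict[str, LambdaSchedule] | None = None,
    protocol: WindowProtocol = WindowProtocol(),
    master_seed: int = 0,
    gate_verdict: GateVerdict | None = None,
    stages=STAGES,
) -> TIResult:
    """Full staged TI in both environments.

    ddG = dG_mut(complex) - dG_mut(free); negative = improved binding.  If a
    failed stability-gate verdict is supplied, the result is marked rejected
    and no legs are run.
    """
    schedules = schedules or default_schedules()
    if gate_verdict is not None and not gate_verdict.passed:
        return TIResult(
            mutation=mutation, dG_stage={},
            dG_mut_complex=float("nan"), dG_mut_free=float("nan"),
            err_complex=float("nan"), err_free=float("nan"),
            rejected=True, gate_rmsd=gate_verdict.max_rmsd,
        )
    systems = {"complex": complex_system, "free": free_system}
    dG_stage: dict[tuple[str, str], tuple[float, float]] = {}
    totals, errs = {}, {}
    for env, system in systems.items():
        tot, var = 0.0, 0.0
        for stage in stages:
            dg, err, _ = run_stage(
                system, schedules[stage], protocol,
                master_seed=master_seed, seed_tag=f"{mutation}|{env}",
            )
            dG_stage[(env, stage)] = (dg, err)
            tot += dg
            var += err**2
        totals[env], errs[env] = tot, float(np.sqrt(var))
    return TIResult(
        mutation=mutation,
        dG_stage=dG_stage,
        dG_mut_complex=totals["complex"],
        dG_mut_free=totals["free"],
        err_complex=errs["complex"],
        err_free=errs["free"],
        gate_rmsd=None if gate_verdict is None else gate_verdict.max_rmsd,
    )


def kd_fold_change(ddG: float, T: float = 300.0) -> float:
    """Fold change in Kd implied by a binding free-energy change:
    exp(-ddG / RT); ddG < 0 gives fold > 1 (improvement)."""
    if T <= 0:
        raise AlchemyError("temperature must be > 0")
    return float(np.exp(-ddG / (GAS_CONSTANT_KCAL * T)))
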