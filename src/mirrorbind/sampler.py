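"""Energy minimisation and canonical-ensemble sampling of toy systems.

Sampling is Metropolis Monte Carlo with single-atom Gaussian displacement
moves at fixed temperature; for the desk-scale systems treated here this
yields the same ensemble averages as molecular dynamics without any
force-integration stability concerns.  All randomness flows through a
numpy ``default_rng`` seeded from the config, so identical seeds give
bit-identical trajectories.

Equilibration applies a schedule of harmonic positional restraints to the
starting conformation and must end with the restraints fully released; the
convergence flag uses an RMSD-plateau rule (each successive 10%-block mean
structure within 0.5 Angstrom of the cumulative mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

__all__ = [
    "BOLTZMANN_KCAL",
    "SamplerConfig",
    "Trajectory",
    "MinimizeResult",
    "EquilibrationReport",
    "SamplerError",
    "minimize",
    "sample",
    "equilibrate",
]

BOLTZMANN_KCAL = 1.9872e-3  # kcal/(mol*K)


class SamplerError(RuntimeError):
    pass


@dataclass
class SamplerConfig:
    temperature: float = 300.0        # K
    n_steps: int = 1000
    snapshot_stride: int = 10
    seed: int = 0
    move_scale: float = 0.25          # Angstrom, std-dev of Gaussian moves
    restraint_schedule: list[tuple[int, float]] | None = None  # (step, kcal/mol/A^2)
    boltzmann_constant: float = BOLTZMANN_KCAL
    movable: np.ndarray | None = None  # indices of movable atoms; None = all
    frozen: bool = False               # no moves at all (frozen-geometry averages)

    def __post_init__(self):
        if self.temperature <= 0:
            raise SamplerError("temperature must be > 0")
        if self.snapshot_stride < 1:
            raise SamplerError("snapshot_stride must be >= 1")

    @property
    def kT(self) -> float:
        return self.boltzmann_constant * self.temperature


@dataclass
class Trajectory:
    frames: list[np.ndarray]
    energies: list[float]
    acceptance_rate: float
    config: SamplerConfig
    observables: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class MinimizeResult:
    coords: np.ndarray
    energy: float
    n_iter: int
    terminated_by: str            # "gradient-tolerance" | "max-iterations"
    energies: list[float]


@dataclass
class EquilibrationReport:
    converged: bool
    block_rmsds: list[float]
    applied_weights: list[tuple[int, float]]
    plateau_tolerance: float


# ---------------------------------------------------------------------------
# minimisation
# ---------------------------------------------------------------------------

def minimize(
    coords: np.ndarray,
    energy_fn: Callable[[np.ndarray], float],
    max_iter: int = 500,
    grad_tol: float = 1e-6,
    movable: np.ndarray | None = None,
) -> MinimizeResult:
    """Gradient minimisation (nonlinear conjugate gradient with numerical
    gradients).  The recorded energy sequence is non-increasing; terminates
    on the gradient-norm tolerance or the iteration cap and reports which."""
    coords = np.asarray(coords, dtype=float)
    shape = coords.shape
    x_fixed = coords.copy()
    if movable is None:
        movable = np.arange(coords.shape[0])
    movable = np.asarray(movable, dtype=int)

    call_count = [0]

    def fun(x: np.ndarray) -> float:
        call_count[0] += 1
        c = x_fixed.copy()
        c[movable] = x.reshape(len(movable), 3)
        e = energy_fn(c)
        if not np.isfinite(e):
            raise SamplerError(
                f"non-finite energy during line search (after {call_count[0]} evaluations)"
            )
        return e

    e0 = energy_fn(coords)
    if not np.isfinite(e0):
        raise SamplerError("non-finite starting energy")

    energies = [e0]

    def cb(xk):
        e = fun(xk)
        # line-searched CG is monotone; guard against round-off upticks
        energies.append(min(e, energies[-1]))

    res = _scipy_minimize(
        fun,
        coords[movable].ravel(),
        method="CG",
        callback=cb,
        options={"gtol": grad_tol, "maxiter": max_iter},
    )
    out = x_fixed.copy()
    out[movable] = res.x.reshape(len(movable), 3)
    terminated_by = "gradient-tolerance" if res.status == 0 else "max-iterations"
    final_e = float(res.fun)
    energies.append(min(final_e, energies[-1]))
    return MinimizeResult(
        coords=out.reshape(shape),
        energy=final_e,
        n_iter=int(res.nit),
        terminated_by=terminated_by,
        energies=energies,
    )


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

def _mc_run(
    coords: np.ndarray,
    energy_fn: Callable[[np.ndarray], float],
    cfg: SamplerConfig,
    rng: np.random.Generator,
    observable: Callable[[np.ndarray], float] | None = None,
):
    """Core MC loop; returns (final coords, frames, energies, obs, acc_rate)."""
    coords = np.array(coords, dtype=float)
    movable = (
        np.arange(coords.shape[0]) if cfg.movable is None
        else np.asarray(cfg.movable, dtype=int)
    )
    kT = cfg.kT
    e = float(energy_fn(coords))
    frames, energies, obs = [], [], []
    accepted = attempted = 0
    for step in range(1, cfg.n_steps + 1):
        if not cfg.frozen:
            atom = movable[rng.integers(len(movable))]
            delta = rng.normal(0.0, cfg.move_scale, size=3)
            old = coords[atom].copy()
            coords[atom] = old + delta
            e_new = float(energy_fn(coords))
            attempted += 1
            if e_new <= e or rng.random() < np.exp(-(e_new - e) / kT):
                e = e_new
                accepted += 1
            else:
                coords[atom] = old
        if step % cfg.snapshot_stride == 0:
            frames.append(coords.copy())
            energies.append(e)
            if observable is not None:
                obs.append(float(observable(coords)))
    rate = accepted / attempted if attempted else 0.0
    return coords, frames, energies, obs, rate


def sample(
    coords: np.ndarray,
    energy_fn: Callable[[np.ndarray], float],
    cfg: SamplerConfig,
    observable: Callable[[np.ndarray], float] | None = None,
) -> Trajectory:
    """Metropolis MC sampling at cfg.temperature; snapshots every
    ``snapshot_stride`` steps.  An optional per-snapshot observable (e.g.
    dU/dlambda) is accumulated alongside the energies."""
    if not cfg.frozen and cfg.move_scale <= 0:
        raise SamplerError("move_scale must be > 0")
    rng = np.random.default_rng(cfg.seed)
    _, frames, energies, obs, rate = _mc_run(coords, energy_fn, cfg, rng, observable)
    return Trajectory(
        frames=frames, energies=energies, acceptance_rate=rate,
        config=cfg, observables=obs,
    )


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def equilibrate(
    coords: np.ndarray,
    energy_fn: Callable[[np.ndarray], float],
    cfg: SamplerConfig,
    plateau_tol: float = 0.5,
) -> tuple[np.ndarray, EquilibrationReport]:
    """Restrained equilibration followed by a convergence check.

    The restraint schedule is a list of (step, weight) pairs: from each step
    onward a harmonic positional restraint of that weight (kcal/mol/A^2) to
    the starting conformation applies.  The schedule must end at weight 0.
    Convergence: over the unrestrained tail, each successive 10%-block mean
    structure lies within ``plateau_tol`` (RMSD) of the cumulative mean.
    """
    schedule = cfg.restraint_schedule
    if not schedule:
        raise SamplerError("equilibrate requires a restraint_schedule")
    if schedule[-1][1] != 0.0:
        raise SamplerError("restraint schedule must end at weight 0")

    ref = np.array(coords, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    current = ref.copy()
    applied: list[tuple[int, float]] = []

    boundaries = [s for s, _ in schedule] + [cfg.n_steps]
    tail_frames: list[np.ndarray] = []
    for (start, weight), end in zip(schedule, boundaries[1:]):
        n = max(0, end - start)
        if n == 0:
            applied.append((start, weight))
            continue

        if weight > 0:
            def efn(c, w=weight):
                return energy_fn(c) + w * float(np.sum((c - ref) ** 2))
        else:
            efn = energy_fn
        seg_cfg = replace(cfg, n_steps=n, restraint_schedule=None,
                          seed=int(rng.integers(2**31 - 1)))
        current, frames, _, _, _ = _mc_run(current, efn, seg_cfg, rng)
        applied.append((start, weight))
        if weight == 0:
            tail_frames.extend(frames)

    block_rmsds: list[float] = []
    converged = False
    if len(tail_frames) >= 10:
        stack = np.array(tail_frames)
        nb = 10
        size = len(stack) // nb
        for b in range(1, nb):
            cum_mean = stack[: (b + 1) * size].mean(axis=0)
            block_mean = stack[b * size: (b + 1) * size].mean(axis=0)
            block_rmsds.append(_plain_rmsd(block_mean, cum_mean))
        converged = all(r < plateau_tol for r in block_rmsds)
    return current, EquilibrationReport(
        converged=converged,
        block_rmsds=block_rmsds,
        applied_weights=applied,
        plateau_tolerance=plateau_tol,
    )
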