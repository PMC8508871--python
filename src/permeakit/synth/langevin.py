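"""Overdamped (Brownian) dynamics on a 1D landscape.

The sampler is the desk-scale surrogate for the all-atom engine: an
Euler–Maruyama discretization of the overdamped Langevin equation

    ξ_{t+1} = ξ_t − (Δt/γ) dU_tot/dξ + sqrt(2 kT Δt / γ) η_t,   η ~ N(0,1),

where U_tot is the landscape plus all restraints.  Only configurational
sampling matters downstream (histograms, not kinetics), so friction γ and
the timestep are free numerical parameters; defaults make a 10 ns-equivalent
window 10^5 steps.

Steered pulling reuses the same integrator with a harmonic restraint whose
center follows a prescribed monotone schedule, mimicking the slow-pulling
stage used to seed umbrella windows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit

from ..constants import thermal_energy
from .landscape import BiasSpec, PotentialSpec

__all__ = [
    "LangevinConfig",
    "DivergenceError",
    "simulate_overdamped",
    "steered_pull",
    "linear_schedule",
]


class DivergenceError(RuntimeError):
    """The integrator left the configured coordinate bounds."""

    def __init__(self, step: int, position: float, bound: float):
        self.step = step
        super().__init__(
            f"trajectory diverged at step {step}: |xi| = {abs(position):.3g} "
            f"exceeded bound {bound:.3g}; reduce the timestep or check the potential"
        )


@dataclass(frozen=True)
class LangevinConfig:
    """Numerical parameters of the Brownian sampler.

    kT               : kcal/mol (default 300 K)
    friction         : γ, kcal mol^-1 Å^-2 ns (mobility is Δt/γ)
    timestep         : ns
    n_steps          : number of update steps (output has n_steps+1 frames)
    seed             : RNG seed; identical seeds give identical trajectories
    initial_position : Å
    bound            : |ξ| beyond which the run is declared divergent
    """

    kT: float = thermal_energy()
    friction: float = 0.5
    timestep: float = 1e-4
    n_steps: int = 100_000
    seed: int = 0
    initial_position: float = 0.0
    bound: float = 1e4

    def __post_init__(self) -> None:
        if self.kT <= 0 or self.friction <= 0 or self.timestep <= 0:
            raise ValueError("kT, friction and timestep must all be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.bound <= 0:
            raise ValueError("bound must be positive")


@njit(cache=True)
def _integrate(x0, noise, mob_dt, amps, cens, wids, bkind, bcen, bk, brad,
               pull_k, pull_cen, bound):  # pragma: no cover - exercised via wrapper
    n = noise.shape[0]
    out = np.empty(n + 1)
    out[0] = x0
    x = x0
    for t in range(n):
        g = 0.0
        for i in range(amps.shape[0]):
            d = x - cens[i]
            w2 = wids[i] * wids[i]
            g += amps[i] * np.exp(-0.5 * d * d / w2) * (-d / w2)
        for i in range(bkind.shape[0]):
            d = x - bcen[i]
            if bkind[i] == 0:  # harmonic
                g += bk[i] * d
            else:
                ad = abs(d)
                excess = ad - brad[i]
                sgn = 1.0 if d > 0.0 else -1.0
                if bkind[i] == 1:  # flat bottom: restoring outside radius
                    if excess > 0.0:
                        g += bk[i] * excess * sgn
                else:  # lower bound: repulsive inside floor
                    if excess < 0.0:
                        g += bk[i] * excess * sgn
        if pull_k > 0.0:
            g += pull_k * (x - pull_cen[t])
        x = x - mob_dt * g + noise[t]
        out[t + 1] = x
        if not (-bound < x < bound):
            return out[: t + 2], t + 1
    return out, -1


def _bias_arrays(biases: Sequence[BiasSpec]):
    kinds = np.array([b.kind_code for b in biases], dtype=np.int64)
    cens = np.array([b.center for b in biases], dtype=float)
    ks = np.array([b.force_constant for b in biases], dtype=float)
    rads = np.array([b.radius_or_floor for b in biases], dtype=float)
    return kinds, cens, ks, rads


def _run(spec, biases, cfg, pull_k, pull_centers):
    amps, cens, wids = spec.term_arrays()
    bkind, bcen, bk, brad = _bias_arrays(biases)
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal(cfg.n_steps) * np.sqrt(
        2.0 * cfg.kT * cfg.timestep / cfg.friction
    )
    traj, bad_step = _integrate(
        float(cfg.initial_position), noise, cfg.timestep / cfg.friction,
        amps, cens, wids, bkind, bcen, bk, brad,
        float(pull_k), pull_centers, float(cfg.bound),
    )
    if bad_step >= 0:
        raise DivergenceError(bad_step, traj[-1], cfg.bound)
    return traj


def simulate_overdamped(
    spec: PotentialSpec,
    biases: Sequence[BiasSpec] = (),
    cfg: LangevinConfig = LangevinConfig(),
) -> np.ndarray:
    """Sample the biased landscape; returns ξ at frames 0..n_steps (Å)."""
    return _run(spec, tuple(biases), cfg, 0.0, np.zeros(1))


def linear_schedule(start: float, end: float, n_steps: int) -> np.ndarray:
    """Restraint-center schedule moving linearly from start to end (n_steps+1 frames)."""
    return np.linspace(start, end, n_steps + 1)


def steered_pull(
    spec: PotentialSpec,
    k_pull: float,
    schedule: np.ndarray,
    cfg: LangevinConfig,
    biases: Sequence[BiasSpec] = (),
):
    """Drag the particle with a moving harmonic restraint.

    schedule : restraint-center position at every frame, length n_steps+1,
               monotone along the pull direction.

    Returns (trajectory, schedule) — the restraint-center log is the schedule
    itself, which the restraint follows exactly.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.shape != (cfg.n_steps + 1,):
        raise ValueError(
            f"schedule must have n_steps+1 = {cfg.n_steps + 1} frames, "
            f"got {schedule.shape}"
        )
    if k_pull <= 0:
        raise ValueError("k_pull must be positive")
    d = np.diff(schedule)
    if len(d) and not (np.all(d >= 0) or np.all(d <= 0)):
        raise ValueError("pull schedule must be monotone in the pull direction")
    # center applied during step t -> t+1 is the frame-(t+1) target
    traj = _run(spec, tuple(biases), cfg, k_pull, schedule[1:].copy())
    return traj, schedule
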