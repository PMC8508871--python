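"""Two-species single-file exclusion pore on a 1D lattice.

Fixed-step Monte Carlo of two particle species entering a pore of
``n_sites`` sites from either end and hopping symmetrically between
neighboring sites.  With exclusion on, at most one particle occupies a site
and particles cannot pass each other — the single-file situation in which
opposing fluxes block rather than electrically compensate each other.  With
exclusion off, particles are independent, which is the transport picture
underlying the GHK (constant-field) model.

Rates are illustrative, free parameters; the model makes no kinetic claims
about any specific channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LatticePoreConfig", "LatticeResult", "simulate_single_file"]


@dataclass(frozen=True)
class LatticePoreConfig:
    """Lattice pore parameters (rates in ns^-1, dt in ns).

    entry_*  : injection attempt rates for species a/b at the left/right end
    hop_rate : symmetric nearest-neighbor hop attempt rate per particle
    exclusion: single-file occupancy constraint on/off
    """

    n_sites: int = 8
    entry_a_left: float = 100.0
    entry_a_right: float = 0.0
    entry_b_left: float = 0.0
    entry_b_right: float = 100.0
    hop_rate: float = 50.0
    exclusion: bool = True
    n_steps: int = 200_000
    dt: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        rates = (self.entry_a_left, self.entry_a_right, self.entry_b_left,
                 self.entry_b_right, self.hop_rate)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be >= 0")
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("dt must be > 0 and n_steps >= 1")
        if self.hop_rate * self.dt / 2.0 > 0.5:
            raise ValueError("hop_rate*dt/2 must be <= 0.5 (per-step probability)")


@dataclass(frozen=True)
class LatticeResult:
    """Net fluxes (crossings/ns, positive = left→right at the right boundary),
    per-species boundary-event counts, mean occupancy per site, and the
    occupancy trace (mean over sites, one value per recorded interval)."""

    net_flux_a: float
    net_flux_b: float
    exits_right: dict
    exits_left: dict
    entries: dict
    mean_occupancy: float
    occupancy_trace: np.ndarray
    total_time: float


def simulate_single_file(cfg: LatticePoreConfig,
                         trace_stride: int = 1000) -> LatticeResult:
    """Run the lattice Monte Carlo; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    # particle state: parallel lists of species (0=a, 1=b) and site index
    species: list[int] = []
    sites: list[int] = []
    n = cfg.n_sites
    p_hop = cfg.hop_rate * cfg.dt / 2.0
    p_entry = {
        (0, "left"): cfg.entry_a_left * cfg.dt,
        (0, "right"): cfg.entry_a_right * cfg.dt,
        (1, "left"): cfg.entry_b_left * cfg.dt,
        (1, "right"): cfg.entry_b_right * cfg.dt,
    }
    occupied = np.zeros(n, dtype=bool)
    exits_right = {0: 0, 1: 0}
    exits_left = {0: 0, 1: 0}
    entries = {(0, "left"): 0, (0, "right"): 0, (1, "left"): 0, (1, "right"): 0}
    occ_sum = 0.0
    trace = []

    for step in range(cfg.n_steps):
        # injections
        for (sp, side), p in p_entry.items():
            if p > 0 and rng.random() < p:
                site = 0 if side == "left" else n - 1
                if cfg.exclusion and occupied[site]:
                    continue
                species.append(sp)
                sites.append(site)
                occupied[site] = True
                entries[(sp, side)] += 1
        # moves, in random order
        if species:
            order = rng.permutation(len(species))
            removed = []
            for idx in order:
                u = rng.random()
                if u < p_hop:
                    step_dir = +1
                elif u < 2.0 * p_hop:
                    step_dir = -1
                else:
                    continue
                target = sites[idx] + step_dir
                if target < 0 or target >= n:
                    (exits_left if target < 0 else exits_right)[species[idx]] += 1
                    removed.append(idx)
                    occupied[sites[idx]] = _still_occupied(sites, idx, cfg.exclusion)
                    sites[idx] = -1_000_000  # off-lattice sentinel
                else:
                    if cfg.exclusion and occupied[target]:
                        continue
                    occupied[sites[idx]] = _still_occupied(sites, idx, cfg.exclusion)
                    sites[idx] = target
                    occupied[target] = True
            if removed:
                keep = [i for i in range(len(species)) if sites[i] != -1_000_000]
                species = [species[i] for i in keep]
                sites = [sites[i] for i in keep]
            # rebuild occupancy (cheap for small n) to stay exact without
            # exclusion, where several particles can share a site
            occupied[:] = False
            for s in sites:
                occupied[s] = True
        occ_sum += occupied.mean()
        if (step + 1) % trace_stride == 0:
            trace.append(occupied.mean())

    total_time = cfg.n_steps * cfg.dt
    net_a = (exits_right[0] - entries[(0, "right")]) / total_time
    net_b = (exits_right[1] - entries[(1, "right")]) / total_time
    return LatticeResult(
        net_flux_a=net_a,
        net_flux_b=net_b,
        exits_right={"a": exits_right[0], "b": exits_right[1]},
        exits_left={"a": exits_left[0], "b": exits_left[1]},
        entries={f"{'ab'[sp]}_{side}": c for (sp, side), c in entries.items()},
        mean_occupancy=occ_sum / cfg.n_steps,
        occupancy_trace=np.array(trace),
        total_time=total_time,
    )


def _still_occupied(sites, moving_idx, exclusion) -> bool:
    """After moving particle moving_idx off its site, is that site still held?

    With exclusion this is always False (one particle per site); without
    exclusion another particle may share the site.
    """
    if exclusion:
        return False
    origin = sites[moving_idx]
    return any(s == origin for i, s in enumerate(sites) if i != moving_idx)
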