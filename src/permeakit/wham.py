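"""Umbrella-sampling analysis: window planning, WHAM, and PMF features.

The weighted histogram analysis method (WHAM) combines biased histograms
from harmonic umbrella windows into one unbiased free-energy profile by
solving the coupled self-consistent equations

    P(ξ_b) = Σ_j n_j(ξ_b) / Σ_j N_j exp[(f_j − w_j(ξ_b)) / kT]
    f_j    = −kT ln Σ_b P(ξ_b) exp(−w_j(ξ_b) / kT)

with w_j(ξ) = ½ k_j (ξ − ξ_j)² the window bias, iterated until the window
free energies f_j change by less than a tolerance.  G(ξ) = −kT ln P(ξ) up
to a constant; the gauge is fixed by f_1 = 0 and the profile is anchored by
shifting its designated bulk bins (first and last ``bulk_points`` bins) to
zero mean.

Per-bin uncertainties follow the block convention of the source protocol:
the retained samples of every window are split into contiguous blocks of
one simulated nanosecond, WHAM + shift is solved per block, and the SEM
across block profiles (n−1 denominator) is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .constants import thermal_energy

__all__ = [
    "WindowPlan",
    "UmbrellaWindow",
    "WhamConfig",
    "ConvergenceRecord",
    "PMFProfile",
    "PMFFeatures",
    "WhamError",
    "plan_windows",
    "bin_window",
    "wham_solve",
    "shift_profile",
    "block_error",
    "compute_pmf",
    "extract_features",
]


class WhamError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# planning
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowPlan:
    """Equally spaced umbrella-window centers along the pull axis.

    The start frame is not counted as a window: centers sit at
    start + i*spacing for i = 1..n_total.  Terminal windows (the gate
    region at the far end of the pull) can be dropped after planning.
    """

    centers: np.ndarray
    spacing: float
    n_total: int
    n_dropped_terminal: int

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_dropped_terminal

    @property
    def retained_centers(self) -> np.ndarray:
        return self.centers[: self.n_retained]


def plan_windows(
    pull_span: float,
    spacing: float,
    drop_terminal: float = 0.0,
    start: float = 0.0,
) -> WindowPlan:
    """Plan round(pull_span/spacing) windows at spacing Å apart; drop the
    trailing round(drop_terminal/spacing) windows from the far end."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > pull_span:
        raise ValueError(f"spacing {spacing} exceeds pull span {pull_span}")
    if not 0 <= drop_terminal <= pull_span:
        raise ValueError("drop_terminal must lie in [0, pull_span]")
    n_total = int(round(pull_span / spacing))
    n_drop = int(round(drop_terminal / spacing))
    centers = start + spacing * np.arange(1, n_total + 1)
    return WindowPlan(centers=centers, spacing=spacing, n_total=n_total,
                      n_dropped_terminal=n_drop)


# --------------------------------------------------------------------------
# windows and binning
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased window: harmonic restraint center/force constant and the
    sampled reaction-coordinate series.

    n_equilibration_discard leading frames are removed before any analysis;
    block_length (frames, nominally one simulated nanosecond) drives the
    block-error estimate.
    """

    center: float
    force_constant: float
    samples: np.ndarray
    n_equilibration_discard: int = 0
    block_length: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=float).ravel())
        # k = 0 is permitted: an unbiased window, under which WHAM
        # degenerates to direct Boltzmann inversion of the histogram
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.n_equilibration_discard < 0:
            raise ValueError("n_equilibration_discard must be >= 0")
        if self.retained.size == 0:
            raise ValueError("window has no samples after equilibration discard")

    @property
    def retained(self) -> np.ndarray:
        return self.samples[self.n_equilibration_discard:]

    def bias_energy(self, xi: np.ndarray) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(xi) - self.center) ** 2


@dataclass(frozen=True)
class WhamConfig:
    n_bins: int = 300
    tolerance: float = 1e-7  # max |Δf_j| between iterations, kcal/mol
    max_iterations: int = 100_000
    kT: float = thermal_energy()
    bulk_points: int = 10
    #: internal empty-bin runs longer than this fraction of n_bins abort
    #: with a disconnected-coverage error; shorter runs become +inf bins
    max_gap_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.kT <= 0:
            raise ValueError("kT must be > 0")


@dataclass(frozen=True)
class ConvergenceRecord:
    iterations: int
    final_residual: float
    n_empty_bins: int


@dataclass(frozen=True)
class PMFProfile:
    """Binned free-energy profile.  Bins never visited by any window carry
    +inf and are excluded from shifting and feature extraction."""

    xi: np.ndarray
    free_energy: np.ndarray
    error: Optional[np.ndarray] = None
    shift: float = 0.0
    n_samples: Optional[np.ndarray] = None
    convergence: Optional[ConvergenceRecord] = None
    window_free_energies: Optional[np.ndarray] = None

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def bin_window(window: UmbrellaWindow, grid_edges: np.ndarray) -> np.ndarray:
    """Histogram the window's retained samples on the given bin edges.

    Raises if every sample falls outside the grid.
    """
    samples = window.retained
    counts, _ = np.histogram(samples, bins=grid_edges)
    if counts.sum() == 0:
        raise WhamError(
            f"window at {window.center}: all {samples.size} samples fall "
            f"outside the grid [{grid_edges[0]}, {grid_edges[-1]}]"
        )
    return counts


def _make_grid(windows: Sequence[UmbrellaWindow], cfg: WhamConfig,
               grid_range: Optional[Tuple[float, float]]):
    if grid_range is None:
        lo = min(w.retained.min() for w in windows)
        hi = max(w.retained.max() for w in windows)
    else:
        lo, hi = grid_range
    if not hi > lo:
        raise WhamError("degenerate coordinate range for binning")
    edges = np.linspace(lo, hi, cfg.n_bins + 1)
    # guard against the max sample landing on the open edge
    edges[-1] = np.nextafter(edges[-1], np.inf)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    cfg: WhamConfig = WhamConfig(),
    grid_range: Optional[Tuple[float, float]] = None,
) -> PMFProfile:
    """Self-consistent WHAM solution; returns the *unshifted* profile."""
    windows = list(windows)
    if not windows:
        raise WhamError("need at least one window")
    edges, centers = _make_grid(windows, cfg, grid_range)
    counts = np.stack([bin_window(w, edges) for w in windows])  # (J, B)
    n_j = counts.sum(axis=1).astype(float)                      # samples per window
    n_b = counts.sum(axis=0).astype(float)                      # samples per bin
    bias = np.stack([w.bias_energy(centers) for w in windows])  # (J, B)

    _check_coverage(n_b, centers, cfg)

    kT = cfg.kT
    f = np.zeros(len(windows))
    boltz_bias = np.exp(-bias / kT)          # (J, B); underflow to 0 is fine
    residual = np.inf
    for iteration in range(1, cfg.max_iterations + 1):
        denom = (n_j[:, None] * np.exp(f[:, None] / kT) * boltz_bias).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, n_b / denom, 0.0)
        z_j = boltz_bias @ p                 # (J,)
        f_new = -kT * np.log(z_j)
        f_new -= f_new[0]                    # gauge: f_1 = 0
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < cfg.tolerance:
            break
    else:
        raise WhamError(
            f"WHAM did not converge in {cfg.max_iterations} iterations; "
            f"final residual {residual:.3e} kcal/mol"
        )

    with np.errstate(divide="ignore"):
        g = np.where(n_b > 0, -kT * np.log(np.where(n_b > 0, _final_p(p), 1.0)),
                     np.inf)
    finite = np.isfinite(g)
    g[finite] -= g[finite].min()
    return PMFProfile(
        xi=centers,
        free_energy=g,
        n_samples=n_b,
        convergence=ConvergenceRecord(iterations=iteration,
                                      final_residual=residual,
                                      n_empty_bins=int((n_b == 0).sum())),
        window_free_energies=f,
    )


def _final_p(p: np.ndarray) -> np.ndarray:
    total = p.sum()
    return p / total if total > 0 else p


def _check_coverage(n_b: np.ndarray, centers: np.ndarray, cfg: WhamConfig) -> None:
    nonzero = np.nonzero(n_b)[0]
    if nonzero.size == 0:
        raise WhamError("no samples fall inside the grid")
    interior = n_b[nonzero[0]: nonzero[-1] + 1]
    empty = interior == 0
    if not empty.any():
        return
    # longest internal run of empty bins
    run, best, best_end = 0, 0, 0
    for i, e in enumerate(empty):
        run = run + 1 if e else 0
        if run > best:
            best, best_end = run, i
    max_gap = max(2, int(cfg.max_gap_fraction * cfg.n_bins))
    if best > max_gap:
        j0 = nonzero[0] + best_end - best + 1
        raise WhamError(
            "disconnected window coverage: no samples between "
            f"xi = {centers[j0]:.3f} and xi = {centers[nonzero[0] + best_end]:.3f} "
            f"({best} empty bins)"
        )


# --------------------------------------------------------------------------
# shifting, errors, features
# --------------------------------------------------------------------------

def shift_profile(profile: PMFProfile, bulk_points: int = 10) -> PMFProfile:
    """Anchor the profile: mean free energy over the first and last
    ``bulk_points`` bins becomes exactly zero.  Shape is unchanged."""
    if bulk_points < 1:
        raise ValueError("bulk_points must be >= 1")
    g = profile.free_energy
    if g.size < 2 * bulk_points:
        raise WhamError("profile has fewer than 2*bulk_points bins")
    bulk = np.concatenate([g[:bulk_points], g[-bulk_points:]])
    finite = np.isfinite(bulk)
    if not finite.any():
        raise WhamError("all bulk bins are empty; cannot anchor the profile")
    offset = float(bulk[finite].mean())
    shifted = np.where(np.isfinite(g), g - offset, np.inf)
    return replace(profile, free_energy=shifted, shift=profile.shift + offset)


def _blocks_of(window: UmbrellaWindow) -> list[np.ndarray]:
    if not window.block_length or window.block_length < 2:
        raise WhamError("block_error requires block_length >= 2 on every window")
    retained = window.retained
    n_blocks = retained.size // window.block_length
    if retained.size % window.block_length:
        warnings.warn(
            f"window at {window.center}: dropping "
            f"{retained.size % window.block_length} trailing frames that do "
            "not fill a block", stacklevel=3)
    return [retained[i * window.block_length:(i + 1) * window.block_length]
            for i in range(n_blocks)]


def block_error(
    windows: Sequence[UmbrellaWindow],
    cfg: WhamConfig = WhamConfig(),
    grid_range: Optional[Tuple[float, float]] = None,
):
    """Per-bin SEM across per-block WHAM + shift solutions.

    Returns (sem, block_profiles).  Bins that are empty in some block get
    NaN SEM.
    """
    windows = list(windows)
    per_window_blocks = [_blocks_of(w) for w in windows]
    n_blocks = min(len(b) for b in per_window_blocks)
    if n_blocks < 2:
        raise WhamError("block_error needs at least 2 full blocks")
    if grid_range is None:
        lo = min(w.retained.min() for w in windows)
        hi = max(w.retained.max() for w in windows)
        grid_range = (lo, hi)
    profiles = []
    for b in range(n_blocks):
        block_windows = [
            replace(w, samples=per_window_blocks[j][b], n_equilibration_discard=0)
            for j, w in enumerate(windows)
        ]
        prof = wham_solve(block_windows, cfg, grid_range=grid_range)
        profiles.append(shift_profile(prof, cfg.bulk_points))
    g = np.stack([p.free_energy for p in profiles])
    with np.errstate(invalid="ignore"):
        finite = np.isfinite(g).all(axis=0)
        sem = np.full(g.shape[1], np.nan)
        sem[finite] = g[:, finite].std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return sem, profiles


def compute_pmf(
    windows: Sequence[UmbrellaWindow],
    cfg: WhamConfig = WhamConfig(),
    grid_range: Optional[Tuple[float, float]] = None,
    errors: bool = True,
) -> PMFProfile:
    """Full pipeline: WHAM, bulk shift, and (optionally) block SEM."""
    profile = shift_profile(wham_solve(windows, cfg, grid_range), cfg.bulk_points)
    if errors:
        sem, _ = block_error(windows, cfg, grid_range)
        profile = replace(profile, error=sem)
    return profile


@dataclass(frozen=True)
class PMFFeatures:
    """Scalar features of a shifted PMF.

    sf_barrier: highest free energy inside the selectivity-filter region.
    global_minimum / minimum_position: deepest point of the profile.
    luminal_to_cytosolic_barrier: what an ion entering from the luminal side
    must climb — the maximum past the global minimum (toward the cytosolic
    end, increasing ξ) minus the minimum.
    """

    sf_barrier: float
    global_minimum: float
    minimum_position: float
    luminal_to_cytosolic_barrier: float


def extract_features(
    profile: PMFProfile,
    sf_region: Optional[Tuple[float, float]] = None,
) -> PMFFeatures:
    """Read barrier/minimum features off a shifted profile.

    sf_region defaults to the 10% of the coordinate range nearest the
    luminal (low-ξ) end.
    """
    xi, g = profile.xi, profile.free_energy
    finite = np.isfinite(g)
    if not finite.any():
        raise WhamError("profile has no finite bins")
    if sf_region is None:
        lo = xi[0]
        sf_region = (lo, lo + 0.1 * (xi[-1] - xi[0]))
    a, b = sf_region
    in_region = (xi >= a) & (xi <= b) & finite
    if not in_region.any():
        raise WhamError(f"sf_region ({a}, {b}) contains no finite bins")
    sf_barrier = float(g[in_region].max())
    idx_min = int(np.argmin(np.where(finite, g, np.inf)))
    g_min = float(g[idx_min])
    after = finite & (np.arange(g.size) >= idx_min)
    barrier = float(g[after].max() - g_min)
    return PMFFeatures(
        sf_barrier=sf_barrier,
        global_minimum=g_min,
        minimum_position=float(xi[idx_min]),
        luminal_to_cytosolic_barrier=barrier,
    )
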