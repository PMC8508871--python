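"""First-shell hydration counting along a permeation coordinate.

Counts water oxygens within a species-specific cutoff of an ion (minimum
image under an orthorhombic box if given) and aggregates per-window count
series into a hydration-number profile with block SEM, using the same
n-block convention as the free-energy errors (one block per simulated
nanosecond).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CUTOFFS",
    "count_shell",
    "shell_count_series",
    "hydration_profile",
    "HydrationProfile",
]

#: default ion–oxygen first-shell cutoffs (Å), at the first minimum of the
#: respective ion–water-oxygen radial distribution function
DEFAULT_CUTOFFS = {"K": 3.5, "NA": 3.2, "CA": 3.2}


def count_shell(
    ion_xyz,
    water_oxygens_xyz,
    cutoff: float,
    box: Optional[Sequence[float]] = None,
) -> int:
    """Number of water oxygens with (minimum-image) distance <= cutoff.

    box: optional orthorhombic box lengths (3,) for periodic wrapping.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ion = np.asarray(ion_xyz, dtype=float).reshape(3)
    ox = np.asarray(water_oxygens_xyz, dtype=float).reshape(-1, 3)
    if ox.size == 0:
        return 0
    d = ox - ion
    if box is not None:
        box = np.asarray(box, dtype=float).reshape(3)
        if np.any(box <= 0):
            raise ValueError("box lengths must be positive")
        d -= box * np.round(d / box)
    dist = np.linalg.norm(d, axis=1)
    return int(np.count_nonzero(dist <= cutoff))


def shell_count_series(
    ion_traj,
    water_traj,
    cutoff: float,
    box: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Per-frame shell counts for an ion trajectory (n, 3) against a water
    oxygen trajectory (n, m, 3)."""
    ion_traj = np.asarray(ion_traj, dtype=float)
    water_traj = np.asarray(water_traj, dtype=float)
    if len(ion_traj) != len(water_traj):
        raise ValueError("ion and water trajectories differ in frame count")
    return np.array([
        count_shell(ion_traj[t], water_traj[t], cutoff, box)
        for t in range(len(ion_traj))
    ])


@dataclass(frozen=True)
class HydrationProfile:
    """Mean hydration number ± block SEM per window position."""

    table: pd.DataFrame   # columns: xi, mean, sem, n_blocks, cutoff

    @property
    def xi(self) -> np.ndarray:
        return self.table["xi"].to_numpy()

    @property
    def mean(self) -> np.ndarray:
        return self.table["mean"].to_numpy()

    @property
    def sem(self) -> np.ndarray:
        return self.table["sem"].to_numpy()


def hydration_profile(
    windows: Sequence[Tuple[float, np.ndarray]],
    cutoff: float,
    block_length: int,
) -> HydrationProfile:
    """Aggregate per-window count series into a profile.

    windows      : sequence of (window position ξ, per-frame integer counts)
    block_length : frames per block (nominally one simulated nanosecond);
                   the mean is taken per block and the SEM across blocks
                   (n−1 denominator)
    """
    if block_length < 2:
        raise ValueError("block_length must be >= 2 frames")
    rows = []
    for xi, counts in windows:
        counts = np.asarray(counts, dtype=float).ravel()
        if counts.size == 0:
            raise ValueError(f"window at xi={xi} has no frames")
        n_blocks = counts.size // block_length
        if n_blocks < 1:
            raise ValueError(
                f"window at xi={xi}: {counts.size} frames < one block "
                f"({block_length})"
            )
        block_means = counts[: n_blocks * block_length].reshape(
            n_blocks, block_length).mean(axis=1)
        mean = float(block_means.mean())
        sem = (float(block_means.std(ddof=1) / np.sqrt(n_blocks))
               if n_blocks > 1 else np.nan)
        rows.append((float(xi), mean, sem, n_blocks, cutoff))
    table = pd.DataFrame(rows, columns=["xi", "mean", "sem", "n_blocks",
                                        "cutoff"]).sort_values("xi",
                                                               ignore_index=True)
    return HydrationProfile(table=table)
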