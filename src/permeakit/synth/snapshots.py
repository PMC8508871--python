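"""Hydration-shell snapshot fixtures.

Places an exact number of water oxygens at a first-shell distance and a
second batch at an outer distance around an ion, in deterministic random
orientations, so shell-counting code can be checked against scheduled
counts.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_hydration_snapshot"]


def _random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # degenerate draws are essentially impossible; guard anyway
    norm[norm == 0] = 1.0
    return v / norm


def make_hydration_snapshot(
    ion_position,
    n_first_shell: int,
    r_first: float,
    n_outer: int,
    r_outer: float,
    seed: int = 0,
):
    """Return (ion_xyz (3,), oxygen_xyz (n_first+n_outer, 3)).

    Exactly ``n_first_shell`` oxygens sit at distance ``r_first`` from the
    ion and ``n_outer`` at ``r_outer``.  Orientations are uniform on the
    sphere and reproducible for a fixed seed.
    """
    if n_first_shell < 0 or n_outer < 0:
        raise ValueError("shell counts must be >= 0")
    if (n_first_shell and r_first <= 0) or (n_outer and r_outer <= 0):
        raise ValueError("shell radii must be positive")
    ion = np.asarray(ion_position, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)
    first = ion + r_first * _random_unit_vectors(n_first_shell, rng)
    outer = ion + r_outer * _random_unit_vectors(n_outer, rng)
    return ion, np.concatenate([first, outer], axis=0)
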