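"""Scripted membrane-crossing trajectories.

Generates per-ion z(t) series with an exactly known number of complete
passes through a slab (the selectivity-filter region), so the permeation
counter can be validated against ground truth.  Between scheduled
crossings the ion rests well outside the slab planes (margin >> noise), and
during a crossing window it moves smoothly from one side to the other.

Consecutive same-direction crossings are realized the periodic-boundary
way: after passing upward through the slab the ion keeps drifting upward
into the next periodic image's "below" region, exactly as an ion that
recirculates through a periodic box.  Output can optionally be wrapped into
[0, Lz) to exercise trajectory unwrapping downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["ScheduledCrossing", "CrossingScript", "make_crossing_trajectories"]


@dataclass(frozen=True)
class ScheduledCrossing:
    """One planned slab traversal: direction +1 (up, toward +z) or −1, over
    frames [start, end]."""

    direction: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if not (0 <= self.start < self.end):
            raise ValueError("need 0 <= start < end")


@dataclass(frozen=True)
class CrossingScript:
    """Schedule of crossings for a set of ions.

    schedules    : per-ion sequence of ScheduledCrossing, time-ordered
    slab_lower/upper : slab plane positions, Å
    n_frames     : trajectory length
    box_length_z : Å; if set, output may be wrapped and must satisfy
                   Lz > slab height + 2*margin
    noise_sd     : Å of Gaussian jitter added everywhere
    margin       : Å rest-distance from the nearest plane (>= 6*noise_sd
                   keeps scheduled counts exact)
    wrap         : wrap output into [0, Lz)
    """

    schedules: Tuple[Tuple[ScheduledCrossing, ...], ...]
    slab_lower: float
    slab_upper: float
    n_frames: int
    box_length_z: float | None = None
    noise_sd: float = 0.3
    margin: float = 5.0
    wrap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedules", tuple(
            tuple(c if isinstance(c, ScheduledCrossing) else ScheduledCrossing(*c)
                  for c in ion)
            for ion in self.schedules
        ))
        if not self.slab_lower < self.slab_upper:
            raise ValueError("slab_lower must be < slab_upper")
        if self.margin < 6.0 * self.noise_sd:
            raise ValueError("margin must be >= 6*noise_sd to keep counts exact")
        if self.wrap and self.box_length_z is None:
            raise ValueError("wrap=True requires box_length_z")
        if self.box_length_z is not None:
            if self.box_length_z <= (self.slab_upper - self.slab_lower) + 2 * self.margin:
                raise ValueError("box_length_z too small for slab plus margins")
        for i, ion in enumerate(self.schedules):
            for a, b in zip(ion, ion[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping crossing windows for ion {i}")
                if self.box_length_z is None and a.direction == b.direction:
                    raise ValueError(
                        f"ion {i}: consecutive same-direction crossings require "
                        "a periodic box (box_length_z)"
                    )
            if ion and ion[-1].end >= self.n_frames:
                raise ValueError(f"crossing window beyond n_frames for ion {i}")

    @property
    def scheduled_counts(self) -> Tuple[Tuple[int, int], ...]:
        """Per-ion (n_up, n_down)."""
        return tuple(
            (sum(1 for c in ion if c.direction > 0),
             sum(1 for c in ion if c.direction < 0))
            for ion in self.schedules
        )


def _rest_levels(script: CrossingScript):
    below = script.slab_lower - script.margin
    above = script.slab_upper + script.margin
    return below, above


def make_crossing_trajectories(script: CrossingScript) -> np.ndarray:
    """Build the z(t) array, shape (n_ions, n_frames)."""
    rng = np.random.default_rng(script.seed)
    period = script.box_length_z if script.box_length_z is not None else (
        # fictitious period for the unwrapped bookkeeping of repeated
        # same-direction crossings when no box is declared
        (script.slab_upper - script.slab_lower) + 4.0 * script.margin
    )
    below0, above0 = _rest_levels(script)
    out = np.empty((len(script.schedules), script.n_frames))

    for i, ion in enumerate(script.schedules):
        z = np.empty(script.n_frames)
        # current rest level in unwrapped coordinates and its type
        if ion and ion[0].direction < 0:
            level, at_above = above0, True
        else:
            level, at_above = below0, False
        t = 0
        for c in ion:
            # drift (crossing nothing) to the next periodic image's staging
            # level when the previous crossing had the same direction
            if c.direction > 0 and at_above:
                target = level + (below0 + period - above0)
            elif c.direction < 0 and not at_above:
                target = level - (below0 + period - above0)
            else:
                target = level
            if target != level:
                gap = c.start - t
                if gap < 1:
                    raise ValueError(
                        "need >= 1 idle frame between same-direction crossings"
                    )
                z[t:c.start] = np.linspace(level, target, gap, endpoint=False)
                t = c.start
                level = target
                at_above = not at_above
            # hold until the window opens
            z[t:c.start] = level
            t = c.start
            # smooth (cosine) traversal through the slab
            span = (above0 - below0) * c.direction
            n = c.end - c.start + 1
            s = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n)))
            z[c.start:c.end + 1] = level + span * s
            level = level + span
            at_above = not at_above
            t = c.end + 1
        z[t:] = level
        z += rng.normal(0.0, script.noise_sd, size=script.n_frames)
        out[i] = z

    if script.wrap:
        out = np.mod(out, script.box_length_z)
    return out
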