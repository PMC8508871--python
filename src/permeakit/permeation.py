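"""Permeation-event counting and field/voltage/flux conversions.

A complete permeation is registered with a two-plane hysteresis rule: an
ion last seen strictly below the slab's lower plane must later be seen
strictly above the upper plane (upward event), or vice versa.  Rattling
between the planes counts nothing, and after an event the ion must fully
exit on the far side before an opposite-direction event can begin.  Under a
periodic box the z series is unwrapped first (minimum-image increments), so
an ion recirculating through the box boundary is counted once per full
passage.

Also provided: Table-style flux summaries (mean ± SD, range, median over
replicas), conversion of an applied uniform field to the equivalent
transmembrane voltage, and the expected ion count for a given single-channel
conductance, voltage and time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import ELEMENTARY_CHARGE_C, KCAL_PER_MOL_E_TO_VOLT

__all__ = [
    "SlabSpec",
    "CrossingEvent",
    "count_crossings",
    "unwrap_z",
    "summarize_flux",
    "field_to_voltage",
    "expected_crossings",
]


@dataclass(frozen=True)
class SlabSpec:
    """The selectivity-filter slab along z.

    cytosol_side: "lower" if the cytosol is at low z (then upward events are
    cytosol→lumen), "upper" otherwise.  Explicit to keep the sign convention
    of applied voltages unambiguous.
    """

    z_lower: float
    z_upper: float
    box_length_z: Optional[float] = None
    cytosol_side: str = "lower"

    def __post_init__(self) -> None:
        if not self.z_lower < self.z_upper:
            raise ValueError("z_lower must be < z_upper")
        if self.cytosol_side not in ("lower", "upper"):
            raise ValueError("cytosol_side must be 'lower' or 'upper'")
        if self.box_length_z is not None:
            if self.box_length_z <= self.z_upper - self.z_lower:
                raise ValueError("box_length_z must exceed the slab height")

    def direction_label(self, upward: bool) -> str:
        if (self.cytosol_side == "lower") == upward:
            return "cytosol->lumen"
        return "lumen->cytosol"


@dataclass(frozen=True)
class CrossingEvent:
    """One complete slab passage."""

    ion: int
    direction: str        # "cytosol->lumen" or "lumen->cytosol"
    upward: bool          # toward +z
    frame: int            # completion frame


def unwrap_z(z: np.ndarray, box_length: float) -> np.ndarray:
    """Remove periodic jumps via minimum-image increments."""
    z = np.asarray(z, dtype=float)
    d = np.diff(z)
    d -= box_length * np.round(d / box_length)
    return np.concatenate([[z[0]], z[0] + np.cumsum(d)])


def _classify(u: float, slab: SlabSpec, period: Optional[float]):
    """Return ('inside', band) or ('gap', g): gap g lies between band g and
    band g+1.  Non-periodic: bands other than 0 do not exist; below the slab
    is gap −1, above is gap 0."""
    if period is None:
        if u < slab.z_lower:
            return ("gap", -1)
        if u > slab.z_upper:
            return ("gap", 0)
        return ("inside", 0)
    k = int(np.floor((u - slab.z_lower) / period))
    rem = u - (slab.z_lower + k * period)
    if rem <= slab.z_upper - slab.z_lower:
        return ("inside", k)
    return ("gap", k)


def count_crossings(
    z_series: np.ndarray,
    slab: SlabSpec,
    ion: int = 0,
) -> List[CrossingEvent]:
    """Hysteresis counting of complete slab passages for one ion."""
    z = np.asarray(z_series, dtype=float).ravel()
    if not np.all(np.isfinite(z)):
        raise ValueError("z series must be finite")
    if z.size == 0:
        return []
    period = slab.box_length_z
    if period is not None:
        d = np.diff(z)
        dm = np.abs(d - period * np.round(d / period))
        # a minimum-image increment at ~half the box is ambiguous: the
        # unwrapping direction is then a coin toss
        big = np.nonzero(dm >= 0.499 * period)[0]
        if big.size:
            warnings.warn(
                f"ion {ion}: {big.size} frame-to-frame jumps are ~box/2 after "
                f"unwrapping and ambiguous (first at frame {big[0] + 1})",
                stacklevel=2,
            )
        u = unwrap_z(z, period)
    else:
        u = z

    events: List[CrossingEvent] = []
    state, idx = _classify(u[0], slab, period)
    # entered_from: gap index the ion came from when inside a band
    entered_from: Optional[int] = None

    def emit(upward: bool, frame: int, n: int = 1) -> None:
        for _ in range(n):
            events.append(CrossingEvent(
                ion=ion, direction=slab.direction_label(upward),
                upward=upward, frame=frame))

    for t in range(1, u.size):
        new_state, new_idx = _classify(u[t], slab, period)
        if (new_state, new_idx) == (state, idx):
            continue
        if state == "gap":
            if new_state == "inside":
                if new_idx > idx:
                    # moving up: fully traversed bands idx+1 .. new_idx-1,
                    # now inside band new_idx entered from below
                    emit(True, t, new_idx - 1 - idx)
                    entered_from = new_idx - 1
                else:
                    # moving down: fully traversed bands idx .. new_idx+1
                    emit(False, t, idx - new_idx)
                    entered_from = new_idx
            else:
                # gap -> different gap: passed |Δ| full bands in one stride
                n_bands = new_idx - idx
                emit(n_bands > 0, t, abs(n_bands))
        else:  # inside band idx
            if new_state == "gap":
                if new_idx >= idx:
                    # exited above: current band completed only if entered
                    # from below; bands idx+1 .. new_idx traversed fully
                    armed = 1 if entered_from == idx - 1 else 0
                    emit(True, t, (new_idx - idx) + armed)
                else:
                    armed = 1 if entered_from == idx else 0
                    emit(False, t, (idx - 1 - new_idx) + armed)
                entered_from = None
            else:
                # inside -> inside a different band in one stride
                moving_up = new_idx > idx
                n_full = abs(new_idx - idx) - 1
                completed_current = (
                    (moving_up and entered_from == idx - 1)
                    or (not moving_up and entered_from == idx)
                )
                emit(moving_up, t, n_full + (1 if completed_current else 0))
                entered_from = new_idx - 1 if moving_up else new_idx
        state, idx = new_state, new_idx
    return events


def summarize_flux(
    counts_by_direction: Dict[str, Sequence[float]],
    include_total: bool = True,
) -> pd.DataFrame:
    """Replica statistics of permeation counts, one row per direction.

    counts_by_direction maps a direction label to the per-replica event
    counts.  Reports mean ± SD (n−1; NaN for a single replica), the
    min–max range, and the median.  With include_total, a 'total' row sums
    directions replica-wise (all directions must then have equally many
    replicas).
    """
    if not counts_by_direction:
        raise ValueError("no counts given")
    data = {k: np.asarray(v, dtype=float) for k, v in counts_by_direction.items()}
    for k, v in data.items():
        if v.size == 0:
            raise ValueError(f"direction {k!r} has no replicas")
    rows = {}
    if include_total and len(data) > 1:
        sizes = {v.size for v in data.values()}
        if len(sizes) != 1:
            raise ValueError("total requires equal replica counts per direction")
        rows["total"] = sum(data.values())
    rows.update(data)
    out = []
    for label, v in rows.items():
        out.append({
            "direction": label,
            "n_replicas": v.size,
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
            "min": float(v.min()),
            "max": float(v.max()),
            "median": float(np.median(v)),
        })
    return pd.DataFrame(out).set_index("direction")


def field_to_voltage(field: float, box_length_z: float) -> float:
    """Transmembrane voltage (V) equivalent to a uniform applied field.

    field: kcal mol^-1 Å^-1 e^-1; box_length_z: Å.  ΔV = E · L_z · 0.0433641.
    """
    if box_length_z <= 0:
        raise ValueError("box_length_z must be positive")
    return field * box_length_z * KCAL_PER_MOL_E_TO_VOLT


def expected_crossings(
    conductance_pS: float,
    voltage_V: float,
    interval_ns: float,
    valence: int,
):
    """Expected ion count N = G·ΔV·Δt / (|z| e) for a single channel.

    Returns (N as a float, nearest integer).
    """
    if valence == 0:
        raise ValueError("valence must be nonzero")
    if conductance_pS <= 0 or voltage_V <= 0 or interval_ns <= 0:
        raise ValueError("conductance, voltage and interval must be positive")
    charge = conductance_pS * 1e-12 * voltage_V * interval_ns * 1e-9
    n = charge / (abs(valence) * ELEMENTARY_CHARGE_C)
    return n, int(round(n))
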