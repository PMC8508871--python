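"""Goldman–Hodgkin–Katz constant-field flux model.

For a species X with valence z, relative permeability P and concentrations
[X]_cyt / [X]_lum on the two membrane sides, the GHK charge-weighted flux
at voltage V (convention: V = φ_cytosol − φ_lumen; positive flux moves
cations cytosol→lumen) is

    Φ_X(V) = P z u ([X]_cyt − [X]_lum e^{−u}) / (1 − e^{−u}),   u = zFV/RT,

which is the familiar GHK current equation up to the constant factor F²V/RT
per unit area.  The V→0 limit is Φ = P z ([X]_cyt − [X]_lum), implemented
through expm1 so the function is numerically continuous through V = 0.
Total current is proportional to Σ_X Φ_X, is strictly monotone in V, and
its unique zero is the reversal potential.  Under bi-ionic conditions (one
permeant species per side) the measured reversal potential fixes the
permeability ratio P_B/P_A, which is how "relative permeabilities" of
channels are derived from zero-current voltages.

The model assumes independent ion movement through a homogeneous membrane
— exactly the assumption that fails for a single-file pore, where opposing
fluxes block each other instead of compensating electrically (see
``permeakit.synth.lattice`` for the contrasting model).  Activity
coefficients are ignored: concentrations are used as activities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .constants import thermal_voltage

__all__ = [
    "IonSpecies",
    "GhkSetup",
    "ghk_flux",
    "total_current",
    "reversal_potential",
    "bi_ionic_permeability_ratio",
    "nernst_potential",
]

DEFAULT_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class IonSpecies:
    """An ion species in a GHK setup (concentrations in mM)."""

    name: str
    valence: int
    conc_cytosolic: float
    conc_luminal: float
    permeability: float = 1.0

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise ValueError("valence must be a nonzero integer")
        if self.conc_cytosolic < 0 or self.conc_luminal < 0:
            raise ValueError("concentrations must be >= 0")
        if self.permeability < 0:
            raise ValueError("permeability must be >= 0")


@dataclass(frozen=True)
class GhkSetup:
    """Species list plus temperature; voltage convention V = φ_cyt − φ_lum."""

    species: Tuple[IonSpecies, ...]
    temperature_k: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not self.species:
            raise ValueError("need at least one species")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")
        if not any(s.permeability > 0 for s in self.species):
            raise ValueError("at least one species must have permeability > 0")


def ghk_flux(species: IonSpecies, voltage: float,
             temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Charge-weighted GHK flux Φ (arbitrary units; sign = net cation
    movement cytosol→lumen)."""
    if not np.isfinite(voltage):
        raise ValueError("voltage must be finite")
    z = species.valence
    p = species.permeability
    c_cyt, c_lum = species.conc_cytosolic, species.conc_luminal
    u = z * voltage / thermal_voltage(temperature_k)
    if u == 0.0:
        return p * z * (c_cyt - c_lum)
    em = np.expm1(-u)          # e^{−u} − 1, accurate for tiny u
    return p * z * u * (c_cyt - c_lum * (1.0 + em)) / (-em)


def total_current(setup: GhkSetup, voltage: float) -> float:
    """Signed total current, proportional to Σ_X Φ_X; strictly increasing
    in V whenever some permeant species is present on either side."""
    return sum(ghk_flux(s, voltage, setup.temperature_k) for s in setup.species)


def nernst_potential(species: IonSpecies,
                     temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Equilibrium potential (RT/zF)·ln([X]_lum/[X]_cyt) in volts."""
    if species.conc_cytosolic <= 0 or species.conc_luminal <= 0:
        raise ValueError("Nernst potential needs positive concentrations on both sides")
    return (thermal_voltage(temperature_k) / species.valence) * np.log(
        species.conc_luminal / species.conc_cytosolic)


def reversal_potential(setup: GhkSetup,
                       bracket: Tuple[float, float] = (-0.5, 0.5)) -> float:
    """Voltage at which the total GHK current is zero (bisection bracket in
    volts; unique root by monotonicity)."""
    lo, hi = bracket
    i_lo = total_current(setup, lo)
    i_hi = total_current(setup, hi)
    if i_lo == 0.0:
        return lo
    if i_hi == 0.0:
        return hi
    if np.sign(i_lo) == np.sign(i_hi):
        raise ValueError(
            f"total current does not change sign on [{lo}, {hi}] V: "
            f"I({lo}) = {i_lo:.4g}, I({hi}) = {i_hi:.4g}"
        )
    return float(brentq(lambda v: total_current(setup, v), lo, hi,
                        xtol=1e-12, rtol=8.9e-16))


def bi_ionic_permeability_ratio(
    ion_cytosolic: IonSpecies,
    ion_luminal: IonSpecies,
    v_rev: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Permeability ratio P_luminal/P_cytosolic from a bi-ionic reversal
    potential.

    ion_cytosolic must be present only on the cytosolic side and
    ion_luminal only on the luminal side (bi-ionic condition).  Solves
    Φ_A + (P_B/P_A) Φ_B|_{P=1} = 0 at V = v_rev; at v_rev = 0 this reduces
    to the closed form z_A [A]_cyt / (z_B [B]_lum).
    """
    if ion_cytosolic.conc_luminal != 0 or ion_cytosolic.conc_cytosolic <= 0:
        raise ValueError("cytosolic species must have concentration on the "
                         "cytosolic side only")
    if ion_luminal.conc_cytosolic != 0 or ion_luminal.conc_luminal <= 0:
        raise ValueError("luminal species must have concentration on the "
                         "luminal side only")
    a = replace(ion_cytosolic, permeability=1.0)
    b = replace(ion_luminal, permeability=1.0)
    flux_a = ghk_flux(a, v_rev, temperature_k)
    flux_b = ghk_flux(b, v_rev, temperature_k)
    if flux_b == 0.0:
        raise ValueError("luminal species carries no flux at v_rev; "
                         "ratio is undetermined")
    ratio = -flux_a / flux_b
    if ratio < 0:
        raise ValueError(
            f"no positive permeability ratio reproduces v_rev = {v_rev} V "
            "with these concentrations"
        )
    return float(ratio)
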