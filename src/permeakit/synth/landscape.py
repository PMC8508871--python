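"""Analytic 1D free-energy landscapes and restraint potentials.

A :class:`PotentialSpec` is a sum of Gaussian wells/barriers plus a constant
offset.  It serves as the known ground truth against which the umbrella
sampling + WHAM pipeline is validated: energies and gradients are available
in closed form, and the exact Boltzmann density can be computed by
quadrature.

:class:`BiasSpec` models the restraints used in biased sampling of a single
ion along the pore axis: the harmonic umbrella restraint on the reaction
coordinate, a flat-bottom restraint (zero inside a radius, harmonic
outside), and a lower-bound exclusion restraint (harmonic inside a floor
distance, zero beyond it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "GaussianTerm",
    "PotentialSpec",
    "BiasSpec",
    "evaluate_potential",
    "total_energy",
    "total_gradient",
    "boltzmann_density",
]


@dataclass(frozen=True)
class GaussianTerm:
    """One Gaussian feature of the landscape.

    amplitude : kcal/mol (negative = well, positive = barrier)
    center    : Å
    width     : Å (standard deviation; must be > 0)
    """

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"Gaussian width must be > 0, got {self.width}")
        for name in ("amplitude", "center", "width"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"Gaussian {name} must be finite")


@dataclass(frozen=True)
class PotentialSpec:
    """Sum-of-Gaussians 1D potential U(ξ) = offset + Σ A_i exp(−(ξ−c_i)²/2w_i²)."""

    terms: Tuple[GaussianTerm, ...] = ()
    offset: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(
            t if isinstance(t, GaussianTerm) else GaussianTerm(*t)
            for t in self.terms
        ))
        if not np.isfinite(self.offset):
            raise ValueError("offset must be finite")

    # -- closed-form evaluation -------------------------------------------

    def energy(self, xi):
        xi = _check_coordinate(xi)
        u = np.full_like(xi, self.offset, dtype=float)
        for t in self.terms:
            u += t.amplitude * np.exp(-0.5 * ((xi - t.center) / t.width) ** 2)
        return u if u.ndim else float(u)

    def gradient(self, xi):
        xi = _check_coordinate(xi)
        g = np.zeros_like(xi, dtype=float)
        for t in self.terms:
            d = xi - t.center
            g += t.amplitude * np.exp(-0.5 * (d / t.width) ** 2) * (-d / t.width**2)
        return g if g.ndim else float(g)

    def term_arrays(self):
        """(amplitudes, centers, widths) as float64 arrays for the integrator."""
        if not self.terms:
            z = np.zeros(0)
            return z, z.copy(), np.ones(0)
        a = np.array([t.amplitude for t in self.terms], dtype=float)
        c = np.array([t.center for t in self.terms], dtype=float)
        w = np.array([t.width for t in self.terms], dtype=float)
        return a, c, w


_BIAS_KINDS = ("harmonic", "flat_bottom", "lower_bound")


@dataclass(frozen=True)
class BiasSpec:
    """A restraint acting on the 1D coordinate.

    kind            : "harmonic", "flat_bottom", or "lower_bound"
    center          : Å, reference point of the restraint
    force_constant  : kcal mol^-1 Å^-2 (≥ 0)
    radius_or_floor : Å; flat-bottom radius or exclusion floor distance
                      (unused for "harmonic")

    Energies:
      harmonic    W = ½ k (ξ − c)²
      flat_bottom W = 0 for |ξ−c| ≤ r, else ½ k (|ξ−c| − r)²
      lower_bound W = 0 for |ξ−c| ≥ d_min, else ½ k (|ξ−c| − d_min)²
    """

    kind: str
    center: float
    force_constant: float
    radius_or_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _BIAS_KINDS:
            raise ValueError(f"unknown bias kind {self.kind!r}; expected one of {_BIAS_KINDS}")
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.radius_or_floor < 0:
            raise ValueError("radius_or_floor must be >= 0")

    @property
    def kind_code(self) -> int:
        return _BIAS_KINDS.index(self.kind)

    def energy(self, xi):
        xi = _check_coordinate(xi)
        d = xi - self.center
        k = self.force_constant
        if self.kind == "harmonic":
            w = 0.5 * k * d**2
        else:
            ad = np.abs(d)
            excess = ad - self.radius_or_floor
            if self.kind == "flat_bottom":
                w = np.where(excess > 0, 0.5 * k * excess**2, 0.0)
            else:  # lower_bound
                w = np.where(excess < 0, 0.5 * k * excess**2, 0.0)
        return w if np.ndim(w) else float(w)

    def gradient(self, xi):
        xi = _check_coordinate(xi)
        d = xi - self.center
        k = self.force_constant
        if self.kind == "harmonic":
            g = k * d
        else:
            ad = np.abs(d)
            excess = ad - self.radius_or_floor
            sgn = np.sign(d)
            if self.kind == "flat_bottom":
                g = np.where(excess > 0, k * excess * sgn, 0.0)
            else:
                g = np.where(excess < 0, k * excess * sgn, 0.0)
        return g if np.ndim(g) else float(g)


def _check_coordinate(xi):
    arr = np.asarray(xi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("reaction coordinate must be finite")
    return arr


def evaluate_potential(spec: PotentialSpec, xi):
    """Energy (kcal/mol) and gradient (kcal mol^-1 Å^-1) of the landscape at ξ."""
    return spec.energy(xi), spec.gradient(xi)


def total_energy(spec: PotentialSpec, biases: Sequence[BiasSpec], xi):
    """U(ξ) + Σ W_b(ξ) for the given landscape and restraints."""
    u = spec.energy(xi)
    for b in biases:
        u = u + b.energy(xi)
    return u


def total_gradient(spec: PotentialSpec, biases: Sequence[BiasSpec], xi):
    g = spec.gradient(xi)
    for b in biases:
        g = g + b.gradient(xi)
    return g


def boltzmann_density(
    spec: PotentialSpec,
    biases: Iterable[BiasSpec],
    kT: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Normalized Boltzmann density exp(−(U+W)/kT)/Z on a uniform grid.

    Z is computed by trapezoidal quadrature over the grid, so the grid must
    cover essentially all of the probability mass.
    """
    grid = np.asarray(grid, dtype=float)
    u = total_energy(spec, tuple(biases), grid)
    w = np.exp(-(u - np.min(u)) / kT)
    z = np.trapezoid(w, grid)
    return w / z
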