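"""Statistical checks of the Brownian sampler against closed-form results.

The sampler produces correlated series, so naive per-sample statistics are
too optimistic.  The χ²-against-Boltzmann check therefore thins the series
by a stride comfortably above the integrated autocorrelation time before
comparing the histogram to the quadrature Boltzmann density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .synth.landscape import BiasSpec, PotentialSpec, boltzmann_density

__all__ = [
    "integrated_autocorrelation_time",
    "equipartition_ratio",
    "BoltzmannCheck",
    "boltzmann_histogram_test",
]


def integrated_autocorrelation_time(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time (in steps) by FFT, with a
    self-consistent window (stop summing at lag ~ c*tau)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 1.0
    x = x - x.mean()
    f = np.fft.rfft(x, n=2 * n)
    acf = np.fft.irfft(f * np.conjugate(f))[:n].real
    if acf[0] <= 0:
        return 1.0
    acf /= acf[0]
    tau = 1.0
    for m in range(1, n):
        tau += 2.0 * acf[m]
        if m >= c * tau:
            break
    return max(tau, 1.0)


def equipartition_ratio(samples: np.ndarray, force_constant: float,
                        kT: float) -> float:
    """Sample variance of a harmonically restrained coordinate divided by
    the equipartition value kT/k (→ 1 for a well-converged run)."""
    if force_constant <= 0:
        raise ValueError("force_constant must be positive")
    return float(np.var(np.asarray(samples, dtype=float)) / (kT / force_constant))


@dataclass(frozen=True)
class BoltzmannCheck:
    chi2: float
    p_value: float
    dof: int
    n_effective: int
    stride: int
    max_abs_deviation_se: float   # max |observed − expected| / binomial SE


def boltzmann_histogram_test(
    samples: np.ndarray,
    spec: PotentialSpec,
    biases: Sequence[BiasSpec],
    kT: float,
    n_bins: int = 12,
    stride: Optional[int] = None,
    min_expected: float = 10.0,
) -> BoltzmannCheck:
    """χ² comparison of the sampled histogram with the exact Boltzmann
    distribution of U + W, computed by quadrature.

    stride defaults to 3× the integrated autocorrelation time, making the
    thinned samples effectively independent so the χ² reference
    distribution applies.  Sparse edge bins (expected < min_expected
    counts) are merged inward.
    """
    samples = np.asarray(samples, dtype=float)
    if stride is None:
        tau = integrated_autocorrelation_time(samples)
        stride = max(1, int(np.ceil(3.0 * tau)))
    thin = samples[::stride]
    n = thin.size
    lo, hi = thin.min(), thin.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    counts, _ = np.histogram(thin, bins=edges)

    # expected bin probabilities from dense quadrature of the biased density
    fine = np.linspace(lo - 0.25 * (hi - lo), hi + 0.25 * (hi - lo), 20001)
    dens = boltzmann_density(spec, biases, kT, fine)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1])
                                           * np.diff(fine))])
    cdf /= cdf[-1]
    probs = np.diff(np.interp(edges, fine, cdf))
    probs /= probs.sum()
    expected = n * probs

    counts, expected = _merge_sparse_bins(counts, expected, min_expected)
    dof = len(counts) - 1
    if dof < 1:
        raise ValueError("too few populated bins for a chi-square test")
    chi2, p = stats.chisquare(counts, expected)
    se = np.sqrt(expected * (1.0 - expected / n))
    max_dev = float(np.max(np.abs(counts - expected) / np.where(se > 0, se, 1.0)))
    return BoltzmannCheck(chi2=float(chi2), p_value=float(p), dof=dof,
                          n_effective=n, stride=stride,
                          max_abs_deviation_se=max_dev)


def _merge_sparse_bins(counts, expected, min_expected):
    counts = list(counts.astype(float))
    expected = list(expected)
    i = 0
    while i < len(counts):
        if expected[i] < min_expected and len(counts) > 1:
            j = i + 1 if i + 1 < len(counts) else i - 1
            counts[j] += counts[i]
            expected[j] += expected[i]
            del counts[i], expected[i]
        else:
            i += 1
    return np.array(counts), np.array(expected)
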