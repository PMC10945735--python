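"""Subsampling transforms for VAF spectra.

Sequencing a sample of ``S`` cells out of ``N`` redistributes every variant's
abundance hypergeometrically (sampling cells without replacement).  The
expected sampled spectrum is the linear transform

    Vtilde(i) = sum_j V(j) * P_hypergeom(i; N, j, S),    i = 1..S,

applied either to a discrete abundance spectrum (exact hypergeometric pmf) or
to a continuous abundance density from the PDE solver (log-gamma continuation
of the pmf, integrated over the size grid).  Variants sampled to abundance 0
are dropped from the reported spectrum, which is what shifts the *observed*
frequencies upward relative to the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

__all__ = [
    "SampledSpectrum",
    "expected_sampled_vaf",
    "expected_sampled_density",
    "stochastic_sample_spectrum",
    "read_depth_noise",
]


@dataclass(frozen=True)
class SampledSpectrum:
    """Expected (or realized) variant counts at sample abundances 1..S."""

    S: int
    counts: np.ndarray  # index i-1 holds abundance-i count
    parent_N: int

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(1, self.S + 1) / self.S


def expected_sampled_vaf(counts, N: int, S: int) -> SampledSpectrum:
    """Expected sampled spectrum of a discrete abundance spectrum.

    Parameters
    ----------
    counts : array-like
        ``counts[j-1]`` = number of variants at population abundance ``j``,
        for ``j = 1..len(counts)`` (``len(counts) <= N``).
    N, S : int
        Population and sample sizes, ``1 <= S <= N``.
    """
    counts = np.asarray(counts, dtype=float)
    if S > N:
        raise ValueError(f"sample size S={S} exceeds population N={N}")
    if S < 1:
        raise ValueError("S must be >= 1")
    j = np.arange(1, len(counts) + 1)
    nz = counts > 0
    out = np.zeros(S)
    i = np.arange(0, S + 1)
    for jj, vj in zip(j[nz], counts[nz]):
        pmf = hypergeom.pmf(i, N, jj, S)
        out += vj * pmf[1:]
    return SampledSpectrum(S=S, counts=out, parent_N=N)


def _log_hyper_pmf(i: np.ndarray, N: int, kappa: np.ndarray, S: int):
    """Hypergeometric log-pmf continued to real-valued success counts kappa.

    ``C(kappa, i) * C(N-kappa, S-i) / C(N, S)`` via log-gamma differences;
    entries with impossible support return -inf.
    """
    kap = kappa[:, None]
    ii = i[None, :]
    with np.errstate(invalid="ignore"):
        lg = (
            gammaln(kap + 1) - gammaln(ii + 1) - gammaln(kap - ii + 1)
            + gammaln(N - kap + 1) - gammaln(S - ii + 1)
            - gammaln(N - kap - S + ii + 1)
            - (gammaln(N + 1) - gammaln(S + 1) - gammaln(N - S + 1))
        )
    bad = (ii > kap) | (S - ii > N - kap)
    lg = np.where(bad, -np.inf, lg)
    return lg


def expected_sampled_density(kappa, density, N: int, S: int) -> SampledSpectrum:
    """Expected sampled spectrum of a continuous abundance density.

    ``Vtilde(i) = integral V(kappa) P(i; N, kappa, S) dkappa`` evaluated by
    trapezoidal quadrature on the solver grid, with the hypergeometric pmf
    continued to non-integer ``kappa`` through log-gamma differences (stable
    for N up to ~1e6).
    """
    kappa = np.asarray(kappa, dtype=float)
    density = np.asarray(density, dtype=float)
    if S > N:
        raise ValueError(f"sample size S={S} exceeds population N={N}")
    inside = (kappa >= 0.5) & (kappa <= N)
    kap = kappa[inside]
    dens = np.clip(density[inside], 0.0, None)
    # node-centered quadrature weights; the edge cells extend half a unit
    # beyond the first/last node so a unit-spaced grid reproduces the
    # discrete abundance sum exactly
    w = np.empty_like(kap)
    w[1:-1] = 0.5 * (kap[2:] - kap[:-2])
    w[0] = 0.5 * (kap[1] - kap[0]) + 0.5
    w[-1] = 0.5 * (kap[-1] - kap[-2]) + 0.5
    i = np.arange(1, S + 1, dtype=float)
    pmf = np.exp(_log_hyper_pmf(i, N, kap, S))
    out = (w * dens) @ pmf
    return SampledSpectrum(S=S, counts=out, parent_N=N)


def stochastic_sample_spectrum(genealogy, S: int, seed=None) -> SampledSpectrum:
    """Realized spectrum of a uniform sample of S cells from a genealogy."""
    _, spectrum = genealogy.subsample(S, seed=seed)
    return SampledSpectrum(S=S, counts=np.asarray(spectrum, dtype=float),
                           parent_N=genealogy.N)


def read_depth_noise(sampled: SampledSpectrum, depth: int, seed=None) -> np.ndarray:
    """Binomial read-sampling noise around sample frequencies.

    For each variant class (abundance ``i`` holding ``counts[i-1]`` variants,
    rounded to integers for realization), draws reads carrying the variant as
    ``Binomial(depth, i/S)`` and returns the array of observed frequencies
    (one entry per variant).  Emulates bulk-sequencing noise only; no
    sequencing-error model.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = []
    for i, c in enumerate(np.rint(sampled.counts).astype(int), start=1):
        if c <= 0:
            continue
        reads = rng.binomial(depth, i / sampled.S, size=c)
        freqs.append(reads / depth)
    if not freqs:
        return np.empty(0)
    return np.concatenate(freqs)
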