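"""Single-cell mutational-burden statistics and the (mu, lambda) estimators.

A cell's burden is the sum of the mutations picked up in each of its past
divisions, ``m_j = sum_i u_ji`` over ``y_j`` divisions.  Without knowing the
distributions of ``y`` and ``u`` beyond independence of the increments,

    E(m) = E(y) E(u),        Var(m) = E(y) Var(u) + E(u)^2 Var(y).

With ``u ~ Poisson(mu)`` these identities invert into estimators for the
expected divisions per lineage, ``E(y) = E(m)/mu``, and -- given a dispersion
assumption ``Var(y)/E(y)`` -- for the mutation rate itself,

    mu_hat = (Var(m)/E(m) - 1) * E(y)/Var(y).

The per-lineage division count integrates the phase-dependent rates: growth
and Moran divisions add on average two mutated daughters per event and hence
count double relative to asymmetric divisions,

    y(t) = int_0^t [ 2 rho (1 - 1/(2N)) + phi + 2 gamma (1 - 1/(N+1)) ] dtau,

phase-split via the Heaviside gating of the rates.  Solving ``y(t) = R`` for
the total homeostatic rate ``lambda = rho + phi`` (with ``rho = (1-p) lambda``)
converts an observed mean burden into a division-rate estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import poisson

from .params import ModelParams, build_params, mixed_phase_onset, population_size

__all__ = [
    "BurdenSample",
    "burden_moments",
    "estimate_divisions",
    "estimate_mu",
    "compound_poisson_pmf",
    "expected_divisions",
    "solve_lambda",
    "lambda_interval",
]


@dataclass(frozen=True)
class BurdenSample:
    """Per-cell mutation counts with summary moments."""

    burdens: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "burdens",
                           np.asarray(self.burdens, dtype=np.int64))

    @property
    def S(self) -> int:
        return len(self.burdens)

    @property
    def mean(self) -> float:
        return float(np.mean(self.burdens))

    @property
    def var(self) -> float:
        return float(np.var(self.burdens, ddof=1)) if self.S > 1 else 0.0

    @property
    def theta(self) -> float:
        """Dispersion ratio Var(m)/E(m); nan when the mean is zero."""
        m = self.mean
        return self.var / m if m > 0 else float("nan")


def burden_moments(sample: BurdenSample) -> tuple[float, float, float, float]:
    """(mean, unbiased variance, dispersion ratio, standard error of mean)."""
    if sample.S < 2:
        raise ValueError("need at least two cells for a variance")
    se = float(np.sqrt(sample.var / sample.S))
    return sample.mean, sample.var, sample.theta, se


def estimate_divisions(mean_burden: float, mu: float) -> float:
    """Expected divisions per lineage, ``E(y) = E(m) / mu``."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return mean_burden / mu


def estimate_mu(mean_burden: float, var_burden: float,
                dispersion: float = 1.0) -> float:
    """Mutation-rate estimator ``(Var(m)/E(m) - 1) / dispersion``.

    ``dispersion = Var(y)/E(y)`` encodes the assumed division-count noise;
    1 corresponds to Poisson-distributed divisions (exponential waiting
    times).  A negative return flags under-dispersed burdens (warned, not
    clamped).
    """
    if mean_burden <= 0:
        raise ValueError("mean burden must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    mu_hat = (var_burden / mean_burden - 1.0) / dispersion
    if mu_hat < 0:
        warnings.warn(
            "burden distribution is under-dispersed (Var < mean); "
            "mutation-rate estimate is negative", stacklevel=2)
    return mu_hat


def compound_poisson_pmf(Ey: float, mu: float, m_range) -> np.ndarray:
    """Pmf of a Poisson(Ey) sum of Poisson(mu) increments on ``m_range``.

    The null model for single-cell burdens: ``y ~ Poisson(Ey)`` divisions,
    each adding ``Poisson(mu)`` mutations.  Mean ``Ey*mu``, variance
    ``Ey*mu*(1+mu)``.
    """
    if Ey <= 0 or mu <= 0:
        raise ValueError("Ey and mu must be positive")
    m = np.asarray(m_range, dtype=np.int64)
    half = 12.0 * np.sqrt(Ey) + 12.0
    ys = np.arange(max(0, int(Ey - half)), int(Ey + half) + 1)
    wy = poisson.pmf(ys, Ey)
    # P(m) = sum_y P(y) Poisson(m; y*mu)
    pm = wy @ poisson.pmf(m[None, :], (ys * mu)[:, None])
    return pm


def _integrand(params: ModelParams, gated: bool):
    """Per-lineage division-rate integrand; `gated` switches homeostasis on."""
    def f(tau):
        N = population_size(params, tau)
        growth = 2.0 * params.gamma * (1.0 - 1.0 / (N + 1.0)) \
            if tau < params.tM else 0.0
        homeo = (2.0 * params.rho * (1.0 - 0.5 / N) + params.phi) if gated else 0.0
        return growth + homeo
    return f


def expected_divisions(params: ModelParams, t: float) -> float:
    """Expected number of divisions per lineage ``y(t)``, by quadrature.

    The integral is split at the mixed-phase onset and at maturity, where the
    integrand switches branch.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    tH = mixed_phase_onset(params)
    total = 0.0
    pieces = [
        (0.0, min(tH, t), False),
        (min(tH, t), min(params.tM, t), True),
        (min(params.tM, t), t, True),
    ]
    for a, b, gated in pieces:
        if b > a:
            total += quad(_integrand(params, gated), a, b, limit=200)[0]
    return total


def solve_lambda(
    R: float,
    NM: float,
    NH: float,
    tM: float,
    p: float,
    t: float,
    growth_kind: str = "exponential-capped",
) -> float:
    """Homeostatic division rate solving ``y(t) = R`` at fixed ``p``.

    ``R = E(m)/mu`` is the observed mean number of divisions per lineage.
    Solved by Brent root finding on the quadrature of ``y(t)``; ``y`` is
    strictly increasing in lambda, so the root is unique when it exists.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if t <= tM:
        raise ValueError("observation age t must exceed maturity tM")

    def y_of_lam(lam):
        pr = build_params(NM=NM, tM=tM, NH=NH, lam=lam, p=p,
                          growth_kind=growth_kind)
        return expected_divisions(pr, t)

    y0 = y_of_lam(0.0)
    if R < y0:
        raise ValueError(
            f"R={R:.3g} is below the growth-phase-only division count "
            f"{y0:.3g}; no homeostatic rate can produce it")
    # bracket: y grows ~ (2-p) * lam * (t - tM)
    hi = max(1.0, 4.0 * (R - y0) / ((2.0 - p) * (t - tM)))
    while y_of_lam(hi) < R:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("failed to bracket lambda")
    return brentq(lambda lam: y_of_lam(lam) - R, 0.0, hi, xtol=1e-10,
                  rtol=1e-12)


def lambda_interval(
    mean_burden: float,
    se_mean: float,
    mu: float,
    t: float,
    p: float = 0.0,
    tM_range=(1.0, 10.0),
    NH_range=(2.0, 1000.0),
    NM_range=(2e4, 5e5),
    n_sweep: int = 3,
) -> dict:
    """Central lambda plus two interval notions.

    ``sweep``: the (min, max) of the point estimate over a grid of the
    nuisance parameters ``(tM, NH, NM)`` (the structural uncertainty);
    ``se``: the interval from propagating the standard error of the mean
    burden at the central nuisance values.  Both are reported because they
    answer different questions.
    """
    R = estimate_divisions(mean_burden, mu)
    tMs = np.linspace(*tM_range, n_sweep)
    NHs = np.geomspace(*NH_range, n_sweep)
    NMs = np.geomspace(*NM_range, n_sweep)
    central_args = dict(NM=float(np.sqrt(NM_range[0] * NM_range[1])),
                        NH=float(np.sqrt(NH_range[0] * NH_range[1])),
                        tM=float(np.mean(tM_range)))
    central = solve_lambda(R, p=p, t=t, **central_args)
    sweep = []
    for tMv in tMs:
        for NHv in NHs:
            for NMv in NMs:
                try:
                    sweep.append(solve_lambda(R, NM=NMv, NH=NHv, tM=tMv,
                                              p=p, t=t))
                except ValueError:
                    continue
    R_lo = estimate_divisions(max(mean_burden - se_mean, 1e-12), mu)
    R_hi = estimate_divisions(mean_burden + se_mean, mu)
    se_iv = (solve_lambda(R_lo, p=p, t=t, **central_args),
             solve_lambda(R_hi, p=p, t=t, **central_args))
    return {
        "lambda": central,
        "sweep_interval": (float(np.min(sweep)), float(np.max(sweep))),
        "se_interval": se_iv,
        "R": R,
    }
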