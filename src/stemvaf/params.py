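"""Demographic and mutational parameters of the three-phase stem cell model.

The tissue is modelled as a well-mixed pool of stem cells that expands from a
single founder to a mature size ``NM`` and is then maintained at constant size.
Three phases are distinguished:

* an **early growth** phase (``t < tM`` and ``N <= NH``) driven purely by
  symmetric self-renewing divisions at per-cell rate ``gamma``;
* a **mixed** phase (``t < tM`` and ``N > NH``) in which growth divisions run
  alongside homeostatic turnover -- Moran events (a symmetric division paired
  with a removal) at rate ``rho`` and asymmetric divisions at rate ``phi``;
* a **mature** phase (``t >= tM``) of pure homeostasis at constant ``N = NM``.

Every daughter cell produced by any division acquires ``Poisson(mu)`` novel
mutations under the infinite-sites assumption.

The homeostatic rates are canonically parameterised by the total division rate
``lam = rho + phi`` and the asymmetric fraction ``p = phi / lam``, because the
population-size inference operates in ``(N, p)`` space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "ModelParams",
    "build_params",
    "rates_at",
    "population_size",
    "mixed_phase_onset",
]

_GROWTH_KINDS = ("exponential-capped", "logistic", "linear-adult")


@dataclass(frozen=True)
class ModelParams:
    """All rates of the three-phase model (units: cells, years).

    Attributes
    ----------
    NM : float
        Mature (carrying-capacity) population size, cells.
    tM : float
        Age at which the population reaches mature size, years.
    NH : float
        Population size at which homeostatic divisions switch on.
    gamma : float
        Growth-division rate per cell per year during expansion.
    rho : float
        Symmetric homeostatic (Moran) division rate per cell per year.
    phi : float
        Asymmetric division rate per cell per year.
    mu : float
        Mutation rate, mutations per daughter cell per division.
    p : float
        Asymmetric fraction of homeostatic divisions, ``phi / (rho + phi)``.
    lam : float
        Total homeostatic division rate ``rho + phi``.
    growth_kind : str
        One of ``exponential-capped``, ``logistic``, ``linear-adult``.
    linear_slope : float
        Relative adult growth slope ``c`` (per year) for ``linear-adult``:
        ``N(t) = NM * (1 + c*(t - tM))`` after maturity.
    """

    NM: float
    tM: float
    NH: float
    gamma: float
    rho: float
    phi: float
    mu: float
    p: float
    lam: float
    growth_kind: str = "exponential-capped"
    linear_slope: float = 0.005

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with fields replaced; (lam, p) stay consistent."""
        new = replace(self, **kwargs)
        if {"lam", "p"} & set(kwargs) and not {"rho", "phi"} & set(kwargs):
            return build_params(
                NM=new.NM, tM=new.tM, NH=new.NH, lam=new.lam, p=new.p,
                mu=new.mu, growth_kind=new.growth_kind,
                linear_slope=new.linear_slope,
            )
        return new


def build_params(
    NM: float,
    tM: float,
    NH: float = 1.0,
    lam: float = 0.0,
    p: float = 0.0,
    mu: float = 1.0,
    growth_kind: str = "exponential-capped",
    linear_slope: float = 0.005,
) -> ModelParams:
    """Construct a validated :class:`ModelParams`.

    ``gamma`` is derived from the requirement that exponential growth from a
    single cell reaches ``NM`` at ``tM``: ``gamma = ln(NM) / tM``.  The
    homeostatic rates are split as ``rho = (1-p)*lam``, ``phi = p*lam``.
    """
    if NM < 2:
        raise ValueError(f"NM must be >= 2 cells, got {NM}")
    if tM <= 0:
        raise ValueError(f"tM must be positive, got {tM}")
    if not (1 <= NH <= NM):
        raise ValueError(f"NH must lie in [1, NM]={[1, NM]}, got {NH}")
    if lam < 0:
        raise ValueError(f"lam must be non-negative, got {lam}")
    if not (0 <= p <= 1):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if mu < 0:
        raise ValueError(f"mu must be non-negative, got {mu}")
    if growth_kind not in _GROWTH_KINDS:
        raise ValueError(f"growth_kind must be one of {_GROWTH_KINDS}")
    gamma = math.log(NM) / tM
    return ModelParams(
        NM=float(NM), tM=float(tM), NH=float(NH), gamma=gamma,
        rho=(1.0 - p) * lam, phi=p * lam, mu=float(mu), p=float(p),
        lam=float(lam), growth_kind=growth_kind,
        linear_slope=float(linear_slope),
    )


def mixed_phase_onset(params: ModelParams) -> float:
    """Time at which N(t) first exceeds ``NH`` (onset of homeostatic events).

    Analytic for exponential growth; solved numerically (bisection) for the
    logistic growth curve.
    """
    if params.NH <= 1:
        return 0.0
    if params.growth_kind in ("exponential-capped", "linear-adult"):
        return min(math.log(params.NH) / params.gamma, params.tM)
    # logistic: N(t) = NM / (1 + (NM-1) e^{-g t}) with g chosen so that
    # N(tM) = 0.99 NM  (maturity defined at 99% of capacity)
    lo, hi = 0.0, params.tM
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if population_size(params, mid) < params.NH:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _logistic_rate(params: ModelParams) -> float:
    # growth-rate g for the from-one-cell logistic reaching 0.99*NM at tM
    NM = params.NM
    return math.log((NM - 1.0) * 0.99 / 0.01) / params.tM


def population_size(params: ModelParams, t: float) -> float:
    """Deterministic population size N(t) for the configured growth curve.

    ``exponential-capped``: ``min(exp(gamma t), NM)``;
    ``logistic``: logistic growth from one cell, 99% of ``NM`` at ``tM``;
    ``linear-adult``: exponential to ``NM`` at ``tM`` then a slow linear
    adult increase ``NM*(1 + c*(t - tM))``.
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    kind = params.growth_kind
    if kind == "exponential-capped":
        return _capped_exp(params, t)
    if kind == "logistic":
        g = _logistic_rate(params)
        return params.NM / (1.0 + (params.NM - 1.0) * math.exp(-g * t))
    # linear-adult
    if t < params.tM:
        return _capped_exp(params, t)
    return params.NM * (1.0 + params.linear_slope * (t - params.tM))


def _capped_exp(params: ModelParams, t: float) -> float:
    if params.gamma * t >= math.log(params.NM):
        return params.NM
    return math.exp(params.gamma * t)


def rates_at(params: ModelParams, t: float, N: float) -> tuple[float, float, float]:
    """Phase-dependent per-cell rates ``(gamma_eff, rho_eff, phi_eff)``.

    Growth divisions run while ``t < tM``; homeostatic (Moran and asymmetric)
    events run once the population exceeds ``NH``:

    * early phase  (t < tM, N <= NH):  (gamma, 0, 0)
    * mixed phase  (t < tM, N >  NH):  (gamma, rho, phi)
    * mature phase (t >= tM):          (0, rho, phi)
    """
    if t < 0 or N < 1:
        raise ValueError("require t >= 0 and N >= 1")
    growing = t < params.tM
    homeostatic = (N > params.NH) or not growing
    gamma_eff = params.gamma if growing else 0.0
    rho_eff = params.rho if homeostatic else 0.0
    phi_eff = params.phi if homeostatic else 0.0
    return gamma_eff, rho_eff, phi_eff
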