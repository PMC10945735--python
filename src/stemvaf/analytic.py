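"""Closed-form and brute-force reference spectra.

Two regimes of the neutral site-frequency spectrum admit exact expectations:

* the **Moran equilibrium** of a constant population, ``V*(k) = mu * N / k``,
  where ``mu`` counts the new variants injected per birth event;
* the **pure-birth** (strict growth) spectrum, which is on-shape from the very
  first division: ``V_k(t) = 2 mu (t+1) / (k (k+1))`` after ``t`` division
  events, with ``mu`` mutations per daughter (so ``2 mu`` per division).

The small-N master-equation integrator serves as the brute-force oracle for
the Moran result, and the event-time recursion for the pure-birth one.  Note
the convention split: a symmetric division of the full tissue model mutates
*both* daughters, so a per-division rate ``mu`` corresponds to a per-birth
rate ``2 mu`` in the Moran formula above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SpectrumShape",
    "moran_equilibrium",
    "moran_master_iteration",
    "pure_birth_recursion",
    "pure_birth_closed",
    "frequency_spectrum",
]


@dataclass(frozen=True)
class SpectrumShape:
    """A reference spectrum: expected variant counts on an abundance axis.

    ``kind`` is ``"growing"`` or ``"constant"``; ``support`` holds the
    abundances (or frequencies) and ``values`` the expected counts/density,
    linear in the mutation rate.
    """

    kind: str
    support: np.ndarray
    values: np.ndarray


def moran_equilibrium(N: int, mu: float = 1.0) -> SpectrumShape:
    """Equilibrium spectrum of a constant-N Moran population.

    ``V*(k) = mu * N / k`` for ``k = 1..N-1``, with ``mu`` the expected number
    of new variants per birth event.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    k = np.arange(1, N)
    return SpectrumShape(kind="constant", support=k, values=mu * N / k)


def moran_master_iteration(
    N: int,
    mu: float = 1.0,
    rho: float = 1.0,
    t_end: float = None,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Integrate the N-1 coupled Moran master equations to (near) stationarity.

    The per-abundance flux is ``C_k = (k/N)(1 - k/N) V_k`` and

        dV_k/dt = rho * (C_{k-1} + C_{k+1} - 2 C_k),

    with the ``k=1`` influx term ``C_0`` replaced by the fixed rate ``mu`` and
    the reflecting/absorbing boundary at ``k = N`` dropping the middle term.
    Brute-force oracle; intended for small N (<= 200).

    Returns ``V[k]`` for ``k = 1..N-1`` (array of length N-1).
    """
    if N > 200:
        raise ValueError("master-equation oracle is meant for N <= 200")
    k = np.arange(1, N)
    pk = (k / N) * (1.0 - k / N)

    def rhs(_t, v):
        c = pk * v
        dv = np.empty_like(v)
        # interior: C_{k-1} + C_{k+1} - 2 C_k
        dv[1:-1] = c[:-2] + c[2:] - 2.0 * c[1:-1]
        dv[0] = mu + c[1] - 2.0 * c[0]
        dv[-1] = c[-2] - 2.0 * c[-1]
        return rho * dv

    if t_end is None:
        # relaxation time scales like N^2 / rho for the slowest retained mode
        t_end = 50.0 * N * N / rho
    sol = solve_ivp(rhs, (0.0, t_end), np.zeros(N - 1), method="BDF",
                    rtol=rtol, atol=1e-12 * mu * N)
    return sol.y[:, -1]


def pure_birth_recursion(t_events: int, mu: float = 1.0) -> np.ndarray:
    """Expected spectrum of a strictly growing population, in event time.

    Starting from one unmutated cell, each event divides a uniformly chosen
    cell into two daughters carrying ``Poisson(mu)`` new variants each.  The
    expectations obey

        V_k(t+1) = (1 - k/(t+1)) V_k(t) + (k-1)/(t+1) V_{k-1}(t),
        V_1(t+1) = (1 - 1/(t+1)) V_1(t) + 2 mu.

    Returns ``V[k]`` for ``k = 1..t_events`` (array of length ``t_events``).
    """
    if t_events < 1:
        raise ValueError("t_events must be >= 1")
    v = np.zeros(t_events + 1)  # v[0] unused; abundances 1..t_events
    for t in range(t_events):
        kmax = t + 1  # highest abundance reachable after this event
        k = np.arange(2, kmax + 1)
        v[2:kmax + 1] = (1.0 - k / (t + 1)) * v[2:kmax + 1] \
            + (k - 1) / (t + 1) * v[1:kmax]
        v[1] = (1.0 - 1.0 / (t + 1)) * v[1] + 2.0 * mu
    return v[1:]


def pure_birth_closed(k, t_events: int, mu: float = 1.0):
    """Closed form of the pure-birth expectation: ``2 mu (t+1) / (k (k+1))``.

    Valid for ``1 <= k <= t_events``.
    """
    k = np.asarray(k)
    if np.any(k < 1) or np.any(k > t_events):
        raise ValueError("require 1 <= k <= t_events")
    return 2.0 * mu * (t_events + 1) / (k * (k + 1.0))


def frequency_spectrum(kind: str, mu: float, f):
    """Textbook frequency-space shapes of the two regimes.

    ``growing``: ``2 mu / (f + f^2)``; ``constant``: ``mu / f`` up to the
    caller's normalization (fixed to ``mu*N`` in abundance space).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    if kind == "growing":
        return 2.0 * mu / (f + f * f)
    if kind == "constant":
        return mu / f
    raise ValueError("kind must be 'growing' or 'constant'")
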