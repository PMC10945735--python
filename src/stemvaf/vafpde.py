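"""Expected VAF dynamics: method-of-lines solver on a variable-step grid.

The expected number of variants ``V(kappa, t)`` at absolute abundance
``kappa = f * N(t)`` obeys the advection--diffusion equation with a point
influx of new variants at ``kappa = 1``:

    dV/dt = -d/dkappa [A V] + d^2/dkappa^2 [B V] + C(t) delta(kappa - 1),

    A = gamma * kappa,
    B = kappa (1 - kappa/N(t)) rho + gamma kappa / 2,
    C = 2 mu N(t) (rho + gamma + phi/2),

with the phase-gated rates of :func:`stemvaf.params.rates_at`.  Working in
absolute size (not frequency) keeps the influx point fixed while the
population grows.  The size grid has unit spacing at ``kappa = 1`` and steps
growing linearly with index, ``dkappa_i = 1 + (i-1) alpha`` with ``alpha``
fixed by the requirement that the steps exactly span ``[1, N]``.  The delta
influx becomes a step of height ``2 / (dkappa_left + dkappa_right)`` at the
``kappa = 1`` node; boundaries at ``kappa = 0`` (extinction) and
``kappa = N`` (fixation) are absorbing (Dirichlet zero).

A useful discrete property of the flux-conservative central scheme used
here: the constant-N stationary state solves ``B V`` piecewise-linear
exactly, giving ``V = C / (rho kappa)`` on the nodes -- the Moran
equilibrium with per-event influx ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .params import ModelParams, mixed_phase_onset, population_size, rates_at

__all__ = [
    "SizeGrid",
    "VafSolution",
    "build_grid",
    "coefficients",
    "evolve_expected_vaf",
    "transition_profile",
]


@dataclass(frozen=True)
class SizeGrid:
    """Variable-step abundance grid spanning [1, N].

    ``kappa`` holds the ``n`` strictly increasing node positions with
    ``kappa[0] = 1`` and ``kappa[-1] = N``; ``steps[i]`` is the distance
    between nodes i and i+1, growing linearly with index so that the finest
    resolution sits at the influx point.
    """

    n: int
    kappa: np.ndarray
    steps: np.ndarray
    alpha: float

    @property
    def N(self) -> float:
        return float(self.kappa[-1])


def build_grid(N: float, n: int) -> SizeGrid:
    """Grid of ``n`` nodes on [1, N]: ``dkappa_i = 1 + (i-1) alpha``.

    ``alpha = 2 (N - n) / ((n-1)(n-2))`` makes the steps telescope exactly
    from 1 to N (``sum dkappa = N - 1``).
    """
    if n < 4:
        raise ValueError("need at least 4 grid points")
    if N <= n:
        raise ValueError(f"N={N} must exceed the number of grid points n={n}")
    alpha = 2.0 * (N - n) / ((n - 1.0) * (n - 2.0))
    i = np.arange(1, n)
    steps = 1.0 + (i - 1) * alpha
    kappa = np.concatenate(([1.0], 1.0 + np.cumsum(steps)))
    kappa[-1] = N  # exact to rounding
    return SizeGrid(n=n, kappa=kappa, steps=steps, alpha=alpha)


def coefficients(params: ModelParams, kappa, t: float,
                 mature_only: bool = False):
    """Drift A, diffusion B and influx amplitude C at time ``t``.

    ``mature_only`` evaluates the homeostatic branch regardless of ``t``
    (used for constant-population runs).  Coefficients vanish beyond the
    current population size.
    """
    kappa = np.asarray(kappa, dtype=float)
    if mature_only:
        N = params.NM
        g, r, f = 0.0, params.rho, params.phi
    else:
        N = population_size(params, t)
        g, r, f = rates_at(params, t, N)
    # beyond the current population size the solution is (numerically) zero;
    # only the Moran diffusion needs clamping, so coefficients stay smooth in
    # time while N(t) sweeps across the grid
    A = g * kappa
    B = np.clip(kappa * (1.0 - kappa / N), 0.0, None) * r + g * kappa / 2.0
    C = 2.0 * params.mu * N * (r + g + f / 2.0)
    return A, B, C


@dataclass(frozen=True)
class VafSolution:
    """Expected VAF density on the size grid at one observation time."""

    grid: SizeGrid
    values: np.ndarray  # V(kappa_i, t_obs), variants per unit kappa
    t_obs: float
    params: ModelParams
    N_obs: float

    @property
    def kappa(self) -> np.ndarray:
        return self.grid.kappa

    def interp(self, kappa_eval) -> np.ndarray:
        """Linear interpolation of V onto arbitrary abundances."""
        return np.interp(np.asarray(kappa_eval, dtype=float),
                         self.grid.kappa, self.values)

    def total_variants(self) -> float:
        return float(np.trapezoid(np.clip(self.values, 0.0, None),
                                  self.grid.kappa))


class _Operator:
    """Tridiagonal method-of-lines operator on the extended grid.

    Nodes are ``[0] + kappa`` (the extinction boundary prepended); the state
    vector covers interior nodes ``kappa[0..n-2]`` with Dirichlet zero at
    both boundaries.
    """

    def __init__(self, params: ModelParams, grid: SizeGrid,
                 mature_only: bool):
        self.params = params
        self.grid = grid
        self.mature_only = mature_only
        self.x = np.concatenate(([0.0], grid.kappa))  # n+1 nodes
        self.hl = np.diff(self.x)[:-1]   # left step of interior node m
        self.hr = np.diff(self.x)[1:]    # right step
        self.h = 0.5 * (self.hl + self.hr)
        self.n_int = grid.n - 1

    def _AB(self, t):
        A, B, C = coefficients(self.params, self.x, t,
                               mature_only=self.mature_only)
        return A, B, C

    def bands(self, t):
        """Tridiagonal operator bands (lower, diag, upper) and source."""
        A, B, C = self._AB(t)
        # half-step advection coefficients
        a_l = 0.5 * (A[:-2] + A[1:-1])
        a_r = 0.5 * (A[1:-1] + A[2:])
        lower = (0.5 * a_l + B[:-2] / self.hl) / self.h
        diag = (0.5 * a_l - B[1:-1] / self.hl
                - 0.5 * a_r - B[1:-1] / self.hr) / self.h
        upper = -(0.5 * a_r - B[2:] / self.hr) / self.h
        src = np.zeros(self.n_int)
        src[0] = C / self.h[0]  # step approximation of C * delta(kappa - 1)
        return lower, diag, upper, src

    @staticmethod
    def apply(bands, y):
        lower, diag, upper, src = bands
        out = diag * y + src
        out[1:] += lower[1:] * y[:-1]
        out[:-1] += upper[:-1] * y[1:]
        return out

    @staticmethod
    def sparse_jac(bands):
        lower, diag, upper, _ = bands
        return sparse.diags([lower[1:], diag, upper[:-1]],
                            offsets=[-1, 0, 1], format="csc")

    def matrices(self, t):
        bands = self.bands(t)
        return self.sparse_jac(bands), bands[3]


def _solve(params: ModelParams, t_list, n: int, rtol: float, atol: float,
           mature_only: bool, v0=None) -> list[VafSolution]:
    t_list = sorted(float(t) for t in t_list)
    t_end = t_list[-1]
    grid = build_grid(params.NM, n)
    op = _Operator(params, grid, mature_only)

    if mature_only:
        breaks = [0.0, t_end]
    else:
        tH = mixed_phase_onset(params)
        breaks = sorted({0.0, min(tH, t_end), min(params.tM, t_end), t_end})

    if v0 is None:
        v = np.zeros(op.n_int)
    else:
        v0 = np.asarray(v0, dtype=float)
        if len(v0) == grid.n:  # given on the full grid incl. fixation node
            v0 = v0[:-1]
        v = v0.copy()
    outputs: dict[float, np.ndarray] = {}
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b <= a:
            continue
        want = [tt for tt in t_list if a < tt <= b]
        t_eval = sorted(set(want + [b]))

        # coefficients are time-independent once the population is constant
        frozen = mature_only or (
            a >= params.tM and params.growth_kind != "linear-adult")
        if frozen:
            bands0 = op.bands(0.5 * (a + b))
            jac0 = op.sparse_jac(bands0)

            def rhs(t, y, bands=bands0):
                return op.apply(bands, y)

            def jac(t, y, J=jac0):
                return J
        else:
            def rhs(t, y):
                return op.apply(op.bands(t), y)

            def jac(t, y):
                return op.sparse_jac(op.bands(t))

        sol = solve_ivp(rhs, (a, b), v, method="BDF", jac=jac,
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"VAF solver failed on [{a}, {b}] at rtol={rtol}, "
                f"atol={atol}: {sol.message}")
        for tt, col in zip(sol.t, sol.y.T):
            outputs[tt] = col
        v = sol.y[:, -1]

    results = []
    for tt in t_list:
        col = outputs[tt]
        values = np.concatenate((col, [0.0]))  # fixation boundary node
        N_obs = params.NM if mature_only else population_size(params, tt)
        results.append(VafSolution(grid=grid, values=values, t_obs=tt,
                                   params=params, N_obs=N_obs))
    return results


def evolve_expected_vaf(
    params: ModelParams,
    t_obs: float,
    n: int = 400,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    mature_only: bool = False,
    v0=None,
) -> VafSolution:
    """Integrate the expected-VAF equation from V=0 at t=0 to ``t_obs``.

    ``mature_only=True`` runs a constant-size population (homeostatic rates
    from the start) -- the pure Moran reference configuration.  ``v0``
    optionally replaces the empty initial condition (values on the grid
    nodes).
    """
    if t_obs <= 0:
        raise ValueError("t_obs must be positive")
    return _solve(params, [t_obs], n, rtol, atol, mature_only, v0=v0)[0]


def transition_profile(
    params: ModelParams,
    t_list,
    n: int = 400,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> list[VafSolution]:
    """Solutions at a sequence of observation times (one integration)."""
    t_list = list(t_list)
    if not t_list or any(t <= 0 for t in t_list):
        raise ValueError("observation times must be positive")
    if sorted(t_list) != t_list:
        raise ValueError("t_list must be increasing")
    return _solve(params, t_list, n, rtol, atol, mature_only=False)
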