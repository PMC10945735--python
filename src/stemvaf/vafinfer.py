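"""Bulk/sample VAF-spectrum estimators.

Three inference tools operate on observed spectra:

* :func:`regress_mu` -- the least-squares mutation-rate estimator
  ``mu_hat = Cov(V_data, V_ref) / Var(V_ref)`` against a reference shape
  computed at unit mutation rate (growing ``~ 1/f^2`` or constant
  ``~ 1/f``, both pushed through the hypergeometric sampling transform so
  that data and reference live on the same sample-frequency support);
* :func:`average_age_group` -- per-bin averaging of donor spectra within age
  brackets (the growing-to-constant transition diagnostic);
* the **lowest-frequency lattice fit** -- for each candidate ``(NM, p)`` the
  expected sampled variant count at frequency ``1/S`` is computed from the
  VAF equation and compared with the observed count; the zero contour of the
  resulting error lattice is the set of parameter pairs consistent with the
  data, and its ``p = 0`` intercept bounds the population size from above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .analytic import moran_equilibrium, pure_birth_closed
from .params import build_params
from .sampling import SampledSpectrum, expected_sampled_density, expected_sampled_vaf
from .vafpde import evolve_expected_vaf

__all__ = [
    "FitLattice",
    "regress_mu",
    "reference_sampled_shape",
    "average_age_group",
    "delta_vf",
    "lattice_fit",
    "zero_contour",
    "max_population",
]


def regress_mu(V_data, V_ref, freqs=None, fmax: float = 0.5) -> float:
    """Mutation rate by linear regression of data against a unit-mu reference.

    ``mu_hat = Cov(V_data, V_ref) / Var(V_ref)``; exactly scale-equivariant
    and equal to ``c`` when ``V_data = c * V_ref``.  If ``freqs`` is given,
    the support is restricted to ``f <= fmax`` and the fixed class ``f = 1``
    is always dropped.
    """
    d = np.asarray(V_data, dtype=float)
    r = np.asarray(V_ref, dtype=float)
    if d.shape != r.shape:
        raise ValueError("data and reference must share a support")
    if freqs is not None:
        f = np.asarray(freqs, dtype=float)
        keep = (f <= fmax) & (f < 1.0)
        d, r = d[keep], r[keep]
    if len(d) < 3:
        raise ValueError("need at least 3 support points")
    var = np.var(r)
    if var == 0:
        raise ValueError("degenerate (constant) reference shape")
    return float(np.cov(d, r, bias=True)[0, 1] / var)


def reference_sampled_shape(kind: str, N: int, S: int) -> SampledSpectrum:
    """Unit-mutation-rate reference spectrum at sample size S.

    ``growing``: the pure-birth expectation ``V_k = 2 N / (k (k+1))``;
    ``constant``: the Moran equilibrium with the model's per-division
    convention (two mutated daughters per symmetric division),
    ``V_k = 2 N / k``.  Both are pushed through the hypergeometric sampling
    transform so they live on the data's sample frequencies.
    """
    k = np.arange(1, N)
    if kind == "growing":
        counts = pure_birth_closed(k, N - 1, mu=1.0)
    elif kind == "constant":
        counts = 2.0 * moran_equilibrium(N, mu=1.0).values
    else:
        raise ValueError("kind must be 'growing' or 'constant'")
    if S == N:
        return SampledSpectrum(S=S, counts=np.append(counts, 0.0), parent_N=N)
    return expected_sampled_vaf(counts, N=N, S=S)


def average_age_group(spectra, donor_ages=None, brackets=None):
    """Mean spectrum per age bracket across donors on a common support.

    Parameters
    ----------
    spectra : sequence of 1-D arrays
        Per-donor variant counts on a shared frequency binning.
    donor_ages : sequence of float, optional
        If given with ``brackets`` (sequence of ``(lo, hi)`` tuples,
        half-open), returns a dict ``bracket -> (mean spectrum, n_donors)``;
        otherwise returns the plain mean across all donors.
    """
    mat = [np.asarray(s, dtype=float) for s in spectra]
    if not mat:
        raise ValueError("need at least one spectrum")
    if any(m.shape != mat[0].shape for m in mat):
        raise ValueError("spectra must share a common binning")
    mat = np.vstack(mat)
    if donor_ages is None:
        return mat.mean(axis=0)
    ages = np.asarray(donor_ages, dtype=float)
    if brackets is None:
        brackets = [(20.0, 40.0), (40.0, 60.0), (60.0, np.inf)]
    out = {}
    for lo, hi in brackets:
        sel = (ages >= lo) & (ages < hi)
        if sel.any():
            out[(lo, hi)] = (mat[sel].mean(axis=0), int(sel.sum()))
    return out


@dataclass(frozen=True)
class FitLattice:
    """Lowest-frequency prediction errors over the (NM, p) plane.

    ``delta[i, j]`` = predicted minus observed variant count at sample
    frequency 1/S for ``p_axis[i]``, ``NM_axis[j]``.
    """

    NM_axis: np.ndarray
    p_axis: np.ndarray
    delta: np.ndarray
    fixed: dict


def _predicted_lowest(NM: float, p: float, fixed: dict) -> float:
    """Expected sampled variant count at abundance 1 of S, from the PDE."""
    params = build_params(
        NM=NM, tM=fixed["tM"], NH=fixed["NH"], lam=fixed["lam"], p=p,
        mu=fixed["mu"])
    sol = evolve_expected_vaf(params, fixed["t_obs"],
                              n=fixed.get("n", 400),
                              rtol=fixed.get("rtol", 1e-6))
    samp = expected_sampled_density(sol.kappa, sol.values, N=int(round(NM)),
                                    S=fixed["S"])
    return float(samp.counts[0])


def delta_vf(NM: float, p: float, fixed: dict,
             data_lowest_count: float) -> float:
    """Predicted minus observed variant count at the lowest sample frequency.

    ``fixed`` holds the pinned parameters: tM, NH, mu, lam, t_obs, S and
    optionally the solver resolution ``n``.
    """
    if data_lowest_count < 0:
        raise ValueError("observed count must be non-negative")
    return _predicted_lowest(NM, p, fixed) - float(data_lowest_count)


def lattice_fit(data_lowest_count: float, NM_range, p_range,
                fixed: dict) -> FitLattice:
    """Evaluate the lowest-frequency error on an (NM, p) lattice."""
    NM_axis = np.asarray(NM_range, dtype=float)
    p_axis = np.asarray(p_range, dtype=float)
    if len(NM_axis) < 2 or len(p_axis) < 1:
        raise ValueError("degenerate lattice ranges")
    delta = np.empty((len(p_axis), len(NM_axis)))
    for i, p in enumerate(p_axis):
        for j, NM in enumerate(NM_axis):
            delta[i, j] = delta_vf(NM, p, fixed, data_lowest_count)
    return FitLattice(NM_axis=NM_axis, p_axis=p_axis, delta=delta,
                      fixed=dict(fixed))


def zero_contour(lattice: FitLattice) -> np.ndarray:
    """Zero-error curve NM*(p): one interpolated root per p row.

    The error is monotone in NM (larger populations predict more
    low-frequency variants), so each row holds at most one sign change; the
    crossing is refined with a monotone spline in log NM.  Rows without a
    sign change are reported as NaN; an all-NaN curve means no fit.
    """
    logNM = np.log(lattice.NM_axis)
    out = np.full(len(lattice.p_axis), np.nan)
    for i, row in enumerate(lattice.delta):
        s = np.sign(row)
        cross = np.nonzero(s[:-1] * s[1:] <= 0)[0]
        if len(cross) == 0:
            continue
        interp = PchipInterpolator(logNM, row)
        j = cross[0]
        lo, hi = logNM[j], logNM[j + 1]
        for _ in range(80):  # bisection on the monotone interpolant
            mid = 0.5 * (lo + hi)
            if interp(mid) * interp(lo) <= 0:
                hi = mid
            else:
                lo = mid
        out[i] = np.exp(0.5 * (lo + hi))
    if np.all(np.isnan(out)):
        raise ValueError("error lattice has no sign change: no fit in range")
    return out


def max_population(lattice: FitLattice, curve=None) -> float:
    """Maximal consistent population size: the contour's p=0 intercept."""
    if curve is None:
        curve = zero_contour(lattice)
    p = lattice.p_axis
    ok = ~np.isnan(curve)
    if not ok.any():
        raise ValueError("empty zero contour")
    pv, cv = p[ok], curve[ok]
    if pv[0] == 0.0:
        return float(cv[0])
    if len(pv) == 1:
        return float(cv[0])
    # linear extrapolation from the two smallest-p contour points
    slope = (cv[1] - cv[0]) / (pv[1] - pv[0])
    return float(cv[0] - slope * pv[0])
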