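"""Exact stochastic simulation of the three-phase stem cell model.

Event classes (per-cell rates from :func:`stemvaf.params.rates_at`):

* **growth division** -- a uniformly chosen cell is replaced by two daughters
  (population +1);
* **Moran event** -- a uniformly chosen cell divides while a second uniformly
  chosen cell is removed; the dividing and the removed cell may coincide
  (probability 1/N), in which case a single daughter survives;
* **asymmetric division** -- a uniformly chosen cell is replaced by its single
  stem daughter.

Every surviving daughter draws ``Poisson(mu)`` new mutations, each globally
unique (infinite sites).  The genealogy is stored as flat arrays of branch
records (parent link, birth time, mutations on the branch); per-cell burdens
and whole-population or sampled VAF spectra are recovered by tree traversal,
so memory scales with the number of divisions rather than cells x mutations.

The growth phase is gated on population size (``N < NM``) rather than clock
time: with ``gamma = ln(NM)/tM`` the population reaches ``NM`` at ``tM`` up
to the O(1/gamma) jitter of the Yule process, and the mature population size
is then *exactly* constant, which is what the homeostatic theory assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .burden import BurdenSample
from .params import ModelParams

__all__ = [
    "Genealogy",
    "simulate",
    "simulate_burdens",
    "burdens",
    "subsample",
    "simulate_burden_only",
    "dispersion_probability",
]


@dataclass
class Genealogy:
    """Lineage forest of a simulated population.

    ``parent[i]`` is the branch index of node ``i``'s parent (-1 for the
    founder), ``nmut[i]`` the number of novel mutations on the branch into
    node ``i``, and ``birth_time[i]`` its creation time.  Variant identifiers
    are implicit: branch ``i`` owns the half-open id range
    ``[offset[i], offset[i] + nmut[i])`` with ``offset = cumsum(nmut)``,
    which keeps every variant globally unique.  ``alive`` lists the node ids
    of the current cells.
    """

    parent: np.ndarray
    nmut: np.ndarray
    birth_time: np.ndarray
    alive: np.ndarray
    t: float
    params: ModelParams

    @property
    def N(self) -> int:
        return len(self.alive)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def variant_offsets(self) -> np.ndarray:
        off = np.zeros(self.n_nodes + 1, dtype=np.int64)
        np.cumsum(self.nmut, out=off[1:])
        return off

    # -- descendant counting -------------------------------------------------

    def _descendant_counts(self, cells: np.ndarray) -> np.ndarray:
        """Number of cells from ``cells`` descending from each branch node.

        Parents always precede children in the arrays, so a single reverse
        sweep accumulates child counts into parents.
        """
        desc = np.zeros(self.n_nodes, dtype=np.int64)
        desc[cells] = 1
        parent = self.parent.tolist()
        d = desc.tolist()
        for i in range(self.n_nodes - 1, 0, -1):
            di = d[i]
            if di:
                d[parent[i]] += di
        return np.asarray(d, dtype=np.int64)

    def _spectrum_from_desc(self, desc: np.ndarray, size: int) -> np.ndarray:
        counts = np.bincount(desc, weights=self.nmut, minlength=size + 1)
        return counts  # index k = abundance; k=0 extinct, k=size fixed

    def vaf_spectrum(self, include_fixed: bool = False) -> np.ndarray:
        """Whole-population spectrum ``V[k]`` for k = 1..N (or 1..N-1)."""
        desc = self._descendant_counts(self.alive)
        counts = self._spectrum_from_desc(desc, self.N)
        return counts[1:] if include_fixed else counts[1:-1]

    def burdens(self) -> BurdenSample:
        """Per-cell mutation counts: branch sums along each root path."""
        parent = self.parent.tolist()
        nm = self.nmut.tolist()
        tot = [0] * self.n_nodes
        for i in range(self.n_nodes):
            p = parent[i]
            tot[i] = nm[i] + (tot[p] if p >= 0 else 0)
        tot = np.asarray(tot, dtype=np.int64)
        return BurdenSample(tot[self.alive])

    def sample_cells(self, S: int, seed=None) -> np.ndarray:
        """Node ids of a uniform sample of S distinct cells."""
        if not (1 <= S <= self.N):
            raise ValueError(f"require 1 <= S <= N={self.N}, got {S}")
        rng = np.random.default_rng(seed)
        return rng.choice(self.alive, size=S, replace=False)

    def spectrum_of(self, cells: np.ndarray) -> np.ndarray:
        """Spectrum ``V[i]``, i = 1..len(cells), by occupancy among cells."""
        desc = self._descendant_counts(cells)
        return self._spectrum_from_desc(desc, len(cells))[1:]

    def burdens_of(self, cells: np.ndarray) -> BurdenSample:
        """Burdens of an explicit cell set."""
        all_b = self.burdens().burdens
        pos = {c: i for i, c in enumerate(self.alive.tolist())}
        return BurdenSample(all_b[[pos[c] for c in cells.tolist()]])

    def subsample(self, S: int, seed=None) -> tuple[BurdenSample, np.ndarray]:
        """Uniform sample of S distinct cells: (burdens, sample spectrum).

        The sample spectrum counts variants by occupancy among the sampled
        cells only (``V[i]`` for i = 1..S, fixed class included at i=S);
        variants absent from every sampled cell are dropped.
        """
        cells = self.sample_cells(S, seed=seed)
        return self.burdens_of(cells), self.spectrum_of(cells)


def burdens(g: Genealogy) -> BurdenSample:
    """Module-level alias for :meth:`Genealogy.burdens`."""
    return g.burdens()


def subsample(g: Genealogy, S: int, seed=None):
    """Module-level alias for :meth:`Genealogy.subsample`."""
    return g.subsample(S, seed=seed)


# ---------------------------------------------------------------------------
# event engine
# ---------------------------------------------------------------------------

_BLOCK = 65536


class _Draws:
    """Buffered random draws (uniforms, poissons, integers) for the loops."""

    def __init__(self, rng: np.random.Generator, mu: float):
        self.rng = rng
        self.mu = mu
        self._u = []
        self._ui = 0
        self._m = []
        self._mi = 0

    def uniform(self) -> float:
        if self._ui >= len(self._u):
            self._u = self.rng.random(_BLOCK).tolist()
            self._ui = 0
        self._ui += 1
        return self._u[self._ui - 1]

    def poisson(self) -> int:
        if self._mi >= len(self._m):
            self._m = self.rng.poisson(self.mu, _BLOCK).tolist()
            self._mi = 0
        self._mi += 1
        return self._m[self._mi - 1]


def _check_cap(n_events: float, cap: float):
    if n_events > cap:
        warnings.warn(
            f"projected event count {n_events:.3g} exceeds cap {cap:.3g}",
            stacklevel=3)
        raise RuntimeError(
            f"projected event count {n_events:.3g} exceeds the configured "
            f"cap {cap:.3g}; raise max_events to override")


def simulate(
    params: ModelParams,
    t_end: float,
    seed=None,
    max_events: float = 1e8,
) -> Genealogy:
    """Gillespie simulation from one founder cell to age ``t_end`` (years).

    Waiting times are exponential per event class with population totals
    ``N*gamma``, ``N*rho``, ``N*phi`` (phase-gated); acting cells are chosen
    uniformly.  Identical ``(params, t_end, seed)`` give identical output.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed)
    mu, NM, NH = params.mu, params.NM, params.NH
    gamma, rho, phi = params.gamma, params.rho, params.phi

    proj = NM * (rho + phi) * max(t_end - params.tM, 0) + 2 * NM
    _check_cap(proj, max_events)

    parent = [-1]
    nmut = [0]
    btime = [0.0]
    alive = [0]
    draws = _Draws(rng, mu)
    t = 0.0
    N = 1
    nid = 1

    # --- growth + mixed phase: sequential, N changes -----------------------
    while N < NM and t < t_end:
        homeo = N > NH
        g_tot = N * gamma
        r_tot = N * rho if homeo else 0.0
        f_tot = N * phi if homeo else 0.0
        total = g_tot + r_tot + f_tot
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            t = t_end
            break
        u = draws.uniform() * total
        i = int(draws.uniform() * N)
        a = alive[i]
        if u < g_tot:  # growth division: two surviving daughters
            parent.append(a); nmut.append(draws.poisson()); btime.append(t)
            parent.append(a); nmut.append(draws.poisson()); btime.append(t)
            alive[i] = nid
            alive.append(nid + 1)
            nid += 2
            N += 1
        elif u < g_tot + r_tot:  # Moran event
            j = int(draws.uniform() * N)
            if i == j:  # divider also removed: one daughter survives
                parent.append(a); nmut.append(draws.poisson()); btime.append(t)
                alive[i] = nid
                nid += 1
            else:
                parent.append(a); nmut.append(draws.poisson()); btime.append(t)
                parent.append(a); nmut.append(draws.poisson()); btime.append(t)
                alive[i] = nid
                alive[j] = nid + 1
                nid += 2
        else:  # asymmetric division
            parent.append(a); nmut.append(draws.poisson()); btime.append(t)
            alive[i] = nid
            nid += 1

    # --- mature phase: constant N, constant rates, bulk-drawn events --------
    if t < t_end and (rho + phi) > 0:
        span = t_end - t
        K = int(rng.poisson(N * (rho + phi) * span))
        _check_cap(len(parent) + 2 * K, 2 * max_events + 4 * NM)
        times = np.sort(rng.random(K)) * span + t
        is_moran = (rng.random(K) < rho / (rho + phi)).tolist()
        idx1 = rng.integers(0, N, K).tolist()
        idx2 = rng.integers(0, N, K).tolist()
        muts = rng.poisson(mu, 2 * K).tolist() if K else []
        tl = times.tolist()
        mp = 0
        ap = parent.append
        am = nmut.append
        at = btime.append
        for e in range(K):
            i = idx1[e]
            a = alive[i]
            te = tl[e]
            if is_moran[e]:
                j = idx2[e]
                if i == j:
                    ap(a); am(muts[mp]); at(te)
                    alive[i] = nid
                    nid += 1
                    mp += 1
                else:
                    ap(a); am(muts[mp]); at(te)
                    ap(a); am(muts[mp + 1]); at(te)
                    alive[i] = nid
                    alive[j] = nid + 1
                    nid += 2
                    mp += 2
            else:
                ap(a); am(muts[mp]); at(te)
                alive[i] = nid
                nid += 1
                mp += 1
        t = t_end

    return Genealogy(
        parent=np.asarray(parent, dtype=np.int64),
        nmut=np.asarray(nmut, dtype=np.int64),
        birth_time=np.asarray(btime),
        alive=np.asarray(alive, dtype=np.int64),
        t=t_end,
        params=params,
    )


def simulate_burdens(
    params: ModelParams,
    t_end: float,
    seed=None,
    max_events: float = 1e8,
) -> BurdenSample:
    """Burden-only fast path of :func:`simulate` (identical event rules).

    Tracks per-cell mutation counts without variant identities; used for
    large ensembles where only the burden distribution is needed.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed)
    mu, NM, NH = params.mu, params.NM, params.NH
    gamma, rho, phi = params.gamma, params.rho, params.phi
    proj = NM * (rho + phi) * max(t_end - params.tM, 0) + 2 * NM
    _check_cap(proj, max_events)

    draws = _Draws(rng, mu)
    b = [0]
    t = 0.0
    N = 1
    while N < NM and t < t_end:
        homeo = N > NH
        g_tot = N * gamma
        r_tot = N * rho if homeo else 0.0
        f_tot = N * phi if homeo else 0.0
        total = g_tot + r_tot + f_tot
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        u = draws.uniform() * total
        i = int(draws.uniform() * N)
        if u < g_tot:
            pa = b[i]
            b[i] = pa + draws.poisson()
            b.append(pa + draws.poisson())
            N += 1
        elif u < g_tot + r_tot:
            j = int(draws.uniform() * N)
            if i == j:
                b[i] += draws.poisson()
            else:
                pa = b[i]
                b[i] = pa + draws.poisson()
                b[j] = pa + draws.poisson()
        else:
            b[i] += draws.poisson()

    if t < t_end and (rho + phi) > 0:
        K = int(rng.poisson(N * (rho + phi) * (t_end - t)))
        is_moran = (rng.random(K) < rho / (rho + phi)).tolist()
        idx1 = rng.integers(0, N, K).tolist()
        idx2 = rng.integers(0, N, K).tolist()
        muts = rng.poisson(mu, 2 * K).tolist() if K else []
        mp = 0
        for e in range(K):
            i = idx1[e]
            if is_moran[e]:
                j = idx2[e]
                if i == j:
                    b[i] += muts[mp]
                    mp += 1
                else:
                    pa = b[i]
                    b[i] = pa + muts[mp]
                    b[j] = pa + muts[mp + 1]
                    mp += 2
            else:
                b[i] += muts[mp]
                mp += 1

    return BurdenSample(np.asarray(b, dtype=np.int64))


def simulate_burden_only(
    N: int,
    p: float,
    mu: float,
    lam: float,
    t: float,
    reps: int = 1,
    seed=None,
) -> list[BurdenSample]:
    """Homeostasis-only burden fluctuation simulations.

    Starts from ``N`` cells with zero mutations (no growth phase) and runs
    the mature-phase rules for time ``t``: an asymmetric division (fraction
    ``p`` of events) adds ``Poisson(mu)`` to one cell; a symmetric
    replacement copies the divider's burden into the replaced slot and adds
    ``Poisson(mu)`` to both the replaced slot and the divider.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(reps):
        b = [0] * N
        K = int(rng.poisson(N * lam * t))
        asym = (rng.random(K) < p).tolist()
        idx1 = rng.integers(0, N, K).tolist()
        idx2 = rng.integers(0, N, K).tolist()
        muts = rng.poisson(mu, 2 * K).tolist() if K else []
        mp = 0
        for e in range(K):
            i = idx1[e]
            if asym[e]:
                b[i] += muts[mp]
                mp += 1
            else:
                j = idx2[e]
                if i == j:
                    b[i] += muts[mp]
                    mp += 1
                else:
                    pa = b[i]
                    b[i] = pa + muts[mp]
                    b[j] = pa + muts[mp + 1]
                    mp += 2
        out.append(BurdenSample(np.asarray(b, dtype=np.int64)))
    return out


def dispersion_probability(
    N: int,
    p: float,
    mu: float,
    lam: float,
    t: float,
    interval: tuple[float, float] = (3.0, 5.0),
    reps: int = 100,
    seed=None,
) -> float:
    """Fraction of replicates with dispersion ratio strictly inside interval.

    Replicates with zero mean burden (theta undefined) count as outside.
    """
    lo, hi = interval
    samples = simulate_burden_only(N, p, mu, lam, t, reps=reps, seed=seed)
    inside = 0
    for s in samples:
        th = s.theta
        if np.isfinite(th) and lo < th < hi:
            inside += 1
    return inside / reps
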