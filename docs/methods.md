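# Methods

## Model and assumptions

`stemvaf` implements a neutral, well-mixed, three-phase model of a somatic
stem cell pool. A single founder expands by symmetric self-renewing
divisions at per-cell rate `γ`; once the pool exceeds `N_H` cells,
homeostatic turnover starts alongside growth — Moran events (one symmetric
division paired with one uniformly chosen removal) at per-cell rate `ρ` and
asymmetric divisions at rate `φ`; at maturity the pool size is constant and
only homeostatic events continue. Every daughter receives `Poisson(μ)` new
mutations, each globally unique (infinite sites), and there is no selection,
no spatial structure, and no explicitly modelled differentiated compartment.
Only symmetric events move variant frequencies; both event types inject
variants, asymmetric ones at half weight (one surviving daughter).

The homeostatic rates are parameterised by the total rate `λ = ρ + φ` and
the asymmetric fraction `p = φ/λ`, since the data constrain `(N, p)` jointly
rather than `ρ` and `φ` separately. `γ` is pinned by `N(t_M) = N_M`
(`γ = ln N_M / t_M`).

### Mutation-rate conventions

Two bookkeeping conventions coexist in the site-frequency-spectrum
literature and both appear here, reconciled explicitly:

* the **per-daughter** (division) rate `μ` used by the model: a symmetric
  division adds `2μ` expected new variants (`μ(2 − 1/N)` in the Moran phase,
  counting the 1/N chance that the divider is also the removed cell);
* the **per-birth-event** rate `μ_e` of the classical Moran equilibrium
  `V*(k) = μ_e N/k`.

A constant population run at division rate `μ` therefore equilibrates to
`2μN/κ`, and tests against the `μ_e N/k` form use `μ_e = 2μ`. The
pure-birth results are already written in the per-daughter convention
(`V_1(1) = 2μ`).

## Stochastic simulator

An exact Gillespie scheme: per-class population rates `Nγ`, `Nρ`, `Nφ`,
exponential waiting times, uniformly chosen actors. In the mature phase the
rates are constant, so events are generated in bulk (Poisson event count,
multinomial types, sorted uniform times) — the same point process without a
per-event clock. The growth phase is gated on population size (`N < N_M`)
rather than clock time: maturity then occurs at `t_M` up to the O(1/γ)
jitter of the Yule process, and the mature size is *exactly* `N_M`, which
is what the homeostatic theory assumes. Moran removal is drawn uniformly
from the pre-division population, so the divider can remove itself (the
1/N self-replacement term); whether the removal may instead hit a
just-created daughter only changes O(1/N) terms.

The genealogy is stored as flat branch arrays (parent id, mutations on the
branch, birth time); burdens are root-path sums and spectra come from a
single reverse sweep counting alive descendants per branch, so memory and
time scale with the number of divisions, not cells × mutations. A
burden-only engine with the identical event rules serves large ensembles
where variant identities are not needed. An event cap (default `10⁸`)
aborts runaway parameter choices with a warning. A separate
homeostasis-only variant starts from `N` unmutated cells and tracks burdens
under the same update rules, for within-/between-replicate dispersion
studies (`dispersion_probability` reports how often `Var/mean` lands in a
given window, e.g. the empirically motivated 3–5).

## Expected-VAF solver

The expected spectrum `V(κ, t)` solves
`∂t V = −∂κ(AV) + ∂κ²(BV) + Cδ(κ−1)` with `A = γκ`,
`B = κ(1−κ/N)ρ + γκ/2`, `C = 2μN(ρ + γ + φ/2)` and phase-gated rates. We
work in absolute size `κ` (not frequency) so the influx point stays fixed
while `N(t)` grows. Numerical choices:

* **Grid** — `n` nodes (default 400) spanning `[1, N_M]`, steps
  `Δκ_i = 1 + (i−1)α` growing linearly from unit spacing at the influx
  point; `α = 2(N−n)/((n−1)(n−2))` is fixed by requiring the steps to
  telescope exactly to `N − 1`. An extra node at `κ = 0` carries the
  extinction boundary.
* **Discretization** — flux-conservative central differences; the delta
  influx is a step of height `2/(Δκ_left + Δκ_right)` at the `κ = 1` node.
  Dirichlet zero (absorbing) at `κ = 0` and `κ = N_M`; boundary treatment
  is a modelling choice, made explicit here because extinction and fixation
  both permanently remove variants from the segregating range. A useful
  exact property of this scheme: the constant-`N` balance state solves
  `BV` piecewise-linear, giving `V = C/(ρκ)` on the nodes — the discrete
  equilibrium is reproduced without spatial error, and it is an exact fixed
  point of the integrator (checked in the tests). Without the influx the
  same profile necessarily drains through the extinction boundary, so
  stationarity is only meaningful with the source on.
* **Time integration** — stiff BDF (`scipy.solve_ivp`) with analytic
  tridiagonal Jacobian, `rtol 10⁻⁶`, split at the phase breakpoints; the
  operator is rebuilt per evaluation during growth and frozen in the
  constant-coefficient mature phase. Coefficients are kept smooth in time
  (only the Moran diffusion is clamped at `κ > N(t)`, where the solution is
  numerically zero anyway) — a hard moving cutoff at `N(t)` forces the
  integrator to resolve every node crossing and costs an order of
  magnitude.
* **Accuracy** — grid-refinement convergence (<1% change at the lowest
  node on doubling `n`) is asserted in the test suite, not at runtime. The
  diffusion (Fokker–Planck) approximation itself deviates from the exact
  jump process at `κ` of order one during growth (≈17% at `κ = 1`,
  <5% for `κ ≥ 4`); in the mature phase the low-`κ` classes relax to the
  exactly-represented Moran balance, which is why the lowest-frequency
  fitting observable is reliable at late ages.

Three growth curves are supported: exponential capped at `N_M`; logistic
*from one cell* with maturity defined at `0.99 N_M` (the unnormalized
logistic that starts at `N_M/2` is not used — growth must start from the
founder); and exponential-then-linear adult growth with slope `c` (default
0.005/year, configurable — the scenario in which a constant per-division
mutation rate masquerades as an age-increasing effective rate).

## Sampling transform

Sequencing `S` of `N` cells redistributes abundances hypergeometrically.
The discrete transform uses `scipy.stats.hypergeom` exactly; the PDE-grid
version continues the pmf to real `κ` by log-gamma differences (stable to
`N ~ 10⁶`) and integrates with node-centered weights whose edge cells
extend half a unit, so a unit-spaced grid reproduces the discrete sum
exactly. The undetected (`i = 0`) class is dropped from outputs, which is
what shifts observed frequencies upward relative to truth.

## Burden inference

From `m_j = Σ_i u_ji` over `y_j` past divisions:
`E(m) = E(y)E(u)`, `Var(m) = E(y)Var(u) + E(u)²Var(y)`. With
`u ~ Poisson(μ)`: `E(y) = E(m)/μ` and
`μ̂ = (Var(m)/E(m) − 1)·E(y)/Var(y)`; the dispersion factor defaults to 1
(Poisson division counts). Negative estimates (under-dispersed burdens) are
reported with a warning, never clamped — they are diagnostic of
division-independent mutation accumulation. The standard error of the mean
burden is `σ_m/√S`.

The expected divisions per lineage integrate the phase-gated rates with
growth and Moran events counting double (two surviving daughters each):

```
y(t) = ∫₀ᵗ [ 2ρ(1 − 1/2N) + φ + 2γ(1 − 1/(N+1)) ] dτ,
```

evaluated by adaptive quadrature with `N(τ)` from the configured growth
curve. `solve_lambda` inverts `y(t) = R` by Brent root finding (`y` is
strictly increasing in `λ`); a closed-form transcription of the integral is
error-prone and deliberately not used beyond the large-`N` limit
`λ ≈ (R − 2 ln N_M)/((2−p)(t−t_M))` kept as a cross-check.
`lambda_interval` reports two distinct uncertainty notions separately: the
spread of the point estimate over a sweep of the nuisance parameters
`(t_M, N_H, N_M)`, and the propagation of the burden mean's standard error
at central nuisance values.

The compound Poisson distribution (`Poisson(E(y))` divisions of
`Poisson(μ)` mutations) is evaluated by truncated mixture summation
(±12 SD) and describes burdens averaged over *independent* populations.
Within one population, shared ancestry reduces `Var(m)` — pairwise burden
variance grows only with the coalescence-limited divergence time — so the
single-population `μ̂` is biased downward, increasingly so for small `N`.
The tests assert both the CPD match across ensembles and the bias direction
within populations.

## VAF inference

* `regress_mu` — least-squares slope `Cov(V_d, V_r)/Var(V_r)` against a
  unit-rate reference shape. References are the *discrete expected sampled*
  spectra (pure-birth `2N/(k(k+1))` or constant-population `2N/k`, pushed
  through the sampling transform at the data's `S`), which puts data and
  reference on the same support without binning arbitrariness. The support
  excludes `f > 0.5` and the fixed class by default (configurable); the
  estimator is exactly scale-equivariant.
* `average_age_group` — per-bin donor means within age brackets (defaults
  20–39 / 40–59 / 60+, configurable edges).
* **Lowest-frequency lattice fit** — across replicates the `1/S` class has
  the smallest coefficient of variation among sampled classes (asserted in
  the tests), so it is the fitting observable. For each lattice point
  `(N_M, p)` the expected sampled count at abundance one is computed
  (PDE → sampling transform) and compared with the observed count; the
  zero contour of this error surface — one monotone root in `N_M` per `p`
  row, refined by monotone (PCHIP) interpolation in `log N_M` — is the set
  of parameter pairs consistent with the data. Its `p = 0` intercept is the
  maximal population size; if `p = 0` is not on the lattice the intercept is
  linearly extrapolated from the two smallest-`p` contour points. Absence
  of a sign change is reported explicitly as "no fit in range".

## Synthetic data

The generator produces the two study-like modalities the estimators
consume, with the generating parameters and seed recorded in a manifest:

* **single-cell**: a full three-phase simulation, a uniform sample of
  `S = 89` cells at age 59 by default (the size and age of the reference
  hematopoietic dataset), written as burden list, binary cell×variant
  matrix and sample VAF spectrum;
* **bulk-cohort**: per-donor expected spectra at the donor ages, realized
  variant counts drawn Poisson per abundance class (independent-sites
  approximation — genealogical correlations between variants are available
  only through the simulator route, which scales less well), and binomial
  read-depth noise around each sample frequency.

What the generator does **not** emulate: sequencing error and artefact
modes, copy-number and mappability effects, trinucleotide signatures,
selection/drivers, spatial sampling structure, and (in the bulk route) the
covariance between variant counts induced by shared genealogy. Passing
recovery tests on these data therefore validates the estimators under the
model's own assumptions — correctness of the machinery, not robustness to
real-data artefacts.

## Problem sizes in the shipped checks

The quantitative checks run at desk scale, chosen so each validates the
claimed behaviour with useful statistical power: stochastic-vs-PDE
agreement at `N = 100` over 2000 replicates (within 10% at `κ ≤ 20`);
burden-based recovery at `N_M = 10³`, age 59, `S = 89` over 100 replicates;
lattice self-recovery from one `N_M = 10⁴` population (intercept within 20%);
Moran-equilibrium convergence at `N = 10³` (2% at `κ ≤ N/10`). Full-scale
analyses (`N_M` up to `5·10⁵` in the lattice) use the identical code paths;
only the lattice resolution and solver grid are configurable.

## Known limitations

* The diffusion approximation's O(1) relative error at `κ ≈ 1` during
  growth phases (inherent to the PDE, not the discretization).
* Single-population mutation-rate estimates inherit the coalescent downward
  bias described above; only ensemble averages are unbiased.
* The real single-cell blood calls and the esophagus cohort are controlled-
  access/external downloads; the package ships estimator machinery and
  synthetic stand-ins, not those datasets, and makes no quantitative claim
  about them.
* No confidence machinery beyond the lattice/contour geometry and the
  reported intervals; no multi-frequency joint likelihood.
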