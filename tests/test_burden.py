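import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemvaf import (
    BurdenSample,
    build_params,
    burden_moments,
    compound_poisson_pmf,
    estimate_divisions,
    estimate_mu,
    expected_divisions,
    simulate,
    simulate_burdens,
    solve_lambda,
)
from stemvaf.burden import lambda_interval


def draw_cpd(Ey, mu, size, rng):
    """Independent compound-Poisson burdens (the no-shared-history null)."""
    y = rng.poisson(Ey, size)
    return rng.poisson(mu * y)


class TestMoments:
    def test_constant_burdens(self):
        m, v, th, se = burden_moments(BurdenSample([2, 2, 2]))
        assert (m, v, th, se) == (2.0, 0.0, 0.0, 0.0)

    def test_rejects_single_cell(self):
        with pytest.raises(ValueError):
            burden_moments(BurdenSample([5]))

    def test_theta_nan_for_zero_mean(self):
        assert np.isnan(BurdenSample([0, 0]).theta)

    def test_cpd_dispersion_approaches_one_plus_mu(self):
        # Var(m) = E(y) mu (1 + mu) under the compound model
        rng = np.random.default_rng(0)
        mu = 1.2
        b = BurdenSample(draw_cpd(500.0, mu, 20000, rng))
        assert b.theta == pytest.approx(1 + mu, rel=0.05)

    def test_cpd_sample_mean(self):
        rng = np.random.default_rng(1)
        b = BurdenSample(draw_cpd(500.0, 1.2, 10000, rng))
        se = np.sqrt(b.var / b.S)
        assert abs(b.mean - 600.0) < 3 * se


class TestEstimators:
    def test_divisions_from_mean_burden(self):
        assert estimate_divisions(1000.0, 1.2) == pytest.approx(833.333,
                                                                abs=1e-3)
        assert estimate_divisions(0.0, 1.2) == 0.0
        with pytest.raises(ValueError):
            estimate_divisions(10.0, 0.0)

    def test_pure_poisson_burden_gives_zero_mu(self):
        # division-independent (time-like) mutations: Var = mean -> mu_hat 0
        assert estimate_mu(50.0, 50.0) == pytest.approx(0.0)

    def test_underdispersion_warns_not_clamps(self):
        with pytest.warns(UserWarning):
            got = estimate_mu(100.0, 50.0)
        assert got < 0

    def test_unbiased_on_independent_cpd_samples(self):
        rng = np.random.default_rng(2)
        mu = 1.2
        est = []
        for _ in range(200):
            b = BurdenSample(draw_cpd(400.0, mu, 10000, rng))
            est.append(estimate_mu(b.mean, b.var))
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - mu) < 3 * se

    def test_shared_history_biases_mu_downward(self):
        # within one population, lineages share early divisions, which
        # reduces Var(m) and hence the estimate -- the direction the
        # compound model predicts for correlated genealogies
        import warnings

        p = build_params(NM=100, tM=2.0, NH=10, lam=5.0, p=0.4, mu=1.2)
        est = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # negative draws ok
            for s in range(100):
                b = simulate_burdens(p, 30.0, seed=s)
                est.append(estimate_mu(b.mean, b.var))
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert est.mean() + 3 * se < 1.2


class TestCompoundPoissonPmf:
    def test_zero_class_matches_generating_function(self):
        Ey, mu = 8.0, 0.7
        pmf = compound_poisson_pmf(Ey, mu, [0])
        assert pmf[0] == pytest.approx(np.exp(Ey * (np.exp(-mu) - 1.0)),
                                       rel=1e-10)

    def test_moments_and_normalization(self):
        Ey, mu = 50.0, 1.2
        m = np.arange(0, 400)
        pmf = compound_poisson_pmf(Ey, mu, m)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-8)
        mean = np.sum(m * pmf)
        var = np.sum((m - mean) ** 2 * pmf)
        assert mean == pytest.approx(Ey * mu, rel=1e-6)
        assert var == pytest.approx(Ey * mu * (1 + mu), rel=1e-6)

    def test_matches_ensemble_averaged_burden_histogram(self):
        # the CPD describes burdens averaged over independently evolved
        # populations (shared history washes out across the ensemble)
        p = build_params(NM=60, tM=1.0, NH=5, lam=4.0, p=0.4, mu=1.0)
        t = 10.0
        allb = np.concatenate(
            [simulate_burdens(p, t, seed=s).burdens for s in range(150)])
        Ey = expected_divisions(p, t)
        m_hi = int(allb.max()) + 1
        pmf = compound_poisson_pmf(Ey, 1.0, np.arange(m_hi))
        obs = np.bincount(allb, minlength=m_hi)
        # group tails so every chi-square cell has expectation >= 10
        exp = pmf * len(allb)
        keep = exp >= 10
        chi2 = np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep])
        dof = keep.sum() - 1
        from scipy.stats import chi2 as chi2_dist
        assert chi2 < chi2_dist.ppf(0.95, dof) * 1.5


class TestExpectedDivisions:
    def test_mature_rate_approaches_lambda_times_two_minus_p(self):
        p = build_params(NM=1e5, tM=5.0, NH=50, lam=5.0, p=0.4, mu=1.0)
        dy = expected_divisions(p, 30.0) - expected_divisions(p, 29.0)
        assert dy == pytest.approx(5.0 * (2 - 0.4), rel=1e-3)

    def test_pure_asymmetric_mature_rate_is_lambda(self):
        p = build_params(NM=1e5, tM=5.0, NH=50, lam=5.0, p=1.0, mu=1.0)
        dy = expected_divisions(p, 30.0) - expected_divisions(p, 29.0)
        assert dy == pytest.approx(5.0, rel=1e-3)

    def test_matches_simulated_lineage_division_counts(self):
        # the tree depth of an alive cell counts its past divisions
        p = build_params(NM=300, tM=3.0, NH=20, lam=5.0, p=0.4, mu=1.0)
        t = 20.0
        means = []
        for s in range(40):
            g = simulate(p, t, seed=s)
            depth = np.zeros(g.n_nodes)
            par = g.parent
            for i in range(1, g.n_nodes):
                depth[i] = depth[par[i]] + 1
            means.append(depth[g.alive].mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - expected_divisions(p, t)) < 3 * se


class TestSolveLambda:
    def test_round_trip_recovers_lambda(self):
        for lam in (1.0, 5.0, 12.0):
            p = build_params(NM=2e4, tM=5.0, NH=100, lam=lam, p=0.4, mu=1.0)
            R = expected_divisions(p, 59.0)
            got = solve_lambda(R, NM=2e4, NH=100, tM=5.0, p=0.4, t=59.0)
            assert got == pytest.approx(lam, abs=1e-6)

    def test_mature_dominated_closed_form_limit(self):
        # with homeostasis starting only at maturity (NH ~ NM) and large N,
        # y(t) ~ 2 ln NM + lambda (2-p) (t - tM), so
        # lambda ~ (R - 2 ln NM) / ((2-p)(t-tM))
        R, p, t, tM, NM = 500.0, 0.3, 59.0, 5.0, 5e5
        lam = solve_lambda(R, NM=NM, NH=NM - 1, tM=tM, p=p, t=t)
        closed = (R - 2 * np.log(NM)) / ((2 - p) * (t - tM))
        assert lam == pytest.approx(closed, rel=0.01)

    def test_no_root_when_burden_below_growth_phase_count(self):
        with pytest.raises(ValueError):
            solve_lambda(1.0, NM=1e4, NH=100, tM=5.0, p=0.0, t=59.0)

    def test_interval_report_structure(self):
        out = lambda_interval(mean_burden=1000.0, se_mean=10.0, mu=1.2,
                              t=59.0, n_sweep=2)
        lo, hi = out["sweep_interval"]
        assert lo <= out["lambda"] <= hi
        assert out["se_interval"][0] < out["se_interval"][1]


@settings(deadline=None, max_examples=15, derandomize=True)
@given(lam=st.floats(0.5, 30.0), p=st.floats(0.0, 1.0),
       NM=st.floats(1e3, 1e6), t=st.floats(20.0, 90.0))
def test_lambda_round_trip_property(lam, p, NM, t):
    pr = build_params(NM=NM, tM=5.0, NH=50, lam=lam, p=p, mu=1.0)
    R = expected_divisions(pr, t)
    got = solve_lambda(R, NM=NM, NH=50, tM=5.0, p=p, t=t)
    assert got == pytest.approx(lam, rel=1e-6, abs=1e-6)
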