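import numpy as np
import pytest

from stemvaf import (
    average_age_group,
    build_params,
    delta_vf,
    lattice_fit,
    max_population,
    reference_sampled_shape,
    regress_mu,
    simulate,
    zero_contour,
)
from stemvaf.vafinfer import FitLattice

DESK_FIXED = {"tM": 3.0, "NH": 20.0, "mu": 1.0, "lam": 3.0, "t_obs": 25.0,
              "S": 30, "n": 200}


class TestRegressMu:
    def test_exact_multiple_recovers_scale(self):
        ref = 1.0 / np.arange(1, 40)
        assert regress_mu(3.0 * ref, ref) == pytest.approx(3.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        ref = 1.0 / np.arange(1, 40)
        data = 1.4 * ref + rng.normal(0, 0.01, ref.size)
        assert regress_mu(5.0 * data, ref) == pytest.approx(
            5.0 * regress_mu(data, ref))

    def test_unbiased_under_centered_noise(self):
        rng = np.random.default_rng(1)
        ref = 2.0 / np.arange(1, 60)
        mu = 1.7
        est = [regress_mu(mu * ref + rng.normal(0, 0.05, ref.size), ref)
               for _ in range(500)]
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - mu) < 3 * se

    def test_rejects_degenerate_reference(self):
        with pytest.raises(ValueError):
            regress_mu(np.ones(10), np.ones(10))

    def test_support_restriction_drops_high_frequencies(self):
        ref = 1.0 / np.arange(1, 11)
        data = 2.0 * ref.copy()
        data[-1] += 100.0  # fixed-class outlier must be excluded
        freqs = np.arange(1, 11) / 10
        assert regress_mu(data, ref, freqs=freqs) == pytest.approx(2.0)

    def test_simulated_growing_population_estimate_in_expected_range(self):
        # pure-growth populations at mu=1.2 regressed on the unit-rate
        # growing reference recover roughly the truth (the range the
        # bulk-data fits land in)
        p = build_params(NM=400, tM=1.0, mu=1.2)
        ref = reference_sampled_shape("growing", N=400, S=400)
        freqs = np.arange(1, 401) / 400
        est = []
        for s in range(10):
            g = simulate(p, 2.0, seed=s)
            spec = g.vaf_spectrum(include_fixed=True).astype(float)
            est.append(regress_mu(spec, ref.counts, freqs=freqs))
        assert 1.0 < np.mean(est) < 1.5


class TestReferenceShapes:
    def test_full_sampling_returns_population_shape(self):
        ref = reference_sampled_shape("constant", N=50, S=50)
        k = np.arange(1, 50)
        assert ref.counts[:-1] == pytest.approx(2.0 * 50 / k)

    def test_sampled_reference_is_positive_and_decreasing(self):
        ref = reference_sampled_shape("growing", N=200, S=20)
        assert np.all(ref.counts > 0)
        assert np.all(np.diff(ref.counts[:10]) < 0)


class TestAverageAgeGroup:
    def test_single_donor_identity(self):
        s = np.array([3.0, 2.0, 1.0])
        assert average_age_group([s]) == pytest.approx(s)

    def test_identical_donors_average_to_same_spectrum(self):
        s = np.array([3.0, 2.0, 1.0])
        assert average_age_group([s, s]) == pytest.approx(s)

    def test_bracket_grouping(self):
        young = np.array([10.0, 1.0])
        old = np.array([2.0, 1.0])
        out = average_age_group([young, young, old],
                                donor_ages=[25, 30, 70])
        assert out[(20.0, 40.0)][1] == 2
        assert out[(60.0, np.inf)][0] == pytest.approx(old)

    def test_rejects_empty_and_mismatched(self):
        with pytest.raises(ValueError):
            average_age_group([])
        with pytest.raises(ValueError):
            average_age_group([np.ones(3), np.ones(4)])


class TestLatticeFit:
    def test_delta_vanishes_for_self_consistent_data(self):
        from stemvaf.vafinfer import _predicted_lowest
        predicted = _predicted_lowest(2000.0, 0.0, DESK_FIXED)
        assert delta_vf(2000.0, 0.0, DESK_FIXED, predicted) \
            == pytest.approx(0.0, abs=1e-9)

    def test_predicted_lowest_count_monotone_in_population_size(self):
        from stemvaf.vafinfer import _predicted_lowest
        preds = [_predicted_lowest(NM, 0.0, DESK_FIXED)
                 for NM in (500.0, 2000.0, 8000.0)]
        assert preds[0] < preds[1] < preds[2]

    def test_all_zero_data_has_no_contour(self):
        from stemvaf.vafinfer import _predicted_lowest
        base = _predicted_lowest(500.0, 0.0, DESK_FIXED)
        # observed count below every prediction in range -> delta > 0
        lat = lattice_fit(0.5 * base, np.array([500.0, 2000.0, 8000.0]),
                          np.array([0.0]), DESK_FIXED)
        assert np.all(lat.delta > 0)
        with pytest.raises(ValueError):
            zero_contour(lat)

    def test_contour_trades_population_size_against_asymmetry(self):
        # larger asymmetric fraction shifts less variant mass per division,
        # so matching the same data needs a smaller population: the contour
        # has negative slope in (p, NM)
        from stemvaf.vafinfer import _predicted_lowest
        observed = _predicted_lowest(2000.0, 0.0, DESK_FIXED)
        lat = lattice_fit(observed, np.geomspace(500, 8000, 4),
                          np.array([0.0, 0.4, 0.8]), DESK_FIXED)
        curve = zero_contour(lat)
        assert np.all(np.diff(curve) < 0)
        assert max_population(lat, curve) == pytest.approx(2000.0, rel=0.05)

    def test_max_population_interpolates_to_p_zero(self):
        lat = FitLattice(NM_axis=np.array([1.0, 2.0]),
                         p_axis=np.array([0.2, 0.6]),
                         delta=np.zeros((2, 2)), fixed={})
        curve = np.array([100.0, 50.0])
        assert max_population(lat, curve) == pytest.approx(125.0)


class TestPipelineSelfRecovery:
    def test_contour_brackets_generating_size_in_most_replicates(self):
        # simulate -> sample 89 cells -> lowest-frequency fit: the zero
        # crossing lands within 1.5x of the generating population size in
        # nearly every replicate
        from stemvaf.vafinfer import _predicted_lowest
        NM_true = 2000.0
        p = build_params(NM=NM_true, tM=3.0, NH=20, lam=5.0, p=0.0, mu=1.2)
        fixed = {"tM": 3.0, "NH": 20.0, "mu": 1.2, "lam": 5.0,
                 "t_obs": 30.0, "S": 89, "n": 300}
        NM_axis = np.geomspace(700, 6000, 4)
        preds = np.array([_predicted_lowest(NM, 0.0, fixed)
                          for NM in NM_axis])
        rng = np.random.default_rng(21)
        hits = 0
        reps = 8
        for _ in range(reps):
            g = simulate(p, 30.0, seed=rng)
            obs = float(g.spectrum_of(g.sample_cells(89, seed=rng))[0])
            delta = preds - obs
            assert delta[0] < 0 < delta[-1]
            star = np.exp(np.interp(0.0, delta, np.log(NM_axis)))
            if NM_true / 1.5 <= star <= NM_true * 1.5:
                hits += 1
        assert hits >= reps - 1


class TestSampledClassVariability:
    def test_lowest_frequency_class_has_smallest_relative_spread(self):
        # the justification for fitting only the 1/S class: across
        # replicates its coefficient of variation is the smallest among the
        # sampled abundance classes
        p = build_params(NM=200, tM=2.0, NH=10, lam=4.0, p=0.2, mu=1.0)
        reps, S = 100, 20
        mat = np.empty((reps, S))
        rng = np.random.default_rng(3)
        for r in range(reps):
            g = simulate(p, 15.0, seed=rng)
            mat[r] = g.spectrum_of(g.sample_cells(S, seed=rng))
        means = mat.mean(axis=0)
        cv = mat.std(axis=0, ddof=1) / np.maximum(means, 1e-12)
        classes = np.nonzero(means > 1.0)[0]  # populated classes only
        assert cv[classes].argmin() == 0
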