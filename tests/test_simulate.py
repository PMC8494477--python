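"""Synthetic-data generators and their analytic characterisations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from prevalence import (
    ERPSimParams,
    HierarchicalModelParams,
    TestResultCounts,
    TwoTestGroundTruth,
    expected_prevalence_summaries,
    joint_true_positive_rate,
    map_estimate,
    population_ttest_power,
    simulate_erp,
    simulate_hierarchical,
    simulate_two_tests,
    summary_stat_group_ttest,
    theta_from_gamma,
    within_participant_ttest,
)
from prevalence.simulate import two_test_cell_probabilities


class TestHierarchical:
    def test_degenerate_model_is_constant(self):
        params = HierarchicalModelParams.single(5, 10, 2.5, 0.0, 0.0, seed=1)
        assert np.allclose(simulate_hierarchical(params), 2.5)

    def test_participant_mean_variance(self):
        # marginal of within-participant means is N(mu, sigma_b^2 + sigma_w^2/T)
        params = HierarchicalModelParams.single(4000, 50, 0.0, 2.0, 10.0, seed=2)
        means = simulate_hierarchical(params).mean(axis=1)
        expected_var = 2.0**2 + 10.0**2 / 50
        assert means.var() == pytest.approx(expected_var, rel=0.1)
        assert abs(means.mean()) < 0.15

    def test_mixture_grand_mean(self):
        # heterogeneous population: 75% near zero, 25% at 16 -> grand mean 4
        params = HierarchicalModelParams(
            4000, 20, [(0.75, 0.0, 0.1), (0.25, 16.0, 0.5)], 10.0, seed=3
        )
        data = simulate_hierarchical(params)
        assert data.mean() == pytest.approx(4.0, abs=0.3)

    def test_seed_determinism(self):
        p = HierarchicalModelParams.single(10, 10, 1.0, 2.0, 10.0, seed=4)
        assert np.array_equal(simulate_hierarchical(p), simulate_hierarchical(p))

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            HierarchicalModelParams(10, 10, [(0.5, 0.0, 1.0)], 1.0)


class TestTtests:
    def test_constant_row_errors(self):
        trials = np.ones((3, 10))
        with pytest.raises(ValueError, match="zero trial variance"):
            within_participant_ttest(trials)

    def test_null_at_row_mean(self, rng):
        trials = rng.normal(3.0, 1.0, (1, 40))
        t, p = within_participant_ttest(trials, mu0=float(trials.mean()))
        assert t[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_null_calibration(self, rng):
        trials = rng.normal(0.0, 1.0, (10_000, 20))
        _, p = within_participant_ttest(trials)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)

    def test_group_ttest(self, rng):
        means = rng.normal(0.0, 1.0, 30)
        t, p = summary_stat_group_ttest(means, mu0=float(means.mean()))
        assert t == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            summary_stat_group_ttest(np.ones(10))


class TestErp:
    def test_null_participants_are_pure_noise(self):
        params = ERPSimParams(100, 40, 200, seed=5, amplitude_range=(0.0, 0.0), peak_window=(50.0, 150.0))
        res = simulate_erp(params)
        assert np.all(res.amplitudes == 0.0)
        assert res.data.mean() == pytest.approx(0.0, abs=0.01)
        assert res.data.std() == pytest.approx(1.0, abs=0.01)

    def test_familywise_error_with_bonferroni(self):
        # timepointwise tests, Bonferroni over the time axis: about 5% of
        # pure-noise participants show any significant point
        n, trials, pts = 200, 40, 200
        res = simulate_erp(
            ERPSimParams(n, trials, pts, seed=6, amplitude_range=(0, 0),
                         peak_window=(50.0, 150.0))
        )
        fw = 0
        for i in range(n):
            _, p = within_participant_ttest(res.data[i].T)  # (pts, trials)
            fw += bool((p < 0.05 / pts).any())
        assert 1 <= fw <= 23  # Binomial(200, ~0.05) within ~3.5 sd

    def test_narrow_template_confines_bump(self):
        params = ERPSimParams(
            1, 2000, 100, template_sd=1e-9, amplitude_range=(5.0, 5.0),
            peak_window=(50.0, 50.0), seed=7,
        )
        res = simulate_erp(params)
        mean_trace = res.data[0].mean(axis=0)
        assert mean_trace[50] == pytest.approx(5.0, abs=0.2)
        assert np.all(np.abs(np.delete(mean_trace, 50)) < 0.5)

    def test_subgroup_design(self):
        res = simulate_erp(
            ERPSimParams(20, 10, 100, n_with_effect=10, amplitude_range=(0.3, 0.6),
                         peak_window=(20.0, 80.0), seed=8)
        )
        assert np.all(res.amplitudes[:10] > 0.0)
        assert np.all(res.amplitudes[10:] == 0.0)

    def test_strong_effect_all_detected_gives_full_prevalence(self):
        # all 20 participants carry a strong bump at varied latencies;
        # detection by max-t over time with Bonferroni correction
        pts = 600
        params = ERPSimParams(
            20, 100, pts, template_sd=20.0, amplitude_range=(0.45, 0.6),
            peak_window=(100.0, 400.0), seed=9,
        )
        res = simulate_erp(params)
        k = 0
        for i in range(20):
            _, p = within_participant_ttest(res.data[i].T)
            k += bool((p < 0.05 / pts).any())
        assert k == 20
        from prevalence import summarize

        s = summarize(TestResultCounts(k, 20, 0.05))
        assert s.map == 1.0
        assert s.hpdi_lo == pytest.approx(0.85, abs=0.005)


class TestTwoTests:
    def test_independence(self):
        gt = TwoTestGroundTruth(0.4, 0.3, 0.0, 0.05)
        assert joint_true_positive_rate(gt) == pytest.approx(0.12)

    def test_perfect_correlation(self):
        gt = TwoTestGroundTruth(0.5, 0.5, 1.0, 0.05)
        assert joint_true_positive_rate(gt) == pytest.approx(0.5)

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            joint_true_positive_rate(TwoTestGroundTruth(0.9, 0.9, -1.0, 0.05))

    def test_matches_correlated_bernoulli_oracle(self, rng):
        # brute-force oracle: draw correlated Bernoulli pairs cellwise and
        # compare the empirical both-positive rate and correlation
        gt = TwoTestGroundTruth(0.5, 0.25, 0.2, 0.05)
        g11 = joint_true_positive_rate(gt)
        cells = [g11, 0.5 - g11, 0.25 - g11, 1 - 0.5 - 0.25 + g11]
        draws = rng.choice(4, size=1_000_000, p=cells)
        x = (draws == 0) | (draws == 1)
        y = (draws == 0) | (draws == 2)
        assert (x & y).mean() == pytest.approx(g11, abs=0.002)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.2, abs=0.005)

    def test_no_prevalence_leaves_alpha_squared(self):
        theta = two_test_cell_probabilities(TwoTestGroundTruth(0.0, 0.0, 0.0, 0.05))
        assert theta[0] == pytest.approx(0.05**2)

    @given(
        st.floats(0.05, 0.95), st.floats(0.05, 0.95), st.floats(-0.15, 0.15),
        st.floats(0.01, 0.2),
    )
    def test_cell_probabilities_sum_to_one(self, g1, g2, rho, alpha):
        gt = TwoTestGroundTruth(g1, g2, rho, alpha)
        try:
            theta = two_test_cell_probabilities(gt)
        except ValueError:
            return  # infeasible corner of the strategy space
        assert theta.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(theta >= 0.0)

    def test_counts_near_expectation(self):
        gt = TwoTestGroundTruth(0.5, 0.25, 0.2, 0.05)
        theta = two_test_cell_probabilities(gt)
        ks = np.array(
            [
                [c.k11, c.k10, c.k01, c.k00]
                for c in (simulate_two_tests(gt, 50, seed=s) for s in range(300))
            ]
        )
        assert np.allclose(ks.mean(axis=0) / 50, theta, atol=0.02)

    def test_seed_determinism(self):
        gt = TwoTestGroundTruth(0.5, 0.25, 0.2, 0.05)
        assert simulate_two_tests(gt, 50, seed=3) == simulate_two_tests(gt, 50, seed=3)


class TestPowerAndExpectations:
    def test_null_power_equals_alpha(self):
        assert population_ttest_power(30, 100, 0.0, 2.0, 10.0, 0.05) == pytest.approx(
            0.05, abs=1e-6
        )

    def test_monotone_in_n_and_t(self):
        base = population_ttest_power(20, 100, 1.0, 2.0, 10.0)
        assert population_ttest_power(40, 100, 1.0, 2.0, 10.0) > base
        assert population_ttest_power(20, 400, 1.0, 2.0, 10.0) > base

    def test_matches_monte_carlo(self, rng):
        # participant means are exactly normal under the hierarchical model,
        # so simulating at the mean level is an exact oracle
        n, t = 50, 500
        sd = np.sqrt(2.0**2 + 10.0**2 / t)
        means = rng.normal(1.0, sd, size=(10_000, n))
        _, p = stats.ttest_1samp(means, 0.0, axis=1)
        mc = (p < 0.05).mean()
        assert population_ttest_power(n, t, 1.0, 2.0, 10.0) == pytest.approx(mc, abs=0.01)

    def test_large_noncentrality_is_finite(self):
        assert population_ttest_power(200, 500, 5.0, 1.0, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_expected_map_limit(self):
        e_map, _, _ = expected_prevalence_summaries(1.0, 1e-6, 30)
        assert e_map == pytest.approx(1.0, abs=1e-3)

    def test_hpdi_width_shrinks_with_n(self):
        widths = [
            expected_prevalence_summaries(0.5, 0.05, n)[2] for n in (10, 20, 50, 100)
        ]
        assert np.all(np.diff(widths) < 0)

    def test_enumeration_matches_monte_carlo(self, rng):
        gamma, alpha, n = 0.5, 0.05, 40
        e_map, e_lb, e_w = expected_prevalence_summaries(gamma, alpha, n)
        ks = rng.binomial(n, theta_from_gamma(gamma, alpha), size=10_000)
        uniq, counts = np.unique(ks, return_counts=True)
        from prevalence import PrevalencePosterior, hpdi, lower_bound

        maps = widths = lbs = 0.0
        for k, c in zip(uniq, counts):
            tc = TestResultCounts(int(k), n, alpha)
            post = PrevalencePosterior(tc)
            lo, hi = hpdi(post, 0.96)
            w = c / len(ks)
            maps += w * map_estimate(tc)
            widths += w * (hi - lo)
            lbs += w * lower_bound(post, 0.95)
        assert e_map == pytest.approx(maps, abs=0.01)
        assert e_w == pytest.approx(widths, abs=0.01)
        assert e_lb == pytest.approx(lbs, abs=0.01)


class TestEndToEndRecovery:
    def test_pipeline_recovers_expected_prevalence(self):
        # hierarchical sim -> within-participant t-tests -> prevalence MAP,
        # against the analytic expected rate of significant participants
        mu, sb, sw, t, n = 1.0, 2.0, 10.0, 100, 200
        params = HierarchicalModelParams.single(n, t, mu, sb, sw, seed=17)
        data = simulate_hierarchical(params)
        _, p = within_participant_ttest(data)
        k = int((p < 0.05).sum())
        est = map_estimate(TestResultCounts(k, n, 0.05))
        # analytic oracle: E[significance rate] by Gauss-Hermite quadrature
        xs, ws = np.polynomial.hermite_e.hermegauss(41)
        df = t - 1
        tcrit = stats.t.isf(0.025, df)
        probs = []
        for x in xs:
            ncp = (mu + sb * x) / sw * np.sqrt(t)
            pr = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
            if np.isnan(pr):
                pr = 1.0
            probs.append(pr)
        rate = float(np.sum(ws * np.array(probs)) / np.sum(ws))
        expected_gamma = (rate - 0.05) / 0.95
        assert abs(est - expected_gamma) < 0.1
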